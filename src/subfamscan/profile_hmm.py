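"""Profile hidden Markov models for protein subfamily discrimination.

A profile HMM is built from a trusted multiple alignment: alignment columns
with sufficient residue occupancy become match states, residues falling
between match columns are modelled by insert states, and absent residues by
(silent) delete states.  Scoring is a *global* (whole-domain) forward pass in
log space, reported as a log2-odds bit score against an i.i.d. null model;
alignment of a query to the model is the Viterbi path.  Statistical
significance comes from a Gumbel (type-I extreme value) fit to the scores of
null-sampled sequences, giving the familiar E-value

    E(s) = N * (1 - exp(-exp(-lambda * (s - mu))))

for a database of N sequences.

All dynamic programming uses natural-log space with no scaling tricks; the
inner loops are numba-compiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from numba import njit
from scipy import stats

from .errors import CalibrationError, ModelError, ScoringError
from .seqio import AMINO_ACIDS, GAP, Alignment, SequenceRecord

_LN2 = math.log(2.0)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_X_CODE = 20  # unknown residue: scored at log-odds zero

# successor slots in transition tables: 0 = next match (or End), 1 = insert,
# 2 = next delete
_TO_M, _TO_I, _TO_D = 0, 1, 2


@dataclass(frozen=True)
class Calibration:
    """Gumbel location/scale of the null score distribution."""

    mu: float
    lam: float
    n_random: int
    seed: int


@dataclass(frozen=True)
class ProfileHMM:
    """Immutable profile HMM parameters.

    match_emissions : (L, 20) row-stochastic
    insert_emissions: (L+1, 20) row-stochastic, insert state I_j sits after
        match state j (I_0 before the first match)
    trans_m/_i/_d   : (L+1, 3) probabilities of (to-match, to-insert,
        to-delete) leaving M_j / I_j / D_j; row 0 of trans_m is the Begin
        state, slot 0 at row L is the End transition
    null_model     : (20,) background residue frequencies
    """

    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    trans_m: np.ndarray
    trans_i: np.ndarray
    trans_d: np.ndarray
    null_model: np.ndarray
    calibration: Calibration | None = None

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def __post_init__(self):
        L = self.length
        if L < 1:
            raise ModelError("profile must have at least one match state")
        for name, arr, shape in [
            ("match_emissions", self.match_emissions, (L, 20)),
            ("insert_emissions", self.insert_emissions, (L + 1, 20)),
            ("trans_m", self.trans_m, (L + 1, 3)),
            ("trans_i", self.trans_i, (L + 1, 3)),
            ("trans_d", self.trans_d, (L + 1, 3)),
            ("null_model", self.null_model, (20,)),
        ]:
            if arr.shape != shape:
                raise ModelError(f"{name}: expected shape {shape}, got {arr.shape}")
        for name, arr in [
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
            ("null_model", self.null_model[None, :]),
            ("trans_m", self.trans_m),
            ("trans_i", self.trans_i),
            ("trans_d", self.trans_d),
        ]:
            sums = arr.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ModelError(f"{name}: rows do not sum to 1 (max dev {abs(sums - 1).max():.2e})")

    # -- derived quantities -------------------------------------------------

    def consensus(self) -> str:
        """Most probable residue per match state."""
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))

    def _log_odds(self):
        """(lm, li, tm, ti, td) natural-log arrays for the DP kernels.

        Emission arrays carry a 21st column for X at log-odds zero; the null
        is folded into the emissions, so path scores are odds ratios.
        """
        L = self.length
        with np.errstate(divide="ignore"):
            ln_null = np.log(self.null_model)
            lm = np.full((L + 1, 21), -np.inf)
            lm[1:, :20] = np.log(self.match_emissions) - ln_null
            lm[1:, 20] = 0.0
            li = np.full((L + 1, 21), 0.0)
            li[:, :20] = np.log(self.insert_emissions) - ln_null
            tm = np.log(self.trans_m)
            ti = np.log(self.trans_i)
            td = np.log(self.trans_d)
        return lm, li, tm, ti, td


def encode_sequence(seq: str) -> np.ndarray:
    """Map residues to integer codes 0..19 (X -> 20); reject anything else."""
    codes = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        if ch in _AA_INDEX:
            codes[i] = _AA_INDEX[ch]
        elif ch == "X":
            codes[i] = _X_CODE
        else:
            raise ScoringError(f"residue {ch!r} at position {i + 1} is outside the alphabet")
    if len(codes) == 0:
        raise ScoringError("cannot score an empty sequence")
    return codes


# ---------------------------------------------------------------------------
# DP kernels


@njit(cache=True)
def _lse3(a, b, c):
    m = max(a, max(b, c))
    if m == -np.inf:
        return -np.inf
    return m + np.log(np.exp(a - m) + np.exp(b - m) + np.exp(c - m))


@njit(cache=True)
def _forward_kernel(codes, lm, li, tm, ti, td):
    T = codes.shape[0]
    L = lm.shape[0] - 1
    NEG = -np.inf
    vm = np.full((T + 1, L + 1), NEG)
    vi = np.full((T + 1, L + 1), NEG)
    vd = np.full((T + 1, L + 1), NEG)
    vm[0, 0] = 0.0  # Begin
    for j in range(1, L + 1):  # leading delete chain
        vd[0, j] = _lse3(vm[0, j - 1] + tm[j - 1, 2], vi[0, j - 1] + ti[j - 1, 2], vd[0, j - 1] + td[j - 1, 2])
    for i in range(1, T + 1):
        x = codes[i - 1]
        vi[i, 0] = li[0, x] + _lse3(vm[i - 1, 0] + tm[0, 1], vi[i - 1, 0] + ti[0, 1], vd[i - 1, 0] + td[0, 1])
        for j in range(1, L + 1):
            vm[i, j] = lm[j, x] + _lse3(
                vm[i - 1, j - 1] + tm[j - 1, 0],
                vi[i - 1, j - 1] + ti[j - 1, 0],
                vd[i - 1, j - 1] + td[j - 1, 0],
            )
            vi[i, j] = li[j, x] + _lse3(
                vm[i - 1, j] + tm[j, 1], vi[i - 1, j] + ti[j, 1], vd[i - 1, j] + td[j, 1]
            )
            vd[i, j] = _lse3(
                vm[i, j - 1] + tm[j - 1, 2], vi[i, j - 1] + ti[j - 1, 2], vd[i, j - 1] + td[j - 1, 2]
            )
    return _lse3(vm[T, L] + tm[L, 0], vi[T, L] + ti[L, 0], vd[T, L] + td[L, 0])


@njit(cache=True)
def _viterbi_kernel(codes, lm, li, tm, ti, td):
    T = codes.shape[0]
    L = lm.shape[0] - 1
    NEG = -np.inf
    vm = np.full((T + 1, L + 1), NEG)
    vi = np.full((T + 1, L + 1), NEG)
    vd = np.full((T + 1, L + 1), NEG)
    pm = np.zeros((T + 1, L + 1), dtype=np.int8)
    pi = np.zeros((T + 1, L + 1), dtype=np.int8)
    pd = np.zeros((T + 1, L + 1), dtype=np.int8)
    vm[0, 0] = 0.0
    for j in range(1, L + 1):
        a = vm[0, j - 1] + tm[j - 1, 2]
        b = vi[0, j - 1] + ti[j - 1, 2]
        c = vd[0, j - 1] + td[j - 1, 2]
        if a >= b and a >= c:
            vd[0, j], pd[0, j] = a, 0
        elif b >= c:
            vd[0, j], pd[0, j] = b, 1
        else:
            vd[0, j], pd[0, j] = c, 2
    for i in range(1, T + 1):
        x = codes[i - 1]
        a = vm[i - 1, 0] + tm[0, 1]
        b = vi[i - 1, 0] + ti[0, 1]
        c = vd[i - 1, 0] + td[0, 1]
        if a >= b and a >= c:
            vi[i, 0], pi[i, 0] = li[0, x] + a, 0
        elif b >= c:
            vi[i, 0], pi[i, 0] = li[0, x] + b, 1
        else:
            vi[i, 0], pi[i, 0] = li[0, x] + c, 2
        for j in range(1, L + 1):
            a = vm[i - 1, j - 1] + tm[j - 1, 0]
            b = vi[i - 1, j - 1] + ti[j - 1, 0]
            c = vd[i - 1, j - 1] + td[j - 1, 0]
            if a >= b and a >= c:
                vm[i, j], pm[i, j] = lm[j, x] + a, 0
            elif b >= c:
                vm[i, j], pm[i, j] = lm[j, x] + b, 1
            else:
                vm[i, j], pm[i, j] = lm[j, x] + c, 2
            a = vm[i - 1, j] + tm[j, 1]
            b = vi[i - 1, j] + ti[j, 1]
            c = vd[i - 1, j] + td[j, 1]
            if a >= b and a >= c:
                vi[i, j], pi[i, j] = li[j, x] + a, 0
            elif b >= c:
                vi[i, j], pi[i, j] = li[j, x] + b, 1
            else:
                vi[i, j], pi[i, j] = li[j, x] + c, 2
            a = vm[i, j - 1] + tm[j - 1, 2]
            b = vi[i, j - 1] + ti[j - 1, 2]
            c = vd[i, j - 1] + td[j - 1, 2]
            if a >= b and a >= c:
                vd[i, j], pd[i, j] = a, 0
            elif b >= c:
                vd[i, j], pd[i, j] = b, 1
            else:
                vd[i, j], pd[i, j] = c, 2
    a = vm[T, L] + tm[L, 0]
    b = vi[T, L] + ti[L, 0]
    c = vd[T, L] + td[L, 0]
    if a >= b and a >= c:
        best, state = a, 0
    elif b >= c:
        best, state = b, 1
    else:
        best, state = c, 2
    return best, state, pm, pi, pd


# ---------------------------------------------------------------------------
# model construction


def match_column_indices(alignment: Alignment, match_occupancy: float = 0.5) -> np.ndarray:
    """0-based alignment columns that qualify as match states."""
    n_seq = len(alignment)
    occ = np.array(
        [
            sum(r.residues[c] != GAP for r in alignment.records) / n_seq
            for c in range(alignment.n_columns)
        ]
    )
    return np.flatnonzero(occ >= match_occupancy)


def build_profile(
    alignment: Alignment,
    match_occupancy: float = 0.5,
    pseudocount_weight: float = 1.0,
    null_model: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from a multiple alignment.

    Columns whose non-gap occupancy is >= ``match_occupancy`` become match
    states.  Emissions are background-mixture pseudocounted,
    ``(counts + w * background) / (n + w)``, with uniform sequence weights;
    transitions are estimated from each row's implied state path with
    Laplace add-one smoothing.
    """
    if null_model is None:
        null_model = np.full(20, 1.0 / 20.0)
    null_model = np.asarray(null_model, dtype=float)
    n_seq = len(alignment)
    n_cols = alignment.n_columns
    w = float(pseudocount_weight)

    match_cols = match_column_indices(alignment, match_occupancy)
    is_match = np.zeros(n_cols, dtype=bool)
    is_match[match_cols] = True
    L = len(match_cols)
    if L == 0:
        raise ModelError("no alignment column reaches the match-state occupancy threshold")

    # column -> match index (1-based); insert region index for non-match cols
    region_of_col = np.searchsorted(match_cols, np.arange(n_cols), side="left")

    match_counts = np.zeros((L, 20))
    insert_counts = np.zeros((L + 1, 20))
    tc_m = np.zeros((L + 1, 3))
    tc_i = np.zeros((L + 1, 3))
    tc_d = np.zeros((L + 1, 3))

    for rec in alignment.records:
        state, pos = _TO_M, 0  # Begin behaves like M_0
        for c in range(n_cols):
            ch = rec.residues[c]
            if is_match[c]:
                j = int(region_of_col[c]) + 1
                if ch == GAP:
                    nxt = _TO_D
                else:
                    nxt = _TO_M
                    if ch != "X":
                        match_counts[j - 1, _AA_INDEX[ch]] += 1
                (tc_m, tc_i, tc_d)[state][pos, nxt] += 1
                state, pos = nxt, j
            elif ch != GAP:
                r = int(region_of_col[c])
                if ch != "X":
                    insert_counts[r, _AA_INDEX[ch]] += 1
                (tc_m, tc_i, tc_d)[state][pos, _TO_I] += 1
                state, pos = _TO_I, r
        (tc_m, tc_i, tc_d)[state][pos, _TO_M] += 1  # -> End

    def _pseudo(counts):
        n = counts.sum(axis=1, keepdims=True)
        return (counts + w * null_model) / (n + w)

    match_emissions = _pseudo(match_counts)
    insert_emissions = _pseudo(insert_counts)

    def _laplace(tc):
        tc = tc + 1.0
        tc[L, _TO_D] = 0.0  # no delete state beyond the last match
        return tc / tc.sum(axis=1, keepdims=True)

    return ProfileHMM(
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        trans_m=_laplace(tc_m),
        trans_i=_laplace(tc_i),
        trans_d=_laplace(tc_d),
        null_model=null_model,
    )


# ---------------------------------------------------------------------------
# scoring / alignment


def forward_score(hmm: ProfileHMM, seq: str | SequenceRecord) -> float:
    """Global forward log2-odds (bit) score of ``seq`` against the model."""
    if isinstance(seq, SequenceRecord):
        seq = seq.ungapped
    codes = encode_sequence(seq)
    ln = _forward_kernel(codes, *hmm._log_odds())
    return float(ln / _LN2)


def viterbi_align(hmm: ProfileHMM, seq: str | SequenceRecord) -> str:
    """Best-path alignment of ``seq`` in model coordinates (a2m style).

    Upper-case letters sit in match columns, ``-`` marks a deleted match
    column, lower-case letters are insertions relative to the model.
    """
    if isinstance(seq, SequenceRecord):
        seq = seq.ungapped
    codes = encode_sequence(seq)
    residues = "".join("X" if c == _X_CODE else AMINO_ACIDS[c] for c in codes)
    _, state, pm, pi, pd = _viterbi_kernel(codes, *hmm._log_odds())
    # traceback from (T, L) in end-state `state`
    i, j = len(codes), hmm.length
    path: list[tuple[int, int, int]] = []  # (state, i, j)
    while not (state == _TO_M and i == 0 and j == 0):
        path.append((state, i, j))
        if state == _TO_M:
            state = int(pm[i, j])
            i, j = i - 1, j - 1
        elif state == _TO_I:
            state = int(pi[i, j])
            i = i - 1
        else:
            state = int(pd[i, j])
            j = j - 1
    out = []
    for st, i, j in reversed(path):
        if st == _TO_M:
            out.append(residues[i - 1])
        elif st == _TO_I:
            out.append(residues[i - 1].lower())
        else:
            out.append(GAP)
    return "".join(out)


def match_columns_only(a2m: str) -> str:
    """Strip insertions from an a2m string, keeping the fixed model width."""
    return "".join(ch for ch in a2m if not ch.islower())


# ---------------------------------------------------------------------------
# E-value calibration


def calibrate(hmm: ProfileHMM, n_random: int = 1000, seed: int = 0) -> ProfileHMM:
    """Fit a Gumbel law to the scores of null-sampled random sequences.

    Draws ``n_random`` i.i.d. sequences of the model length from the null
    residue frequencies, scores them, and fits location/scale by maximum
    likelihood.  Returns a calibrated copy of the model.
    """
    if n_random < 10:
        raise CalibrationError("need at least 10 random sequences to calibrate")
    rng = np.random.default_rng(seed)
    L = hmm.length
    draws = rng.choice(20, size=(n_random, L), p=hmm.null_model)
    lods = hmm._log_odds()
    scores = np.array(
        [_forward_kernel(d.astype(np.int64), *lods) / _LN2 for d in draws]
    )
    if not np.isfinite(scores).all() or scores.std() < 1e-12:
        raise CalibrationError("degenerate null score distribution")
    mu, beta = stats.gumbel_r.fit(scores)
    if beta <= 0:
        raise CalibrationError(f"non-positive Gumbel scale {beta}")
    return replace(
        hmm, calibration=Calibration(mu=float(mu), lam=1.0 / float(beta), n_random=n_random, seed=seed)
    )


def evalue(hmm: ProfileHMM, bit_score: float, db_size: int) -> float:
    """Expected number of null hits scoring >= ``bit_score`` in ``db_size``."""
    if hmm.calibration is None:
        raise CalibrationError("model is not calibrated; run calibrate() first")
    if db_size <= 0:
        raise ValueError("db_size must be positive")
    cal = hmm.calibration
    z = cal.lam * (bit_score - cal.mu)
    p = -math.expm1(-math.exp(-z)) if z > -700 else 1.0
    return db_size * p


def score_sequences(hmm: ProfileHMM, records, db_size: int):
    """Score many records; returns a DataFrame (id, bit_score, evalue)."""
    import pandas as pd

    rows = []
    for rec in records:
        s = forward_score(hmm, rec)
        rows.append((rec.id, s, evalue(hmm, s, db_size)))
    return pd.DataFrame(rows, columns=["id", "bit_score", "evalue"])


# ---------------------------------------------------------------------------
# plain-text serialization


def save_profile(hmm: ProfileHMM, path: str | Path) -> None:
    """Write the profile in a documented plain-text format (one state/line)."""

    def fmt(v):
        return " ".join(repr(float(x)) for x in v)

    with open(path, "w") as fh:
        fh.write("# subfamscan profile v1\n")
        fh.write(f"length {hmm.length}\n")
        if hmm.calibration is None:
            fh.write("calibration none\n")
        else:
            c = hmm.calibration
            fh.write(f"calibration {c.mu!r} {c.lam!r} {c.n_random} {c.seed}\n")
        fh.write(f"null {fmt(hmm.null_model)}\n")
        for j in range(hmm.length):
            fh.write(f"match {j + 1} {fmt(hmm.match_emissions[j])}\n")
        for j in range(hmm.length + 1):
            fh.write(f"insert {j} {fmt(hmm.insert_emissions[j])}\n")
        for name, arr in [("tm", hmm.trans_m), ("ti", hmm.trans_i), ("td", hmm.trans_d)]:
            for j in range(hmm.length + 1):
                fh.write(f"{name} {j} {fmt(arr[j])}\n")


def load_profile(path: str | Path) -> ProfileHMM:
    fields: dict[str, list] = {"match": [], "insert": [], "tm": [], "ti": [], "td": []}
    null = None
    calibration = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, *rest = line.split()
            if key == "length":
                continue
            if key == "calibration":
                if rest[0] != "none":
                    calibration = Calibration(
                        float(rest[0]), float(rest[1]), int(rest[2]), int(rest[3])
                    )
            elif key == "null":
                null = np.array([float(x) for x in rest])
            elif key in fields:
                fields[key].append(np.array([float(x) for x in rest[1:]]))
    return ProfileHMM(
        match_emissions=np.vstack(fields["match"]),
        insert_emissions=np.vstack(fields["insert"]),
        trans_m=np.vstack(fields["tm"]),
        trans_i=np.vstack(fields["ti"]),
        trans_d=np.vstack(fields["td"]),
        null_model=null,
        calibration=calibration,
    )
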