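"""Iterative profile refinement.

The refinement loop mirrors classic iterative homology search: build a
profile from a trusted seed alignment, score a candidate database, absorb the
best hits into the alignment, prune redundancy, rebuild, and repeat until no
new target-family sequences are retrieved (or an iteration cap).  Every
sequence's E-value under every iteration's profile is recorded in an
E-value matrix m_ij (sequence i, iteration j), the bookkeeping object used to
watch the profile converge onto the target family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import profile_hmm as ph
from .errors import ModelError
from .seqio import GAP, Alignment, SequenceRecord, dedupe

log = logging.getLogger(__name__)


@dataclass
class RefinementConfig:
    """Tunables of the refinement loop (defaults follow standard practice
    for this pipeline: absorb the ten best hits, prune at 80% identity,
    cap at seven iterations)."""

    k_top: int = 10
    dedupe_threshold: float = 0.80
    max_iters: int = 7
    match_occupancy: float = 0.5
    pseudocount_weight: float = 1.0
    calibration_n: int = 1000
    target_label: str | None = "PriA"
    db_size: int | None = None  # default: initial training-set size


@dataclass
class IterationState:
    """Snapshot of the loop before iteration ``iteration``."""

    iteration: int
    profile: ph.ProfileHMM
    model_alignment: Alignment
    training_set: list[SequenceRecord]
    retrieved_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.retrieved_ids) & {r.id for r in self.training_set}
        if overlap:
            raise ValueError(f"absorbed ids still in training set: {sorted(overlap)}")


class EvalueMatrix:
    """Sparse matrix of E-values: rows are sequence ids, columns iterations."""

    def __init__(self):
        self._cells: dict[tuple[str, int], float] = {}

    def add(self, seq_id: str, iteration: int, evalue: float) -> None:
        if evalue < 0:
            raise ValueError("E-values must be non-negative")
        self._cells[(seq_id, iteration)] = evalue

    def get(self, seq_id: str, iteration: int) -> float | None:
        return self._cells.get((seq_id, iteration))

    def to_frame(self) -> pd.DataFrame:
        if not self._cells:
            return pd.DataFrame()
        ids = sorted({k[0] for k in self._cells})
        iters = sorted({k[1] for k in self._cells})
        data = [
            [self._cells.get((i, j), np.nan) for j in iters] for i in ids
        ]
        return pd.DataFrame(data, index=ids, columns=[f"iter{j}" for j in iters])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


@dataclass
class RefinementResult:
    profiles: list[ph.ProfileHMM]
    evalue_matrix: EvalueMatrix
    final_state: IterationState
    absorbed: list[list[str]]  # per executed absorbing iteration
    stopped_reason: str = ""


def _calib_seed(base_seed: int, iteration: int) -> int:
    return int((base_seed + 9973 * iteration) % (2**31))


def trim_to_seed_region(alignment: Alignment, seed_ids: set[str]) -> Alignment:
    """Drop columns where the seed rows' consensus is a gap.

    This is the deterministic stand-in for manual alignment editing: the
    model only keeps columns the seed family actually occupies.
    """
    seed_rows = [r for r in alignment.records if r.id in seed_ids]
    if not seed_rows:
        return alignment
    n = alignment.n_columns
    drop = [
        c
        for c in range(n)
        if sum(r.residues[c] == GAP for r in seed_rows) * 2 > len(seed_rows)
    ]
    return alignment.drop_columns(drop) if drop else alignment


def _top_hits(scores: pd.DataFrame, k_top: int) -> pd.DataFrame:
    """Lowest-E hits; ties at the k-th boundary are all included."""
    ranked = scores.sort_values(["evalue", "id"], kind="stable")
    if len(ranked) <= k_top:
        return ranked
    cutoff = ranked["evalue"].iloc[k_top - 1]
    return ranked[ranked["evalue"] <= cutoff]


def run_iteration(
    state: IterationState,
    config: RefinementConfig | None = None,
    seed: int = 0,
    matrix: EvalueMatrix | None = None,
) -> IterationState:
    """One absorb/rebuild cycle; returns the state for the next iteration.

    Scores the training set under the current profile, absorbs the ``k_top``
    best hits (aligned into the model alignment via Viterbi, in score
    order), removes them from the training set, trims and redundancy-prunes
    the alignment, then rebuilds and recalibrates the profile.
    """
    config = config or RefinementConfig()
    if not state.training_set:
        raise ValueError("training set is empty")
    db_size = config.db_size or len(state.training_set)

    scores = ph.score_sequences(state.profile, state.training_set, db_size)
    if matrix is not None:
        for _, row in scores.iterrows():
            matrix.add(row["id"], state.iteration, row["evalue"])

    if len(state.training_set) < config.k_top:
        warnings.warn(
            f"training set ({len(state.training_set)}) smaller than k_top "
            f"({config.k_top}); absorbing all remaining sequences",
            stacklevel=2,
        )
    hits = _top_hits(scores, config.k_top)
    hit_ids = list(hits["id"])
    by_id = {r.id: r for r in state.training_set}

    # project current model alignment onto the current profile's match columns
    match_cols = set(
        ph.match_column_indices(state.model_alignment, config.match_occupancy).tolist()
    )
    non_match = [
        c for c in range(state.model_alignment.n_columns) if c not in match_cols
    ]
    model_rows = (
        state.model_alignment.drop_columns(non_match)
        if non_match
        else state.model_alignment
    )

    aligned_hits = [
        SequenceRecord(
            h,
            ph.match_columns_only(ph.viterbi_align(state.profile, by_id[h])),
            by_id[h].description,
            by_id[h].label,
        )
        for h in hit_ids
    ]
    merged = Alignment(model_rows.records + aligned_hits)
    seed_ids = {r.id for r in model_rows.records}
    merged = trim_to_seed_region(merged, seed_ids)
    merged = dedupe(merged, config.dedupe_threshold)

    next_profile = ph.build_profile(
        merged,
        match_occupancy=config.match_occupancy,
        pseudocount_weight=config.pseudocount_weight,
        null_model=state.profile.null_model,
    )
    next_profile = ph.calibrate(
        next_profile,
        n_random=config.calibration_n,
        seed=_calib_seed(seed, state.iteration + 1),
    )
    log.info(
        "iteration %d absorbed %d hits: %s", state.iteration, len(hit_ids), hit_ids
    )
    return IterationState(
        iteration=state.iteration + 1,
        profile=next_profile,
        model_alignment=merged,
        training_set=[r for r in state.training_set if r.id not in set(hit_ids)],
        retrieved_ids=state.retrieved_ids + hit_ids,
    )


def iterate(
    seed_alignment: Alignment,
    training_set: list[SequenceRecord],
    config: RefinementConfig | None = None,
    seed: int = 0,
) -> RefinementResult:
    """Run the refinement loop to convergence.

    Stops at ``max_iters``, when the training set is exhausted, or — when a
    ``target_label`` is configured — as soon as none of the best hits of an
    iteration carries that label (no new target-family sequences retrieved).
    """
    config = config or RefinementConfig()
    profile = ph.build_profile(
        seed_alignment,
        match_occupancy=config.match_occupancy,
        pseudocount_weight=config.pseudocount_weight,
    )
    profile = ph.calibrate(
        profile, n_random=config.calibration_n, seed=_calib_seed(seed, 1)
    )
    state = IterationState(1, profile, seed_alignment, list(training_set))
    matrix = EvalueMatrix()
    profiles = [profile]
    absorbed: list[list[str]] = []
    reason = "max_iters"

    if not training_set:
        return RefinementResult(profiles, matrix, state, absorbed, "empty training set")

    if config.db_size is None:
        config = RefinementConfig(**{**config.__dict__, "db_size": len(training_set)})

    while True:
        db_size = config.db_size
        scores = ph.score_sequences(state.profile, state.training_set, db_size)
        for _, row in scores.iterrows():
            matrix.add(row["id"], state.iteration, row["evalue"])
        hits = _top_hits(scores, config.k_top)
        if config.target_label is not None:
            labels = {r.id: r.label for r in state.training_set}
            if not any(labels[h] == config.target_label for h in hits["id"]):
                reason = "no new target-family hits"
                break
        if state.iteration >= config.max_iters:
            break
        # absorb (scores recomputed inside run_iteration; matrix already filled)
        state = run_iteration(state, config, seed=seed, matrix=None)
        profiles.append(state.profile)
        absorbed.append(state.retrieved_ids[len(sum(absorbed, [])):])
        if not state.training_set:
            reason = "training set exhausted"
            break
    return RefinementResult(profiles, matrix, state, absorbed, reason)


def refine_profile(
    profile_alignment: Alignment,
    outlier_ids,
    match_occupancy: float = 0.5,
    pseudocount_weight: float = 1.0,
    calibration_n: int = 1000,
    seed: int = 0,
) -> ph.ProfileHMM:
    """Rebuild (and recalibrate) the model after removing outlier sequences.

    The refined profile drops manually flagged outliers from the model
    alignment — sequences whose E-value trajectories mark them as drifting
    away from the target family — and re-estimates everything else
    identically.
    """
    ids = set(outlier_ids)
    missing = ids - set(profile_alignment.ids())
    if missing:
        raise ValueError(f"outlier ids not in alignment: {sorted(missing)}")
    kept = [r for r in profile_alignment.records if r.id not in ids]
    if not kept:
        raise ModelError("removing all sequences leaves nothing to model")
    hmm = ph.build_profile(
        Alignment(kept),
        match_occupancy=match_occupancy,
        pseudocount_weight=pseudocount_weight,
    )
    return ph.calibrate(hmm, n_random=calibration_n, seed=seed)
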