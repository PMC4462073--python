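import math

import numpy as np
import pytest

from subfamscan import profile_hmm as ph
from subfamscan.errors import CalibrationError, ModelError, ScoringError
from subfamscan.seqio import AMINO_ACIDS, Alignment, SequenceRecord

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# independent oracle: explicit enumeration of every state path


def enumerate_forward_odds(hmm, seq):
    """Total odds P(seq|hmm)/P(seq|null) by summing over all explicit paths.

    Linear-space recursion over (state, consumed residues, model position);
    independent of the package's log-space dynamic programming.
    """
    L = hmm.length
    codes = [AA_INDEX[c] for c in seq]
    null = hmm.null_model
    trans = {"M": hmm.trans_m, "I": hmm.trans_i, "D": hmm.trans_d}

    def from_state(state, i, j):
        total = 0.0
        row = trans[state][j]
        if j == L:
            if i == len(codes):
                total += row[0]  # -> End
        else:
            if i < len(codes):
                x = codes[i]
                total += row[0] * (hmm.match_emissions[j, x] / null[x]) * from_state("M", i + 1, j + 1)
            total += row[2] * from_state("D", i, j + 1)
        if i < len(codes):
            x = codes[i]
            total += row[1] * (hmm.insert_emissions[j, x] / null[x]) * from_state("I", i + 1, j)
        return total

    return from_state("M", 0, 0)


def random_profile(rng, length):
    def rows(shape):
        return rng.dirichlet(np.ones(shape[-1]), size=shape[:-1])

    null = rng.dirichlet(np.ones(20))
    tm = rows((length + 1, 3))
    ti = rows((length + 1, 3))
    td = rows((length + 1, 3))
    for t in (tm, ti, td):  # no delete state beyond the last match
        t[length, 2] = 0.0
        t[length] /= t[length].sum()
    return ph.ProfileHMM(
        match_emissions=rows((length, 20)),
        insert_emissions=rows((length + 1, 20)),
        trans_m=tm,
        trans_i=ti,
        trans_d=td,
        null_model=null,
    )


class TestForwardAgainstEnumeration:
    def test_forward_equals_path_enumeration_on_small_models(self):
        """Forward log-odds must match brute-force path summation to 1e-9
        for every small model/sequence combination tried."""
        rng = np.random.default_rng(2024)
        checked = 0
        for length in (1, 2, 3):
            for _ in range(4):
                hmm = random_profile(rng, length)
                for seq_len in (1, 2, 3, 4):
                    for _ in range(3):
                        seq = "".join(rng.choice(list("ACDE"), size=seq_len))
                        expected = math.log2(enumerate_forward_odds(hmm, seq))
                        assert ph.forward_score(hmm, seq) == pytest.approx(
                            expected, abs=1e-9
                        )
                        checked += 1
        assert checked == 144


def one_state_model():
    m = np.zeros((1, 20))
    m[0, AA_INDEX["A"]] = 1.0
    uniform = np.full((2, 20), 1 / 20)
    forced = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    return ph.ProfileHMM(m, uniform, forced.copy(), forced.copy(), forced.copy(), np.full(20, 1 / 20))


class TestForwardScore:
    def test_deterministic_single_match_state_closed_form(self):
        # P(A|model)=1 on the only path, null emits A at 1/20 -> log2(20) bits
        assert ph.forward_score(one_state_model(), "A") == pytest.approx(
            math.log2(20), abs=1e-12
        )

    def test_consensus_dominates_null_sequences(self, tiny_alignment):
        hmm = ph.build_profile(tiny_alignment)
        consensus_score = ph.forward_score(hmm, hmm.consensus())
        rng = np.random.default_rng(0)
        null_scores = [
            ph.forward_score(hmm, "".join(rng.choice(list(AMINO_ACIDS), size=5)))
            for _ in range(20)
        ]
        assert consensus_score >= max(null_scores)

    def test_rejects_residues_outside_alphabet(self, tiny_alignment):
        hmm = ph.build_profile(tiny_alignment)
        with pytest.raises(ScoringError):
            ph.forward_score(hmm, "AC-EF")
        with pytest.raises(ScoringError):
            ph.forward_score(hmm, "")


class TestBuildProfile:
    def test_identical_sequences_make_peaked_match_states(self):
        aln = Alignment([SequenceRecord(f"r{i}", "ACDEF") for i in range(3)])
        hmm = ph.build_profile(aln, pseudocount_weight=0.01)
        assert hmm.length == 5
        assert hmm.consensus() == "ACDEF"
        assert hmm.match_emissions.max(axis=1).min() > 0.99

    def test_occupancy_boundary_column_is_match(self):
        # 2 of 4 residues present: occupancy 0.5 >= 0.5 -> match state
        aln = Alignment(
            [
                SequenceRecord("a", "AC"),
                SequenceRecord("b", "AC"),
                SequenceRecord("c", "A-"),
                SequenceRecord("d", "A-"),
            ]
        )
        assert ph.build_profile(aln, match_occupancy=0.5).length == 2

    def test_low_occupancy_column_becomes_insert_region(self):
        aln = Alignment(
            [
                SequenceRecord("a", "A-C"),
                SequenceRecord("b", "A-C"),
                SequenceRecord("c", "AWC"),
                SequenceRecord("d", "A-C"),
            ]
        )
        hmm = ph.build_profile(aln)
        assert hmm.length == 2
        # the W was observed in the insert region after match state 1
        assert hmm.insert_emissions[1, AA_INDEX["W"]] > hmm.insert_emissions[1, AA_INDEX["A"]]

    def test_no_qualifying_columns_is_an_error(self):
        aln = Alignment([SequenceRecord("a", "A--"), SequenceRecord("b", "-A-"), SequenceRecord("c", "--A")])
        with pytest.raises(ModelError):
            ph.build_profile(aln, match_occupancy=0.5)

    def test_normalization_always_holds(self, tiny_alignment):
        hmm = ph.build_profile(tiny_alignment, pseudocount_weight=2.5)
        # __post_init__ enforces this; re-assert on the arrays directly
        for arr in (hmm.match_emissions, hmm.insert_emissions, hmm.trans_m, hmm.trans_i, hmm.trans_d):
            np.testing.assert_allclose(arr.sum(axis=-1), 1.0, atol=1e-9)


class TestViterbi:
    def test_consensus_aligns_all_match(self, tiny_alignment):
        hmm = ph.build_profile(tiny_alignment)
        assert ph.viterbi_align(hmm, hmm.consensus()) == hmm.consensus()

    def test_missing_residue_creates_one_deletion(self, tiny_alignment):
        hmm = ph.build_profile(tiny_alignment)
        aligned = ph.viterbi_align(hmm, "ACEF")  # consensus ACDEF minus D
        assert aligned == "AC-EF"

    def test_extra_residue_is_lowercase_insertion(self, tiny_alignment):
        hmm = ph.build_profile(tiny_alignment)
        aligned = ph.viterbi_align(hmm, "ACWDEF")
        assert ph.match_columns_only(aligned) == "ACDEF"
        assert [c for c in aligned if c.islower()] == ["w"]

    def test_viterbi_never_exceeds_forward(self, tiny_alignment):
        hmm = ph.build_profile(tiny_alignment)
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(3, 9))))
            codes = ph.encode_sequence(seq)
            vit, *_ = ph._viterbi_kernel(codes, *hmm._log_odds())
            fwd = ph._forward_kernel(codes, *hmm._log_odds())
            assert vit <= fwd + 1e-12


class TestCalibration:
    def test_same_seed_reproduces_parameters(self, tiny_alignment):
        hmm = ph.build_profile(tiny_alignment)
        c1 = ph.calibrate(hmm, 100, seed=3).calibration
        c2 = ph.calibrate(hmm, 100, seed=3).calibration
        assert (c1.mu, c1.lam) == (c2.mu, c2.lam)
        assert c1.lam > 0

    def test_evalue_at_mu_matches_gumbel_closed_form(self, tiny_alignment):
        hmm = ph.calibrate(ph.build_profile(tiny_alignment), 200, seed=1)
        # P(score >= mu) = 1 - exp(-1) for a Gumbel law
        expected = 100 * (1 - math.exp(-1))
        assert ph.evalue(hmm, hmm.calibration.mu, 100) == pytest.approx(expected, rel=1e-9)

    def test_evalue_monotone_and_linear_in_db_size(self, tiny_alignment):
        hmm = ph.calibrate(ph.build_profile(tiny_alignment), 200, seed=1)
        # strictly decreasing in the resolvable regime (far below the Gumbel
        # location the survival function saturates at 1 in float arithmetic)
        mu = hmm.calibration.mu
        scores = np.linspace(mu, mu + 60, 25)
        evals = [ph.evalue(hmm, s, 100) for s in scores]
        assert all(a > b for a, b in zip(evals, evals[1:]))
        assert ph.evalue(hmm, 5.0, 200) == pytest.approx(2 * ph.evalue(hmm, 5.0, 100))
        assert ph.evalue(hmm, 1e6, 100) == pytest.approx(0.0, abs=1e-200)

    def test_evalue_ordering_invariant_to_db_size(self, tiny_alignment):
        hmm = ph.calibrate(ph.build_profile(tiny_alignment), 200, seed=1)
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=5)) for _ in range(8)]
        for db in (10, 1000):
            ranks = np.argsort([ph.evalue(hmm, ph.forward_score(hmm, s), db) for s in seqs])
            if db == 10:
                first = list(ranks)
        assert list(ranks) == first

    def test_uncalibrated_model_cannot_give_evalues(self, tiny_alignment):
        with pytest.raises(CalibrationError):
            ph.evalue(ph.build_profile(tiny_alignment), 10.0, 100)


class TestSerialization:
    def test_profile_text_round_trip_is_exact(self, tiny_alignment, tmp_path):
        hmm = ph.calibrate(ph.build_profile(tiny_alignment), 100, seed=2)
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        ph.save_profile(hmm, p1)
        back = ph.load_profile(p1)
        ph.save_profile(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        np.testing.assert_array_equal(back.match_emissions, hmm.match_emissions)
        assert back.calibration == hmm.calibration


def test_family_specific_profiles_prefer_their_own_sequences(small_config):
    """A model should score sequences drawn from its own family above
    sequences from a ~35%-identity sister family."""
    from subfamscan.synthetic_data import make_family_consensuses, sample_family

    cons = make_family_consensuses(small_config)
    fam_a = sample_family(cons["PriA"], 8, 0.9, seed=11, label="PriA")
    fam_b = sample_family(cons["HisA"], 8, 0.9, seed=12, label="HisA")
    model_a = ph.build_profile(Alignment(fam_a))
    scores_own = [ph.forward_score(model_a, r) for r in fam_a]
    scores_other = [ph.forward_score(model_a, r) for r in fam_b]
    assert min(scores_own) > max(scores_other)
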