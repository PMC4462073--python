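import pytest

from subfamscan import RefinementConfig, SyntheticConfig, run_benchmark_pipeline
from subfamscan.seqio import Alignment, SequenceRecord


@pytest.fixture()
def tiny_alignment():
    """Five ungapped, identical-length rows with one variable column."""
    rows = ["ACDEF", "ACDEF", "ACDEF", "ACDEW", "ACDEF"]
    return Alignment([SequenceRecord(f"r{i}", s) for i, s in enumerate(rows)])


@pytest.fixture(scope="session")
def small_config():
    """A benchmark small enough for repeated full-loop runs in tests."""
    return SyntheticConfig(
        seed=7,
        n_per_family=12,
        n_intermediates=4,
        n_decoys=6,
        n_seed_sequences=16,
        sequence_length=120,
        diagnostic_column=40,
        min_len=100,
        max_len=140,
    )


@pytest.fixture(scope="session")
def small_refinement():
    return RefinementConfig(k_top=5, calibration_n=200)


@pytest.fixture(scope="session")
def default_pipeline():
    """The full-scale recovery benchmark (shared: it is the expensive run)."""
    return run_benchmark_pipeline(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_pipeline(small_config, small_refinement):
    return run_benchmark_pipeline(small_config, small_refinement)
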