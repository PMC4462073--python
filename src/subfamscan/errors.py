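"""Exception hierarchy for subfamscan."""


class SubfamscanError(Exception):
    """Base class for all package errors."""


class FastaParseError(SubfamscanError):
    """Malformed FASTA input; message names the offending line."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ModelError(SubfamscanError):
    """Profile HMM cannot be built or is structurally invalid."""


class ScoringError(SubfamscanError):
    """A sequence cannot be scored against a profile."""


class CalibrationError(SubfamscanError):
    """E-value calibration failed or is missing."""


class ThresholdError(SubfamscanError):
    """Band boundaries cannot be derived (e.g. overlapping score groups)."""


class DesignError(SubfamscanError):
    """Truncation library design is infeasible for the given inputs."""


class GeneratorError(SubfamscanError):
    """Synthetic-data generation could not satisfy its constraints."""
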