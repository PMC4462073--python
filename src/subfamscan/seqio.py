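"""Sequence and alignment I/O, length filtering, identity, redundancy pruning.

Sequences are plain protein strings over the 20-residue alphabet plus ``X``
(unknown).  Alignment rows additionally carry the gap symbol ``-``.  The FASTA
reader is deliberately strict: malformed headers or illegal residue symbols
raise :class:`~subfamscan.errors.FastaParseError` naming the line, which is
what you want when screening large mixed databases before an expensive
profile search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FastaParseError, SubfamscanError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"

_RESIDUE_SET = frozenset(ALPHABET)
_ALIGNED_SET = frozenset(ALPHABET + GAP)

#: Recognised subfamily truth labels.
LABELS = ("HisA", "PriA", "subHisA", "intermediate", "unknown")


@dataclass
class SequenceRecord:
    """A named protein sequence with an optional subfamily truth label.

    ``residues`` is stored upper-case.  Gap symbols are only legal when the
    record lives inside an :class:`Alignment` (``aligned=True`` on
    construction paths that permit them).
    """

    id: str
    residues: str
    description: str = ""
    label: str | None = None

    def __post_init__(self):
        self.residues = self.residues.upper()
        if not self.residues:
            raise SubfamscanError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - _ALIGNED_SET
        if bad:
            raise SubfamscanError(
                f"record {self.id!r}: illegal symbols {sorted(bad)}"
            )
        if self.label is not None and self.label not in LABELS:
            raise SubfamscanError(
                f"record {self.id!r}: unknown label {self.label!r}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.ungapped)


@dataclass
class Alignment:
    """An ordered multiple alignment; every row shares the same width."""

    records: list[SequenceRecord]

    def __post_init__(self):
        if not self.records:
            raise SubfamscanError("alignment must contain at least one record")
        widths = {len(r.residues) for r in self.records}
        if len(widths) != 1:
            raise SubfamscanError(f"ragged alignment: row widths {sorted(widths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, i: int) -> str:
        return "".join(r.residues[i] for r in self.records)

    def drop_columns(self, cols: Iterable[int]) -> "Alignment":
        drop = set(cols)
        keep = [i for i in range(self.n_columns) if i not in drop]
        return Alignment(
            [
                SequenceRecord(
                    r.id,
                    "".join(r.residues[i] for i in keep),
                    r.description,
                    r.label,
                )
                for r in self.records
            ]
        )


def _parse_fasta_lines(lines: Iterable[str], aligned: bool) -> list[tuple[str, str, str]]:
    allowed = _ALIGNED_SET if aligned else _RESIDUE_SET
    entries: list[tuple[str, str, list[str]]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            header = line[1:].strip()
            if not header:
                raise FastaParseError("empty FASTA header", lineno)
            name, _, desc = header.partition(" ")
            entries.append((name, desc, []))
        else:
            if not entries:
                raise FastaParseError("sequence data before first header", lineno)
            chunk = line.strip().upper()
            bad = set(chunk) - allowed
            if bad:
                raise FastaParseError(
                    f"illegal residue symbols {sorted(bad)}", lineno
                )
            entries[-1][2].append(chunk)
    return [(name, desc, "".join(parts)) for name, desc, parts in entries]


def read_fasta(path: str | Path, labels: dict[str, str] | None = None) -> list[SequenceRecord]:
    """Read unaligned FASTA; order preserved, one record per header.

    ``labels`` optionally maps record id -> subfamily truth label.
    """
    with open(path) as fh:
        parsed = _parse_fasta_lines(fh, aligned=False)
    labels = labels or {}
    return [
        SequenceRecord(name, seq, desc, labels.get(name))
        for name, desc, seq in parsed
    ]


def read_alignment(path: str | Path) -> Alignment:
    """Read aligned FASTA (gap symbol ``-``) into an :class:`Alignment`."""
    with open(path) as fh:
        parsed = _parse_fasta_lines(fh, aligned=True)
    return Alignment([SequenceRecord(n, s, d) for n, d, s in parsed])


def write_fasta(records: Sequence[SequenceRecord] | Alignment, path: str | Path, width: int = 60) -> None:
    """Write FASTA with canonical 60-character line wrapping."""
    if isinstance(records, Alignment):
        records = records.records
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def filter_by_length(
    records: Iterable[SequenceRecord], min_len: int, max_len: int
) -> list[SequenceRecord]:
    """Keep records whose ungapped length is within [min_len, max_len]."""
    if min_len < 0 or max_len < 0:
        raise ValueError("length bounds must be non-negative")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in records if min_len <= len(r) <= max_len]


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over columns where both rows are non-gap.

    Returns 0.0 when the two gap patterns share no column.  Case-insensitive.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    a = a.upper()
    b = b.upper()
    shared = matches = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            shared += 1
            if x == y:
                matches += 1
    return matches / shared if shared else 0.0


def dedupe(alignment: Alignment, threshold: float = 0.80) -> Alignment:
    """Greedy redundancy pruning at a percent-identity threshold.

    Scans rows in order; a row is dropped iff its identity to an
    already-kept row is *strictly* above ``threshold``.  When called from the
    refinement loop, row order is score rank, so the better-scoring member of
    a redundant pair survives.  Idempotent.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept: list[SequenceRecord] = []
    for rec in alignment.records:
        if all(pairwise_identity(rec.residues, k.residues) <= threshold for k in kept):
            kept.append(rec)
    return Alignment(kept)


def identity_matrix(alignment: Alignment):
    """All-vs-all identity as a pandas DataFrame (ids on both axes)."""
    import pandas as pd

    ids = alignment.ids()
    rows = [
        [pairwise_identity(a.residues, b.residues) for b in alignment.records]
        for a in alignment.records
    ]
    return pd.DataFrame(rows, index=ids, columns=ids)
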