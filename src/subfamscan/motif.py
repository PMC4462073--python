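"""Diagnostic residues, N-terminal phosphate-binding-site motifs, codon paths.

The HisA/PriA/subHisA subfamilies are told apart by a single diagnostic
residue at a reference position (position 81 in PriA numbering): glycine in
HisA, serine in PriA, threonine in subHisA.  An alanine there marks a
candidate evolutionary intermediate, since Ala is a one-substitution stop on
the codon-level path from Gly to Ser (e.g. GGC -> GCC -> TCC).  The residue
heads the three-column N-PBS motif (GlyGlyGly / AlaGlyGly / SerGlyGly).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .seqio import GAP, Alignment

#: diagnostic residue -> subfamily class
DIAGNOSTIC_CLASSES = {"G": "HisA", "S": "PriA", "T": "subHisA", "A": "intermediate"}

_CODON_TABLE = unambiguous_dna_by_id[1]
_DNA = set("ACGT")


@dataclass(frozen=True)
class CodonPath:
    """Shortest mutational route between two codons.

    ``one_step_intermediates`` are the codons one substitution away from the
    source that still lie on a shortest path to the target, with their
    translations ('*' for stop).
    """

    source_codon: str
    target_codon: str
    min_substitutions: int
    one_step_intermediates: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class MotifCall:
    npbs_motif: str
    diagnostic_residue: str
    residue_class: str


def residue_class(residue: str) -> str:
    """Subfamily implied by the diagnostic residue (total over the alphabet)."""
    if len(residue) != 1:
        raise ValueError("expected a single residue symbol")
    return DIAGNOSTIC_CLASSES.get(residue.upper(), "other")


def map_reference_position(alignment: Alignment, ref_id: str, ref_pos: int) -> int:
    """Alignment column (1-based) holding the reference's ``ref_pos``-th residue.

    ``ref_pos`` is 1-based in the ungapped reference sequence.
    """
    matches = [r for r in alignment.records if r.id == ref_id]
    if not matches:
        raise KeyError(f"reference {ref_id!r} not in alignment")
    row = matches[0].residues
    if not 1 <= ref_pos <= len(row.replace(GAP, "")):
        raise IndexError(
            f"position {ref_pos} beyond reference length {len(row.replace(GAP, ''))}"
        )
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            seen += 1
            if seen == ref_pos:
                return col
    raise AssertionError("unreachable")


def extract_motif(aligned_row: str, diagnostic_column: int, width: int = 3) -> MotifCall:
    """Diagnostic residue and N-PBS motif from an aligned row.

    ``diagnostic_column`` is 1-based in alignment coordinates; the motif is
    the ``width`` columns starting there (gaps kept as '-').
    """
    if not 1 <= diagnostic_column <= len(aligned_row):
        raise IndexError(f"column {diagnostic_column} outside alignment width")
    res = aligned_row[diagnostic_column - 1].upper()
    motif = aligned_row[diagnostic_column - 1 : diagnostic_column - 1 + width].upper()
    return MotifCall(
        npbs_motif=motif,
        diagnostic_residue=res,
        residue_class=residue_class(res) if res != GAP else "other",
    )


def translate_codon(codon: str) -> str:
    """One-letter translation of a DNA codon ('*' for stop)."""
    codon = normalize_codon(codon)
    if codon in _CODON_TABLE.stop_codons:
        return "*"
    return _CODON_TABLE.forward_table[codon]


def normalize_codon(codon: str) -> str:
    """Upper-case, RNA U -> DNA T, validate symbols."""
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or set(codon) - _DNA:
        raise ValueError(f"not a DNA codon: {codon!r}")
    return codon


def codon_path(source: str, target: str) -> CodonPath:
    """Hamming distance between codons plus the one-step shortest-path stops."""
    source = normalize_codon(source)
    target = normalize_codon(target)
    diff = [i for i in range(3) if source[i] != target[i]]
    intermediates = set()
    if len(diff) >= 2:
        for i in diff:
            codon = source[:i] + target[i] + source[i + 1 :]
            intermediates.add((codon, translate_codon(codon)))
    return CodonPath(
        source_codon=source,
        target_codon=target,
        min_substitutions=len(diff),
        one_step_intermediates=frozenset(intermediates),
    )


def codon_path_report(path: CodonPath) -> str:
    """Small human-readable summary of a codon path."""
    lines = [
        f"{path.source_codon} ({translate_codon(path.source_codon)}) -> "
        f"{path.target_codon} ({translate_codon(path.target_codon)}): "
        f"{path.min_substitutions} substitution(s)"
    ]
    for codon, aa in sorted(path.one_step_intermediates):
        lines.append(f"  one-step intermediate: {codon} ({aa})")
    return "\n".join(lines)
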