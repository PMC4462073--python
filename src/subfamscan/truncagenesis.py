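"""Codon-resolution C-terminal truncation library design ("truncagenesis").

Designs the nested reverse-primer sets that delete a protein's C-terminal
residues one codon at a time over a target region (default 75 residues, e.g.
a 261-residue enzyme scanned down to 186).  Each primer anneals immediately
upstream of the removed codons and is finished with an antisense stop codon
plus a restriction site for cloning; primers are partitioned into
consecutive synthesis sets (default 15 per set, hence five sets for a
75-residue region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import DesignError

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class TruncationPrimer:
    name: str
    truncation_point: int  # k: number of codons removed
    sequence: str
    set_index: int  # 1-based synthesis set


@dataclass(frozen=True)
class TruncationDesign:
    target_cds: str
    region_len: int
    set_size: int
    restriction_site: str
    primer_sets: list[list[TruncationPrimer]]

    @property
    def n_variants(self) -> int:
        return self.region_len

    @property
    def primers(self) -> list[TruncationPrimer]:
        return [p for s in self.primer_sets for p in s]


def design_truncation_primers(
    cds: str,
    region_len: int = 75,
    set_size: int = 15,
    restriction_site: str = "AAGCTT",
    anneal_len: int = 18,
    stop_codon: str = "TAA",
) -> TruncationDesign:
    """One reverse primer per truncation point k = 1..region_len.

    The primer for point k is the reverse complement of the last
    ``anneal_len`` nucleotides of the retained coding region, followed by the
    antisense (reverse-complement) stop codon and the restriction site.
    Warns when a retained coding region already contains the restriction
    site (an in-frame cloning clash).
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise DesignError(f"CDS length {len(cds)} is not a multiple of 3")
    if set(cds) - set("ACGT"):
        raise DesignError("CDS contains non-ACGT symbols")
    if set(restriction_site.upper()) - _IUPAC_DNA:
        raise DesignError(f"invalid IUPAC restriction site {restriction_site!r}")
    n_codons = len(cds) // 3
    if region_len < 1:
        raise DesignError("region_len must be >= 1")
    if n_codons < region_len + 1:
        raise DesignError(
            f"CDS of {n_codons} codons too short to remove {region_len} and keep one"
        )
    if 3 * (n_codons - region_len) < anneal_len:
        raise DesignError("annealing segment would run past the start of the CDS")

    anti_stop = str(Seq(stop_codon.upper().replace("U", "T")).reverse_complement())
    primers: list[TruncationPrimer] = []
    clashes: list[str] = []
    for k in range(1, region_len + 1):
        retained = cds[: 3 * (n_codons - k)]
        anneal = retained[-anneal_len:]
        name = f"trunc_{k:03d}"
        if restriction_site.upper() in retained:
            clashes.append(name)
        primers.append(
            TruncationPrimer(
                name=name,
                truncation_point=k,
                sequence=str(Seq(anneal).reverse_complement()) + anti_stop + restriction_site.upper(),
                set_index=(k - 1) // set_size + 1,
            )
        )
    if clashes:
        warnings.warn(
            f"restriction site {restriction_site} occurs inside the retained CDS "
            f"for primers: {', '.join(clashes)}",
            stacklevel=2,
        )
    n_sets = (region_len + set_size - 1) // set_size
    sets = [[p for p in primers if p.set_index == s + 1] for s in range(n_sets)]
    return TruncationDesign(cds, region_len, set_size, restriction_site.upper(), sets)


def implied_cds(design: TruncationDesign, truncation_point: int, stop_codon: str = "TAA") -> str:
    """The truncated coding sequence a primer produces (incl. new stop)."""
    n_codons = len(design.target_cds) // 3
    return design.target_cds[: 3 * (n_codons - truncation_point)] + stop_codon


def coverage(n_colonies: int, n_variants: int) -> int:
    """Integer fold coverage of a variant library by a colony count."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if n_colonies < 0:
        raise ValueError("n_colonies must be non-negative")
    return n_colonies // n_variants


def enumerate_truncations(protein: str, min_len: int) -> list[str]:
    """Prefix variants of length L-1 down to ``min_len`` inclusive."""
    if not 0 < min_len < len(protein):
        raise ValueError(
            f"min_len must be in (0, {len(protein)}), got {min_len}"
        )
    return [protein[:length] for length in range(len(protein) - 1, min_len - 1, -1)]


def primers_to_fasta(design: TruncationDesign, path) -> None:
    with open(path, "w") as fh:
        for p in design.primers:
            fh.write(f">{p.name} set{p.set_index} k={p.truncation_point}\n{p.sequence}\n")


def order_sheet(design: TruncationDesign):
    """Primer order sheet as a DataFrame (name, truncation point, sequence, set)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "name": p.name,
                "truncation_point": p.truncation_point,
                "sequence": p.sequence,
                "set": p.set_index,
            }
            for p in design.primers
        ]
    )
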