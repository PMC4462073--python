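"""Design a codon-resolution C-terminal truncation library.

One reverse primer per truncation point removes the last k codons and
appends an antisense stop codon plus a HindIII site; primers are grouped
into synthesis sets.  A 75-residue scan of a 261-residue protein yields 75
variants (down to 186 residues) in five sets of fifteen primers.
"""

import numpy as np

from subfamscan import coverage, design_truncation_primers, enumerate_truncations

rng = np.random.default_rng(1)
codons = ["GAA", "CAT", "CTG", "CCG", "CGT", "ACC", "GTT", "TGG", "ATG", "GAC"]
cds = "".join(rng.choice(codons) for _ in range(261))

design = design_truncation_primers(cds, region_len=75, set_size=15)
print(f"{design.n_variants} truncation variants in {len(design.primer_sets)} sets "
      f"of {[len(s) for s in design.primer_sets]}")
print(f"first primer ({design.primers[0].name}): {design.primers[0].sequence}")

variants = enumerate_truncations("M" * 261, 186)
print(f"shortest encoded protein: {len(variants[-1])} residues "
      f"({len(variants)} variants total)")
print(f"14,000 colonies over {design.n_variants} variants = "
      f"{coverage(14_000, design.n_variants)}x library coverage")
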