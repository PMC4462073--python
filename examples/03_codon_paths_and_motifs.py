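"""Trace the codon-level mutational path behind a diagnostic-residue switch.

HisA enzymes carry Gly at the diagnostic position of the N-terminal
phosphate-binding site, PriA carries Ser.  At the codon level the switch
GGC (Gly) -> TCC (Ser) needs two substitutions, and one of the single-step
stops encodes alanine — exactly the residue found in candidate evolutionary
intermediates.
"""

from subfamscan import codon_path, residue_class
from subfamscan.motif import codon_path_report

path = codon_path("GGC", "UCC")  # RNA U is normalised to DNA T
print(codon_path_report(path))
print()
for residue in "GSAT W":
    if residue == " ":
        continue
    print(f"diagnostic residue {residue} -> {residue_class(residue)}")
print()
print("an alanine at the diagnostic position flags a Gly->Ser transitional form")
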