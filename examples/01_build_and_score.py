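"""Build a profile HMM from a small trusted alignment and score queries.

The bit score is the log2 odds of the sequence under the model versus an
i.i.d. background; the E-value is the number of hits this good expected by
chance from a database of the stated size (here 4), after Gumbel
calibration against null-sampled sequences.
"""

from subfamscan import build_profile, calibrate, forward_score, viterbi_align
from subfamscan.profile_hmm import evalue
from subfamscan.seqio import Alignment, SequenceRecord

alignment = Alignment(
    [
        SequenceRecord("a", "VEVSGGIRT"),
        SequenceRecord("b", "VEVSGGLRT"),
        SequenceRecord("c", "VEVSGGIKT"),
        SequenceRecord("d", "VELSGGIRT"),
    ]
)
hmm = calibrate(build_profile(alignment), n_random=500, seed=0)
print(f"profile with {hmm.length} match states, consensus {hmm.consensus()}")

queries = {
    "family member": "VEVSGGIRT",
    "one deletion": "VEVSGIRT",
    "unrelated": "WWWWWWWWW",
}
for name, seq in queries.items():
    bits = forward_score(hmm, seq)
    print(
        f"{name:14s} {seq:10s} bit={bits:7.2f}  E={evalue(hmm, bits, 4):.3g}  "
        f"aligned={viterbi_align(hmm, seq)}"
    )
print("higher bits / lower E = closer to the family; '-' marks a deleted column")
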