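# Methods

## Profile HMM

The model is the classic profile architecture: match states M₁..M_L with
20-residue emission vectors, insert states I₀..I_L, silent delete states
D₁..D_L, a Begin state treated as M₀ and an End reached from position L.
Alignment columns whose non-gap occupancy is ≥ `match_occupancy` (default
0.5) become match states. Emissions are background-mixture pseudocounted,

    e(x) = (c(x) + w · q(x)) / (n + w),

with uniform sequence weights, pseudocount weight `w = 1.0` by default and
background `q` uniform (1/20) unless supplied. Transitions are estimated
from each row's implied state path with Laplace add-one smoothing per
source-state bundle; the delete successor at the final position is removed
before normalisation. This is deliberately the simplest estimator that
preserves the pipeline's behaviour; `w` and the occupancy threshold are
exposed.

Scoring is the global forward algorithm in natural-log space (no scaling),
reported as log2-odds bits against the i.i.d. null; because every emitting
state emits exactly one residue, the null factorises into the emission
terms and the DP runs directly on log-odds. Alignment is the Viterbi path,
emitted in a2m convention (upper-case match, `-` deletion, lower-case
insertion). Both inner loops are numba-compiled; a brute-force path
enumeration in the test suite verifies the forward recursion to 1e-9 bits
on all small models.

Unknown residues (`X`) are scored at log-odds zero — they neither support
nor penalise a hit.

### E-value calibration

`n_random` (default 1000) sequences of the model length are drawn from the
null frequencies, scored, and fitted to a Gumbel law by maximum likelihood
(`scipy.stats.gumbel_r.fit`); λ = 1/scale. Then
`E(s) = N · (1 − exp(−exp(−λ(s − μ))))` for a database of N sequences. The
fit is deterministic given the seed. Two numerical notes: far below μ the
survival probability saturates at 1 in float arithmetic (E → N), and far
above μ E underflows to 0; both limits are harmless for ranking. Because
family hits sit hundreds of bits above μ, a percent-level refit of λ moves
their E-values by several decades — E-values are therefore treated as a
ranking/banding scale, and cross-iteration comparisons of model quality are
made in bits.

## Iterative refinement

Each iteration scores the remaining training set, takes the `k_top = 10`
lowest E-values (ties at the boundary included), Viterbi-aligns them into
the model alignment in score order, removes them from the training set
(anti-re-sampling), trims the alignment to the columns whose seed-row
consensus is non-gap (the deterministic stand-in for manual alignment
editing), prunes redundancy greedily at 80% identity — earlier rows, i.e.
model rows and better-scoring hits, survive a conflict — and rebuilds and
recalibrates the model. Identity is counted over columns where both rows
are non-gap, the common convention for redundancy filters; the raw-database
case is handled by aligning both sequences to the current profile first.
The loop stops at `max_iters = 7`, on an exhausted training set, or as soon
as none of the best hits carries the configured target label ("no new
target-family sequences"). The E-value matrix records every scored
sequence per iteration; absorbed sequences simply stop appearing.

`refine_profile` rebuilds the model after removing listed outlier rows,
for the curated-outlier-removal step of the workflow.

## Band classification

`compute_threshold` implements the midpoint rule literally, in linear
E-value space: the worst (largest) E of the better-scoring group subtracted
from the best (smallest) E of the worse group, halved, added back to the
better group's worst E. A `threshold_space: log10` switch computes the
geometric midpoint instead, kept for exploration; linear is the default.
Overlapping groups raise an error prompting manual review.

Four bands partition the axis: E ≤ t₁ → PriA, ≤ t₂ → subHisA, ≤ t₃ → TZ,
else HisA; boundary values go to the better band. With labelled validation
groups, t₁ comes from the PriA/subHisA extremes; when intermediate-labelled
exemplars exist they define the TZ boundaries (t₂ vs subHisA, t₃ vs HisA
— the ordering of the dot classes along the axis). Without exemplars, and
as the automatic fallback when an exemplar group touches a family cluster,
the subHisA–HisA gap is trisected in log10 E and its central half becomes
the TZ. The fallback guarantees the family bands whenever the clusters are
merely ordered, at the cost that planted intermediates near a gap edge can
leak into the adjacent band.

## Motifs and codon paths

Reference numbering is 1-based in the ungapped reference sequence;
`map_reference_position` projects it to an alignment column, and the
pipeline further projects through the final model's match columns. The
N-PBS motif is the three columns starting at the diagnostic column
(GlyGlyGly / AlaGlyGly / SerGlyGly triads). Diagnostic classes: G → HisA,
S → PriA, T → subHisA, A → intermediate, anything else → other. Codon
distance is Hamming distance over the three positions; one-step
intermediates are the single-substitution codons on shortest paths,
translated with the standard genetic code; RNA `U` is normalised to `T`.

## Truncagenesis

One reverse primer per truncation point k = 1..`region_len` (default 75):
the reverse complement of the last `anneal_len` (default 18) nucleotides of
the retained coding region, then the antisense stop codon (default TAA) and
the restriction site (default HindIII, AAGCTT). The string is reported
with the priming segment first and the appended elements last, matching the
synthesis description; melting temperature and synthesis chemistry are out
of scope. Primers partition into consecutive sets of `set_size` (default
15) from the shortest deletion outward. Coverage is floor(colonies /
variants). A warning lists primers whose retained CDS already contains the
restriction site. The structural invariant — translating each
primer-implied CDS reproduces the corresponding prefix variant — is tested
directly.

## Synthetic benchmark generator

The generator emulates the statistical structure the pipeline assumes, not
real sequences. Design choices, in the package's own terms:

- **Consensus geometry.** Three consensuses of length 261 with pairwise
  identities at the edges of the 35% ± 5 band: PriA~subHisA 0.40, PriA~HisA
  0.30, subHisA~HisA 0.35. The asymmetry makes the clusters order PriA <
  subHisA < HisA along the E-axis under a PriA-seeded profile, the geometry
  the classifier is built around. Site categories (all-equal / pairwise-
  equal / all-distinct) are allocated with the all-equal count as small as
  the identity targets allow: maximising the sites where subHisA and HisA
  share a residue keeps their score clusters parallel instead of
  independently noisy. Diagnostic residues G/S/T head a shared Gly-Gly
  motif.
- **Families** are i.i.d. per-site mutants of their consensus (uniform over
  the 19 alternatives, diagnostic column held fixed). The default
  within-family identity range (0.985, 0.995) models tight clades — the
  subfamilies of interest are genus- or sub-clade-restricted — and keeps
  within-cluster score spread small relative to the between-cluster gaps.
- **Seed alignment**: 24–64 (default 64) PriA-family rows at 0.88 identity
  to the consensus, emulating a curated, already non-redundant MSA of
  diverse homologs (rows fall below the 80% pruning threshold, so the
  model stays populated).
- **Intermediates** form one tight lineage, as the real candidate
  intermediates did: a single mosaic backbone (HisA backbone with an exact
  `blend = 0.06` fraction of the HisA/PriA differing sites taken from PriA,
  chosen without replacement so the fraction never fluctuates; alanine at
  the diagnostic column), then divergent copies at the family
  within-identity level. The blend places the lineage inside the
  subHisA–HisA score gap.
- **Decoys** are i.i.d. background draws with lengths spanning the retained
  200–300 size window; the database is the shuffled union, length-filtered.
  All component seeds derive from the single run seed, so outputs are
  byte-reproducible.

What passing the recovery test does **not** show about real data: real
subfamilies have correlated (selection-driven) site differences, indels,
and biased residue composition, none of which the generator models; real
between-cluster gaps are not guaranteed. With no indels in queries, the
identity/trim logic is exercised through gap-bearing alignments in the unit
tests instead.

## Known limitations

- Insert/delete transitions at positions never observed in the training
  alignment fall back to the Laplace prior (uniform over successors), so
  detour paths are cheap; for queries far from the family (~35% identity)
  the forward score absorbs roughly one bit of alternative-path mass per
  mismatched column, and the Viterbi alignment can occasionally shift a
  column through an indel detour. Column-level annotations of transition-
  zone candidates (diagnostic residue, motif) should be confirmed in the
  model alignment — in the recovery study this costs at most one of ten
  intermediates its alanine flag, without affecting band assignment.
- Global (glocal) alignment only; no local or multi-hit modes, no
  Dirichlet-mixture pseudocounts, no HMMER-format compatibility.
- E-values are calibrated per profile; comparisons across profiles are made
  in bits (see above).

## Problem sizes

The recovery study runs the full default conditions: 3 × 50 family
sequences of length 261, 10 intermediates, 50 decoys, ≤ 7 refinement
iterations with 1000-sequence recalibration each — about 40 s on one CPU.
Unit tests use scaled-down benchmarks (length 90–150, 10–15 sequences per
family) chosen to exercise identical code paths.
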