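# Methods

## Duplication scan

The cluster sequence is segmented into windows of `win_len` = 150 bp at a
step of 30 bp; only full-length windows are kept, so a cluster of length L
yields floor((L−150)/30)+1 windows. Every window is compared against every
*eligible* partner window — eligible meaning the two genomic intervals do
not overlap, plus an optional extra gap `min_separation` (default 0 bp).
The comparison is a global (Needleman–Wunsch) alignment with match +5,
mismatch −4, gap open −10, gap extend −0.5; percent identity is
100 × identical columns / alignment length, and N never counts as a match.
The best identity per window forms the identity profile; windows that are
more than 50% N are masked to 0 so repeat-masked stretches cannot seed
calls.

Regions are called on the profile's centered sliding mean over `run` = 5
windows (truncated to the available neighbours at the profile edges, so
cluster termini are not discarded). Maximal runs of windows whose sliding
mean strictly exceeds `id_min` = 80% become candidate regions — the union
of the member windows' intervals — and candidates spanning at least
`min_region` = 500 bp are reported. Because adjacent windows share 120 bp,
two nearby runs can have overlapping base-pair unions; such candidates are
merged before the span filter, which keeps reported regions disjoint. A
region's `mean_identity` is the plain mean of its member windows'
best identities (including any bridged dip windows), so a tandem
duplication block reports a value slightly below the per-copy identity.

Two performance modes wrap the same contract. The default applies a
shared-12-mer prefilter: window pairs sharing no exact 12-mer are skipped
(random 150-mers essentially never share one, while any pair above the 80%
threshold shares many), which turns the quadratic all-vs-all scan into a
near-linear one; an exhaustive mode (`prefilter_k=None`) aligns every pair
and is used to validate the prefilter on ≤20-kb inputs. A `fast` mode
replaces the aligner with gap-free (Hamming) identity.

Numerical caveats, both measured during development and reflected in the
tests:

- *Grid phase.* A duplication whose copy offset is not a multiple of the
  30-bp step has no on-grid partner window; the aligner absorbs the phase
  shift with end gaps and the per-window identity drops by roughly 10
  points for a 10–20 bp offset. Real duplications are arbitrary-phase, so
  reported identities are a lower bound; the planted test fixtures use
  step-multiple (tandem) offsets where the measurement is unbiased.
- *Gap-free optimality.* Under the scoring above, substitution-only pairs
  align gap-free — hence identity equals the Hamming value — only while
  substitutions are not tightly clustered; once ~11+ substitutions of 150
  cluster, two compensating 1-bp gaps can outscore a mismatch run. The
  Hamming-oracle tests therefore construct pairs with isolated
  substitutions (pairwise spacing ≥ 3 bp, ≤ 10% density), a regime verified
  gap-free on 2,000 random pairs.
- *Self-similarity of neighbours.* With `min_separation` = 0, two windows
  whose intervals merely touch are eligible partners; windows 150–180 bp
  apart overlap the same repeat copy in many biological repeats. For real
  scans a `min_separation` of one window length is recommended; the default
  follows the plain non-overlap reading.

## Skews and GRINS

GC skew (G−C)/(G+C) and TA skew (T−A)/(T+A) are computed per window on the
identical grid as the identity scan; N is ignored in the counts and a
window with a zero denominator is flagged undefined rather than imputed
(imputing 0 would bias regions toward failing). A duplicated region's skew
intensity is the mean of the *absolute per-window* skews over its defined
windows — window-level magnitudes, because a region whose halves skew in
opposite directions would cancel under region-level pooling. The default
pass rule is conjunctive: both mean absolute skews must exceed
`skew_min` = 0.15. An `either` rule is exposed for sensitivity analysis.
GRINS calls are always a subset of the duplicated regions; the caller
receives every candidate with its pass flag.

## Phylogeny

Pairwise codon alignment translates both coding sequences (frame 0; one
trailing stop codon is tolerated and stripped, internal stops are errors),
aligns the proteins globally under BLOSUM62 with gap open −11 / extend −1,
and expands each amino-acid column back to its source codon, so nucleotide
gaps are always codon-sized. The p-distance is the mismatch proportion over
comparable sites (pairwise deletion: columns containing a gap or N in
either row are dropped per pair). The Jukes-Cantor correction
d = −(3/4)ln(1 − 4p/3) is undefined at p ≥ 0.75; by default such pairs
raise with the pair named, and an opt-in cap mode substitutes d = 5.0.
Building the tree from *pairwise* distances removes the need for a joint
multiple alignment: the distance matrix, not the alignment, is the input
to neighbor-joining, and a pre-aligned FASTA can be supplied instead
(`aligned=True`) when a shared alignment is preferred.

Neighbor-joining is the canonical Saitou–Nei agglomeration: join the pair
minimising Q(i,j) = (n−2)d(i,j) − r_i − r_j (ties to the lowest index pair
for determinism), branch lengths l_i = d(i,j)/2 + (r_i−r_j)/(2(n−2)),
distance update d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2, negative branch lengths
clamped to 0. The last three nodes are joined by the three-point formulas,
so the output is an unrooted tree with a degree-3 root node; any rooting
shown in figures is presentational. Cherry (`is_sister_pair`) and
two-class bipartition (`split_consistent`) queries are evaluated on the
unrooted split set. On additive matrices NJ is exact; the test suite
verifies split-set and path-metric recovery to 1e-9 on random trees, and
cross-checks the topology against scikit-bio's independent NJ.

## Homology report

Region-vs-region identity matrices use the same global aligners (scan
scoring at the nucleotide level, BLOSUM62 at the protein level) with
identity = 100 × identical columns / alignment length *including gap
columns* — the most conservative common convention, stated in every report
header, since identity values shift by a point or two across conventions.
Truncated domains are flagged against the class median length (median, not
mean, so the truncated members themselves cannot drag the reference down):
a member ≥ `delta_min` = 40 residues shorter than the median is flagged.
The reference truncation signature is ~50 residues; 40 leaves margin
without flagging ordinary length variation. Note that with an even class
size the interpolated median sits between the two central order statistics,
so very small classes dominated by truncated members can under-flag.

## Synthetic data generator

`generate_cluster` emulates the gross anatomy of a PKS cluster: alternating
stop-free module ORFs (random codons at a target GC, stop codons
rejection-sampled) and i.i.d. intermodule spacers, laid out
spacer–module–…–module–spacer. Defaults: 4 modules × 900 bp, 150-bp
spacers, GC 0.5. It does *not* emulate domain grammar, codon-usage bias,
indels, or the strong GC skew of actinomycete genomes — so passing tests
demonstrate correctness of the detection machinery on known truth, not
sensitivity/specificity on real clusters.

`plant_duplication` copies an interval to a destination with each site
substituted (always to a *different* base) with probability `sub_rate`, so
expected identity is exactly 100(1−rate) — clean targets for scan tests.
With `frame` set, codons that the substitutions turned into stops are
repaired by re-drawing a substituted position, keeping the copy
translatable for protein-level analyses. Test fixtures plant *tandem*
copies (destination = source end): the 900-bp offset is a multiple of the
30-bp step, keeping source and copy in phase on the window grid, and the
two blocks merge into a single called region whose truth interval is the
source+copy union. `plant_skew` resequences an interval i.i.d. at base
probabilities solving the two skew equations at the configured GC
(magnitude-1 targets need a zero probability and are rejected); ORF
structure inside the interval is abandoned, since skew detection operates
on raw nucleotides. `evolve_on_tree` applies the Jukes-Cantor process per
site along each branch (substitution probability (3/4)(1−e^(−4d/3)) for
branch length d), with back-substitutions — matching the distance model the
tree inference assumes, unlike the exact-identity duplication planter.

Every generator operation is a pure function of its inputs and an explicit
seed; there is no hidden global random state.

## Problem sizes and defaults in the test suite

The end-to-end fixtures are desk-scale by design: a 10-kb cluster for
planted-duplication recovery (exhaustive all-vs-all mode, ~55k alignments),
a 12-kb flagship cluster with one skewed and one neutral tandem duplicate
for GRINS discrimination, 6-leaf trees at 1,500 sites × 10 replicates for
tree recovery, and 200 random 4–12-leaf trees for the NJ oracle. The
pipelines themselves are deterministic — identical configuration and input
reproduce byte-identical artifacts, and each run writes a JSON manifest of
parameters and input digests sufficient to replay it.
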