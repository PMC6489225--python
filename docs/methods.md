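# Methods

## Scope and data model

The package analyses a plant U-box (PUB) E3 ligase gene family along four
axes: (1) per-protein class assignment from domain architecture, (2) catalog
structure (chromosomal loci, tandem duplication, EST library counts), (3)
distance-based phylogenetics with bootstrap support, and (4) qPCR
stress-response calling by the ΔΔCt method. Proteins are represented as a
length plus an ordered set of located domain hits in a controlled vocabulary
(U_BOX, UFD2, ARM, HEAT, ARM_LIKE, CYCLOPHILIN, PKC, STK_N, WD40, TPR,
MIF4G, DJ1, OTHER). All genomic and residue coordinates are 1-based
inclusive, matching the way gene catalogs print loci.

## Classification rules

The U-box gates everything: no U-box hit means UNCLASSIFIED. Accessory
domains then decide the class by a fixed precedence — UFD2 (I), cyclophilin
(III), TPR+kinase (VIII), kinase (IV), TPR (VII), WD40 (VI), MIF4G (IX),
DJ-1 (X), ARM/HEAT (II), none (V). The precedence is a design choice: class
definitions in the literature describe single-accessory architectures and do
not state conflict handling, so rarer and more specific domains win, and
every fired rule is written to a rationale trace so a curator can audit any
assignment. ARM and HEAT are kept as distinct labels in parsing but act as
one evidence family for Class II.

Two genuinely open points were resolved as follows:

* **II-a/II-b boundary.** The sub-classes separate at "the first quarter of
  the protein length". We compare the **midpoint** of the most N-terminal
  U-box hit against `und_fraction × L` (default 0.25), boundary inclusive on
  the II-b side. The midpoint is preferred to the hit start because start
  coordinates are annotation-tool sensitive (envelope vs alignment bounds);
  both options are exposed (`ubox_point = midpoint | start`). The rule is
  monotone: moving the U-box toward the N-terminus can only flip II-a → II-b.
* **ARM-like regions.** Degenerate ARM-homologous regions (the former
  "GKL-box") do not qualify a protein for Class II and such proteins fall to
  Class V. `arm_like_counts_as_arm = true` restores the superseded grouping
  so both cladistic views can be compared on the same data.

A documented discrepancy: the barley catalog lists 8 II-b genes (19 + 8 = 27
Class II), while the running text of the source literature says "7 members"
for II-b. The packaged catalog and composition follow the table (8).

## Catalog analysis

Locus strings of the form `chrNH:start–end` are parsed accepting both hyphen
and en-dash and digit-grouping commas; blank EST cells read as zero. Tandem
detection sorts genes per chromosome by start and chains neighbours whose
gap (next start − previous end) is at most `tandem_max_gap_bp`. The default
of 100 kb is a design choice — no threshold is standard — chosen so that the
two recently duplicated barley pairs (HvPUB11/12, gap 62,584 bp and
HvPUB58/59, gap 53,809 bp) are detected while merely "clustered" pairs
several megabases apart are not. Output is invariant to input row order and
clusters are disjoint maximal chains.

A transcription note on the packaged barley catalog: the four EST-count
columns of the printed source run together in extracted text, so for rows
with fewer than four printed values the assignment of counts to the
(abiotic, biotic, generative, vegetative) categories is a left-to-right
best-effort reconstruction. Loci, gene IDs, names and class labels are
unambiguous. EST counts feed only descriptive summaries.

## Phylogenetics

Distances are uncorrected p-distances (mismatch proportion over comparable
columns), with gaps and X treated as missing under pairwise deletion
(default) or complete deletion. p-distance is bounded in [0,1] and may
violate the triangle inequality; neighbor joining does not require
metricity. A Poisson multiple-hit correction, d = −ln(1−p), is available by
flag; it diverges as p → 1 and such pairs are rejected with an error.

Neighbor joining follows Saitou–Nei: at each step join the pair minimising
Q(i,j) = (n−2)d(i,j) − r_i − r_j, with branch lengths
l_i = d(i,j)/2 + (r_i − r_j)/(2(n−2)). Numerical choices: a negative branch
length is clamped to zero and its deficit moved to the sister edge so the
pair's split distance d(i,j) is preserved; Q-ties are broken by the smallest
sorted pair of subtree leaf labels, which makes the algorithm deterministic
and invariant to input row order up to relabelling. The final three nodes
are resolved onto the unrooted trifurcation by the closed-form three-taxon
formulas. On additive inputs the algorithm provably recovers the generating
topology and path lengths; the test suite verifies this to 1e-9 on random
5–12-taxon trees and cross-checks topology against an independent NJ
implementation and the four-point condition on quartets.

Bootstrap support resamples alignment columns with replacement (seeded),
rebuilds the NJ tree per replicate, and annotates each internal edge of the
full-data tree with the percentage of replicates containing the same leaf
bipartition (the presentation used by mainstream tree viewers; a replicate
whose resampled columns leave a pair with no comparable site is skipped with
a warning and removed from the denominator). The default is 1000 replicates.

## Expression analysis

Technical replicates are averaged before anything else; biological
replicates are the unit of inference. Per (condition, biological replicate):
ΔCt = mean Cq(target) − mean Cq(reference); ΔΔCt(b) = ΔCt(treated, b) −
mean ΔCt(control); fold(b) = 2^(−ΔΔCt(b)). The reported point estimate is
2^(−mean ΔΔCt) (the geometric mean of replicate folds); the per-replicate
fold standard deviation is reported alongside. The construction makes the
analysis exactly invariant to any constant shift of all Cq values, and the
reference gene's own fold is identically 1.

Significance is a two-sided pooled-variance Student t-test on ΔCt values
across biological replicates — ΔCt is the approximately normal scale, folds
are log-normal. Welch's unequal-variance form is available by flag. Both
groups having zero variance is degenerate: equal means give p = 1, unequal
means give p = 0 with a warning. No multiple-testing correction is applied
by default (per-gene stars); Benjamini–Hochberg is provided.

Calls use inclusive thresholds: induced ("up") at fold ≥ 2.0, strong
suppression ("down") at fold ≤ 1/3, both gated on P < 0.05 unless
`require_significance` is off. Note a threshold-straddling effect inherent
to inclusive cutoffs: an effect planted exactly at the threshold (fold 2)
is called "up" only about half the time because the unbiased estimate falls
on either side; the direction is nonetheless recovered with significance in
essentially every run at the default noise level. Planted effects one
half-log2 beyond the threshold are called reliably (≥ 90–95% of seeds, as
verified by the Monte-Carlo tests).

## Synthetic-data generators

All generators take an explicit integer seed and are deterministic given it.

* **Architectures.** For each requested (class, subclass) a protein is
  emitted whose domain set satisfies exactly that class's rule and no
  higher-precedence rule. Lengths are uniform on 350–1100 aa (the range of
  typical PUB proteins); U-box hits are 60–76 aa. II-a proteins place the
  U-box midpoint in (0.35 L, 0.60 L) with ≥ 2 ARM repeats C-terminal of it;
  II-b in (0.04 L, 0.20 L). Class V proteins carry a non-qualifying ARM-like
  region with probability 0.5, exercising the re-classification rule. The
  default composition is the 67-gene barley family. Classification of the
  generated set recovers the composition exactly, for any seed — this
  round-trip is the basis of the classification acceptance checks, so those
  checks validate the *rules*, not real domain coordinates (which are not
  published for the barley family).
* **Alignments.** Sequences evolve down a known tree under a Jukes–Cantor
  style model on 20 states with uniform equilibrium frequencies: per edge,
  each site substitutes to a uniformly chosen different residue with
  probability 1 − exp(−rate × branch length). This is adequate ground truth
  for NJ-recovery testing; it is not a realistic protein model (no rate
  heterogeneity, no exchangeability structure, no indels), so passing tests
  say nothing about alignment quality on real sequences.
* **Cq tables.** Each gene gets a baseline Cq uniform on 18–30 cycles;
  treated wells are shifted down by the planted log2 fold; independent
  Gaussian noise (default sd 0.2 cycles) is added per technical replicate.
  Defaults are 3 biological × 3 technical replicates. (Source figure legends
  mention four technical replicates while the methods text says triplicate;
  the generator default is 3 with `n_tech` exposed.) With zero noise the
  ΔΔCt analysis recovers planted folds exactly.

## What the synthetic data does not emulate

Real domain-annotation noise (overlapping tools, partial hits, wrong
boundaries), genome-context effects on tandem detection, alignment errors,
amplification-efficiency differences between primer pairs (the ΔΔCt form
assumes ~100% efficiency), and inter-gene correlation in expression. Results
on synthetic data therefore demonstrate correctness of the implemented
rules and estimators under their stated assumptions, not field performance.

## Problem sizes used in the test and acceptance runs

The shipped checks use the 67-protein family for classification, 5–12-taxon
trees (100 random instances) for NJ equivalence, 44-column alignments with
100–200 bootstrap replicates for support behaviour, and 200–1000 simulated
Cq tables for recovery and type-I calibration. These sizes were chosen to
make every documented property measurable in seconds while leaving the
algorithms identical at any scale.

## Known limitations

The classifier trusts its input annotations; it performs no de novo domain
detection. UND (the U-box N-terminal domain of Class II-a) is defined only
negatively — as the region N-terminal of the U-box — and no UND detector is
attempted. The NJ implementation is O(n³) and intended for family-scale
trees (tens to a few hundred taxa), not genome-scale phylogenomics. The
expression module assumes exactly one treated condition per table; factorial
designs must be analysed per contrast.
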