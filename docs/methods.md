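# Methods

This note records the models implemented in `phylogd`, the parameters that
matter, and the design decisions taken where the underlying procedures are
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Simulator

### Topology

A tumour phylogeny with *n* clones is simulated by growing a full rooted
binary tree with *n* leaves (uniform recursive splits) and removing random
leaves until *n* nodes remain; since any *n*-node tree refines into a full
binary tree, every topology is reachable. A germline diploid root is then
attached above the surviving root, which becomes the MRCA; the
germline→MRCA edge is the trunk. Clone counts are drawn uniformly from
{8..16}, {12..24} and {22..30} for tumours sampled at 2–3, 4–7 and 8+
regions respectively, mirroring the ranges seen in large multi-region
non-small-cell lung cancer cohorts.

### Events and genotypes

Each locus in each clone carries (x, y, z): copies of allele A, copies of
allele B, and the number of A copies bearing the SNV (mutations sit on
allele A without loss of generality). Genotypes propagate top-down from the
germline (1, 1, 0), applying each edge's events in a uniformly random
order, so SNVs naturally fall before or after copy-number events and WGDs.
Semantics:

* SNV — z ← z + 1; skipped if allele A is absent. Infinite sites: every
  locus mutates at most once on the whole tree.
* GAIN of magnitude m — the chosen allele gains m copies. On allele A with
  a mutation present, the duplicated copies are mutant copies (z ← z + m):
  this keeps z integral, bounded by x, and preserves constant multiplicity
  whenever all copies are mutant. Magnitudes are 1 + Poisson(0.3).
* LOSS — one copy removed; if z = x beforehand, a mutant copy must go
  (z ← z − 1). A loss on a zero-copy allele is skipped and logged: LOH is
  irreversible.
* WGD — (x, y, z) ← (2x, 2y, 2z); alleles at zero stay at zero.

Copy-number events operate at chromosome-arm scale: the genome is 44
equally weighted autosomal arms, and SNV loci are points on arms that
inherit the arm's copy numbers. Arm-scale granularity keeps the common
allele-specific states ({2,1}, {3,1}, {4,1}, {3,2}, {4,2}, {1,0}, {2,0})
reachable with few events while leaving most of the genome copy-number
stable, as real exomes are.

WGD placement: a truncal WGD with probability 0.4; subclonal WGDs on
uniformly random distinct non-trunk edges, constrained so no lineage
accumulates more than two doublings — triple-doubled genomes are
biologically implausible and outside what major-copy-number ploidy logic
(0/1/2 states per region) can express.

### Bulk samples and reads

Each sample mixes 1 − μ normal diploid cells with μ tumour cells from
n̂ ~ U{3..8} distinct clones (clamped to the clone count) at flat Dirichlet
proportions. With f_ps = Σ u (x + y) per arm and ρ_s the mean of f over
arms, totals are Poisson((f/ρ)γ) and variant reads Binomial(t, ψ) with

ψ = μ Σuz / (μ Σu(x+y) + 2(1 − μ)).

The normal-cell term in ψ is deliberate: a bulk sample contains 1 − μ
diploid unmutated cells, which dilute both mutant and total allele counts;
the pure-tumour form Σuz / Σu(x+y) is recovered at μ = 1. Artefact loci
are appended with ψ computed from freshly drawn per-sample-independent
clone proportions, so they share no clone structure across regions.

### Default distributions

The empirical per-cohort distributions the design calls for are controlled
access, so parametric stand-ins are used, all overridable via `SimConfig`:
coverage γ ~ Normal(413, 60) truncated above 50 (multi-region WES runs at a
median depth near 413× with IQR 367–474); purity ~ U(0.2, 0.9); SNV burden
~ Negative-Binomial(mean 400, shape 4); truncal mutation fraction
~ U(0.40, 0.95); trunk gains/losses ~ Poisson(5) each and subclonal edges
~ Poisson(0.5) each; 10 artefact loci per tumour. Cohorts are
rejection-sampled (not truncated) against the three inclusion constraints
— purity > 0.20 in every sample, > 150 SNVs, truncal proportion < 0.90 —
to preserve distribution shape within the constraint region.

What the simulator does not model: read-level data (counts only),
selection/fitness (placement is neutral-random), sub-arm SCNA breakpoints,
sequencing artefact classes beyond clone-structure-free VAF noise, and sex
chromosomes. Passing tests on these simulations therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to alignment or calling artefacts in real data.

## PhyloCCF and clonality

mutCN = (VAF/μ)(μ·CN_t + 2(1 − μ)) — the standard purity/copy-number
transformation of the VAF; the exact form used is stated so tests can be
exact. Multiplicity is round(mutCN) clipped to [1, major CN]; PhyloCCF =
mutCN / multiplicity clipped to [0, 1.5]. Full ancestral-loss
reconstruction is out of scope; clipping the multiplicity at the regional
major copy number absorbs the common subclonal-loss cases and deviates
from a full reconstruction only at loci with subclonal losses of the
mutant allele.

Cluster-level values are member means with a 1,000-replicate nonparametric
bootstrap percentile CI over member mutations (the CI construction is not
prescribed anywhere; a bootstrap over mutations is the assumption-light
choice). A cluster is clonal in a region if a one-sided rank-sum test of
its members against the truncal members is non-significant at P = 0.05, or
if the 95% CIs overlap with the truncal lower bound floored at 0.9;
otherwise subclonal if its mean PhyloCCF exceeds 0.01 (a numerical floor
for "greater than zero"); otherwise absent. Tumour level: truncal iff
clonal everywhere; absent iff absent everywhere; else subclonal, with the
illusion-of-clonality flag when a tumour-level-subclonal cluster is clonal
in at least one region.

## Clustering and clone trees

Mutations are pre-grouped by exact presence pattern (present = ≥1 mutant
read). Groups under 5 mutations are not clustered; their members join the
nearest cluster by PhyloCCF distance afterwards. Within a group, clustering
runs on the multi-region PhyloCCF vectors with a diagonal-covariance
Gaussian mixture selected by BIC under the cap (10 components at ≥50
mutations, else ⌊n/5⌋). The mixture is a deterministic, testable stand-in
for a Dirichlet-process sampler; the pre-grouping and caps — the parts that
matter for multi-region scaling — are preserved exactly.

Clusters classified clonal in every region are folded into the truncal
cluster before tree building: multiplicity rounding scatters truncal
mutations (for example those doubled by a truncal WGD) into satellites
around PhyloCCF 1.1–1.2, and as separate tree nodes those satellites
violate the pigeonhole rule against the trunk.

Tree rules, both with an absolute tolerance of 0.1 PhyloCCF (no numeric
tolerance is prescribed; 0.1 is roughly twice the cluster-mean noise at
400× and behaves well in the recovery study):

* pigeonhole — in every region each parent's PhyloCCF ≥ the sum of its
  children's minus the tolerance;
* crossing — a cluster may be ancestral to another only if its PhyloCCF is
  at least the descendant's minus the tolerance in every region.

Enumeration inserts clusters in decreasing total-PhyloCCF order, trying
every placed node as a parent with pruning on both rules; it provably
yields every rule-satisfying parent map (each tree is generated along its
own insertion order) up to a cap of 1,000. The default tree maximises the
summed parent–child concordance Σ_edges min_regions(CCF_parent −
CCF_child), with a lexicographic tie-break. Spurious clusters are removed
first by genomic co-localisation (≥5 mutations with more than half on one
copy-number segment — a signature of SCNA-calling error), then, if no tree
exists, by the smallest-total-mutation subset whose removal restores
feasibility (exhaustive to 12 clusters, greedy beyond; the trunk is never
removable).

## WGD detection

Per region, WGD counts follow the major-allele rule (≥2 over ≥50% of the
genome → 1; ≥3 over ≥50% → 2; boundaries inclusive, length-weighted).
A cluster's doubled fraction in a region is the share of members with
mutCN > 1.5 among members in copy-number-stable segments — major CN exactly
2^n_WGD; segments above are amplification-contaminated and segments below
are post-WGD losses. Flags use 0.25 in the first region and 0.1 in further
regions once flagged anywhere (boundaries inclusive, chosen for
determinism).

Event assembly works under the per-region count capacity (no region is
assigned more events than its count):

1. The trunk's doubled regions are first explained away wherever a
   subclonal cluster is also flagged — a subclonal doubling doubles the
   truncal mutations of its sweep as a side effect — and only the
   unexplained regions form a truncal (pre-MRCA) event.
2. Flagged subclonal clusters on one ancestral path collapse onto the most
   derived flagged cluster (ancestors are doubled by their descendants'
   WGDs). An ancestor stays a distinct event only when the counts leave
   room for two events in the descendant's regions *and* the ancestor
   carries doubly doubled mutations (mutCN > 3): two doublings on one
   path quadruple a mutation, whereas contamination by a descendant's
   single doubling is bounded by mutCN 2. Clusters doubled in identical
   region sets share one event — except across an ancestral relationship
   already ruled nested — while different region sets give distinct,
   possibly parallel, events. Events consume capacity in order of
   eligible-mutation support.
3. If every region harbours a WGD and none is truncal yet, one tumour-wide
   truncal event is the most parsimonious explanation.
4. Remaining counts in regions unclaimed by any cluster event are grouped
   by parsimony level sets ("shared where possible"), with two extension
   rules: a level that — jointly with the cluster events — completes a
   partial truncal event to full coverage is that truncal WGD's missing
   regions (applied once, with capacity inside the truncal regions
   returned to the pool); and a level confined to regions where an
   existing cluster event had no eligible mutations extends that event
   rather than opening a new one.
5. At most two subclonal events are reported (estimates beyond two proved
   unreliable); excess events merge by largest region-set overlap, and a
   review flag marks any tumour with more than one subclonal event. The
   manual ploidy-re-review such tumours receive in practice is not
   automated.

Rules 1–4 go beyond the published prose, which delegates the algorithm to
an unpublished implementation; each was adopted to fix a concrete,
traceable misattribution mode (ancestral-contamination false events,
capacity starvation of genuine parallel events, spurious subclonal
completions of partially observed truncal WGDs) observed on simulated
tumours.

## Benchmark

The validation cohort is 500 tumours under the default simulator with one
to three subclonal WGD events injected on random distinct non-trunk edges
(a multiple-WGD detection benchmark needs tumours that actually carry
them). A truth event is detectable in a region when its CCF exceeds 0.75
there, or when a set of pairwise parallel events containing it sums above
0.75 with every member holding at least 0.25 of the region's cancer cells
(the floor excludes negligible riders on someone else's sweep; 0.25 is the
complement of the detectability threshold). The detector receives, per the
validation protocol, the per-region ground-truth-detectable counts
(uncapped), the true cluster identities, read-derived mutation copy
numbers (true purity, rounded bulk copy numbers) and per-mutation major
copy-number states. The baselines consume per-region ploidy-state counts —
what the major-CN rule measures — since that is the only input they are
defined on: `nejm` calls subclonal WGD when some but not all regions carry
one (it can never call two events); `nejm2` calls as many subclonal events
as there are distinct non-minimum count levels. The positive class is
"≥ 2 detectable subclonal events"; sensitivity and specificity are
standard confusion-matrix ratios over tumours.

## Recovery study

The clustering/tree validation simulates tumours at 4–5 regions, 400×
coverage, purity U(0.5, 0.9), 5–9 clones, burden ~NB(600) with truncal
fraction U(0.35, 0.75), no WGDs and no artefacts, rejecting tumours until
every pair of mutation-bearing clones is separated by ≥ 0.2 PhyloCCF in
some region and every cluster has ≥ 10 mutations. The purity floor keeps a
0.2 gap above the noise level (at purity 0.2 and 400× it is ~2σ and
unrecoverable in principle); WGDs are excluded because multiplicity
scatter is the WGD detector's problem, validated separately. Scores:
adjusted Rand index between true and inferred assignments over mutations
retained by both, and whether the true tree (restricted to
mutation-bearing clones) appears among the enumerated trees after
contracting chains of inferred clusters mapped to the same clone —
presence-pattern pre-grouping legitimately splits one subclone across
groups, which is a relabelling, not an error.

## Numerical conventions

Half-even rounding for the truncal SNV count and bulk copy numbers; a
single seeded `numpy` generator threaded through every stochastic step
(fixed seed ⇒ byte-identical cohorts); PhyloCCF clipped to [0, 1.5] and
leaf scores to [0, 1] before maxima; 1-based inclusive genomic coordinates
in all tables; ties in cluster/tree orderings broken lexicographically by
id.

## Known limitations

Sensitivity of the WGD benchmark depends on subclonal cluster sizes, which
under uniform SNV assignment are smaller than empirical per-clone burdens;
doubled-fraction flags are correspondingly noisier than they would be on
cohort-matched simulations. The loss correction in PhyloCCF is the clipped
approximation described above. Tree enumeration caps at 1,000 candidates
and flags truncation. Sex chromosomes, indel-specific VAF corrections and
signature deconvolution are out of scope (the SBS4 classifier consumes
externally estimated weights and counts).
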