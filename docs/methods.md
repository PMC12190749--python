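# Methods

This note records the models, the numerical choices, and the design
decisions behind `markdyn`, and what the synthetic study does and does
not emulate.

## Coordinates, gene models, annotation

All coordinates are 0-based half-open (BED convention); the GTF-subset
reader converts from 1-based inclusive on read. The TSS of a `+` gene is
`tx_start`; of a `−` gene, `tx_end`. Oriented distance of a genomic
position m is `m − TSS` on `+` and `TSS − m` on `−` (upstream negative).
The promoter window is the oriented half-open interval [−1000, +500) and
the enhancer window [−10000, −1000): half-openness makes the two windows
partition at −1000 without double counting. A peak's class is decided by
its midpoint, `floor((start+end)/2)`, so the four classes (promoter,
enhancer, gene body, distal) are mutually exclusive by construction;
full-interval overlap is available as a switch (`mode="overlap"`), in
which case the promoter invariant on `tss_distance` no longer binds —
the reported distance stays midpoint-based. Precedence across genes is
promoter > enhancer > gene body > distal, with ties broken by the
smallest |TSS distance| and then gene id. A peak overlapping two genes'
promoters is therefore assigned to the single nearest TSS; this is a
known divergence risk against tools that report multiple assignments.

Because class definitions are purely oriented, reflecting all
coordinates and flipping strands leaves every assignment unchanged
(exactly so when peak start+end is even; an odd sum moves the floored
midpoint by one base under reflection).

On the tightly packed toy genome (gene slots ~2.3 kb), a −10 kb enhancer
window always reaches several neighbouring genes, so peaks at gene ends
legitimately classify as a neighbour's enhancer under the precedence
rule and the distal class is essentially empty. This is a property of
the miniature genome, not of the annotation logic.

## Consensus peaks

Replicate peaks are filtered on the upstream caller's q-value with a
strict inequality, −log10(q) > 6 (q < 1e-6), threshold configurable.
"Present in at least two biological replicates" is operationalised as
transitive overlap-component voting: pooled peaks are swept in
coordinate order, a maximal run of transitively overlapping peaks forms
a component, and a component whose peaks come from ≥ `min_support`
distinct replicates emits one consensus peak spanning the component
union. Union coordinates retain every supported base and make the
result invariant to replicate order; a single replicate contributing
several peaks counts as support 1. The implementation is checked against
an O(n²) overlap-graph oracle on random instances. Cross-condition
quantitation uses the merged union of all conditions' consensus
intervals, each tagged with its contributing conditions.

## Quantitation and normalization

Fragment membership in a peak is decided by the fragment midpoint
(unambiguous single-peak assignment over the disjoint merged peaks);
library size is the sample's total fragment count including fragments
outside peaks. Between-sample scale factors follow the trimmed mean of
M-values computed on non-overlapping 10 kb genome bins: reference =
sample whose log library size is closest to the mean; per-bin M (log2
depth-scaled ratio) and A (mean log2 abundance) over bins nonzero in
both samples; two-sided trims of 30% (M) and 5% (A), read as the
standard per-tail trims of the TMM recipe; inverse-asymptotic-variance
weights; factors rescaled to geometric mean 1. Bins serve normalization
only; testing is at peak level. Log abundances use CPM with a 0.5 prior
throughout (configurable).

## Differential binding

Counts are modelled as NB(μ, φ) with `Var = μ + φμ²` and offsets
`log(library_size × norm_factor)`. Per peak, the log-likelihood is
maximized under a single-mean null and a per-group alternative (the
score in the log-mean is strictly decreasing, so damped Newton converges
monotonically; all-zero peaks are flagged with p = 1 and lfc = 0), and
`2Δℓ` is referred to χ²(1); a k-group omnibus variant uses χ²(k−1).
This is a deliberate method variant: the quasi-likelihood empirical-
Bayes framework the field often uses is replaced by a plain NB LRT with
explicit dispersion handling, which is desk-scale implementable and
directly testable for calibration.

Dispersion: `estimate_dispersion` is the method-of-moments recipe —
within groups, `φ = (s² − m)/m²` on depth-normalized counts, averaged
across groups, floored at 1e-4, then shrunk toward the 10%-trimmed mean
across peaks with weight 0.3 on that common value. At minimal
replication (≤ 3 per group) per-peak moment estimates are far too noisy
for the χ² far tail, so the high-level `differential_binding` defaults
to a common dispersion estimated by Cox–Reid adjusted profile likelihood
(group means profiled out per peak; the adjustment `−½ log Σ μ/(1+φμ)`
per group removes the downward small-sample bias of the plain profile
MLE). With thousands of peaks this estimate is essentially exact under
the simulation's constant-dispersion condition, and the global-null
type-I error at α = 0.05 lands at 0.050 with no BH rejections at 1% in
the packaged benchmarks. Per-peak shrunk dispersions remain available
(`dispersion="peak"`), and arrays can be passed directly.

Multi-condition designs are analysed as ordered pairwise contrasts
(union of FDR-significant peaks), with the omnibus LRT as a switch; the
BH step-up is implemented directly and cross-checked against an
exhaustive-definition oracle and statsmodels.

PCA of quantified peaks: log2 CPM (prior 0.5), peaks row-centered, SVD;
sample scores are `V·S` and variance-explained fractions `s²/Σs²`.

## Binding–expression correlation

The partition operates on differentially bound promoter peaks of
protein-coding genes — the same restriction the upstream analysis
pattern uses — because at 3–4 timepoints the Pearson null distribution
is heavy (at n = 4 the null r is uniform on [−1, 1]), and without the
DB filter chance correlations of static genes would dominate the
partition. Binding per timepoint is replicate-averaged normalized
log2 CPM; r is computed across shared timepoint labels (≥ 3 required),
classified strictly at +0.8/−0.8; constant vectors have undefined r and
are flagged neutral. The per-gene representative is the max-|r| peak,
ties broken toward the lower genomic coordinate; both the pair-level and
gene-level tables are returned.

## Co-occupancy ledger, colocalization, gene sets

Promoter presence for the ledger uses full-interval overlap (≥ 1 bp of a
peak with the promoter window) — mark presence is a detection question,
unlike the mutually exclusive midpoint annotation; the switch is
exposed. Combination fractions condition on the anchor mark and
partition to 1 per timepoint (undefined when no anchor-positive genes);
transition flows count genes per ordered pair of consecutive combination
states and conserve the gene total per transition. Colocalization is the
fraction of query peaks with ≥ 1 bp overlap to any reference peak,
overall and per feature class. Gene-set over-representation is the
one-sided hypergeometric upper tail on user-supplied GMT collections,
BH-adjusted within each collection (one family per file).

## Motif enrichment

PWMs (MEME minimal format; pseudocount 1e-3 with renormalization) are
scored as natural-log odds against a background distribution, default
the pooled nucleotide frequencies of the control sequences — the
control-matched background absorbs GC composition, the confounder of
interest when marked regions are GC-rich. Scores are discretized at
1e-3; the exact distribution of a random background w-mer is obtained by
per-column convolution, and the scan threshold is the smallest
achievable word score whose tail probability is ≤ the per-position
p-value (default 1e-4, the conventional scanning magnitude; thresholds
are restricted to the distribution's support so degenerate all-ambiguous
windows, which score 0, cannot slip under a zero-mass grid point). Both
strands are scanned; N contributes zero log-odds. A region is a hit when
it contains ≥ 1 position at or above threshold; enrichment is the
one-sided Fisher exact test on the 2×2 region-hit table with BH across
motifs and Haldane 0.5 odds-ratio correction at zero cells. This
fixed-threshold + Fisher design is a self-contained, exactly testable
stand-in for ranked-enrichment tools; it is not a claimed reproduction
of any external tool's defaults. Controls are all regions of the same
feature class with zero-bp overlap to the mark's peaks; an empty control
set is an error advising a larger region universe.

## Tissue comparison

The occupancy matrix is boolean gene × tissue promoter presence
(protein-coding universe). Phi is the 2×2 contingency formula; constant
columns give undefined phi (warning; clustering refuses rather than
imputes). The clustering distance is, literally, the Euclidean distance
between tissue rows of the phi matrix, with `1 − φ` exposed as the
alternative switch; linkage is Ward's minimum variance with tissues
pre-sorted lexicographically so ties are deterministic. UpSet counts are
exclusive membership patterns over genes with ≥ 1 occupancy.

## The synthetic study

One integer seed fans out through `numpy.random.SeedSequence.spawn` to
fixed-order per-component generators (genome, occupancy, peaks, counts,
expression, motifs, tissues, fragments), so every artifact regenerates
byte-identically and components can be regenerated independently.
Defaults: 2 × 500 kb chromosomes, 400 genes (10% non-coding) on a fixed
slot grid with both strands, promoter GC 0.6 vs background 0.4; four
developmental ages, three marks, three replicates; endpoint jitter
sd 20 bp, dropout 0.1, singleton noise peaks at 5% of true loci placed
in a reserved per-chromosome spacer tail so they can never chain into
2-of-n support; NB dispersion 0.1, base mean 100 fragments per peak,
library depth lognormal (sd 0.15) and independent of signal — the
fraction of fragments in peaks rises as marks accumulate (capped at 0.5)
while flat loci keep constant expected CPM, as in a sequencing
experiment where depth is chosen, not earned. Anchor-mark occupancy
follows a monotone onset model with per-age rates (0.55→0.68); co-marks
are conditionally present given the anchor at rates rising 0.62→0.92
(so the all-marks fraction climbs through development); 30% of marked
genes also carry an enhancer and/or gene-body locus.

Planted truth: 25%/15%/60% of protein-coding genes are
positive/negative/null correlation classes. Correlation-class genes have
always-on promoters whose binding ramps geometrically 6-fold across the
ages, and expression log-linear in that ramp (slope +1 or −1) with
Gaussian log-scale noise sd 0.15; null genes have flat promoter
abundance and independent expression. The generic 4-fold differential
binding (20% prevalence, random direction) is planted at enhancer and
gene-body loci only: a promoter trajectory that changes while expression
is independent would acquire chance |r| > 0.8 at four timepoints about
20% of the time and blur the planted partition — at small n the planted
classes must be separable for "recovery" to be meaningful. Onset genes
(promoters gained after the first age) do enter the differential set
with real trajectories and contribute the residual, irreducible
contamination of the partition. Footprints (1–3 per promoter, 15–30 bp)
carry a sharp GC-box PWM instance at rate 0.4 in marked promoters vs
0.05 in unmarked controls; instances are sampled from the PWM and
written into the genome. The tissue matrix has a shared core (25% of
genes occupied everywhere) and two blocks of three tissues (30% of genes
each; in/out rates 0.9/0.05; 2% noise flips).

What the generator does not emulate: read-level data and alignment
artifacts, realistic assay background and peak-shape variation,
copy-number or mappability structure, isoform-aware annotation,
expression measured on a denser grid than binding, correlated
dispersions across peaks, and promoter trajectories that change
independently of expression (see above). Passing tests therefore show
the machinery is correct and calibrated under the stated generative
model, not that biological effect sizes of this magnitude exist in any
real tissue.

## Problem sizes and determinism

The packaged benchmarks use 2000 peaks at 3 vs 3 for calibration (50
seeded runs) and sensitivity, five replicate default studies for the
correlation partition, 20 seeded runs for motif recovery and tissue
clustering, and 40 null runs for motif calibration — sizes chosen so the
whole suite exercises every claim in a few minutes on one core. The
pipeline (`markdyn run`) executes nine stages (consensus, annotate,
quantify, diffbind, correlate, cooccupancy, colocalize, motifs,
tissues), writes TSV/JSON only, and ends with a manifest of sha256
digests; all stages are deterministic functions of the seeded inputs, so
a rerun — including a resume after deleting any stage directory —
rewrites byte-identical outputs.

## Known limitations

Pearson partitioning at 3–4 timepoints is intrinsically noisy and only
meaningful downstream of a variance filter such as the DB restriction;
the NB LRT's χ² reference relies on moderate counts (far-tail
calibration was verified at base mean ~100 and would degrade for very
shallow peaks); TMM on 10 kb bins assumes most bins are not
differential; the consensus union can chain distinct nearby loci through
a bridging replicate peak; and single nearest-TSS assignment undercounts
genes at bidirectional promoters.
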