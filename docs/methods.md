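# Methods

This note documents the models, conventions and design choices behind
`fmnet`, in the spirit of the methods documentation of statsmodels or
msprime: what each stage computes, which knobs matter, and what the
synthetic benchmark does and does not demonstrate.

## Abundance preprocessing

Counts are depth-normalized by **rarefaction**: a single draw without
replacement (multivariate hypergeometric) to a common depth, default the
least-rich sample's total. Subsampling (rather than scaling) preserves
integer counts, so observed-taxa richness remains meaningful; the seed is an
explicit argument and is recorded by the pipeline. The expected
post-rarefaction composition equals the original composition (hypergeometric
mean), which the tests verify over 1000 replicate draws.

Relative tables are **subcompositions** after the mean-abundance filter:
rows may sum to less than 1, never more. The filter bound is inclusive
(mean ≥ threshold, default 0.5%), ties kept.

**Shannon diversity** uses the natural log. **Yue & Clayton θ** is
1 − Σab/(Σa² + Σb² − Σab); **Bray-Curtis** is Σ|a−b|/Σ(a+b) (scipy). Both
lie in [0, 1] on relative inputs and are property-tested for symmetry, zero
diagonal and range. **PCoA** is classical scaling (double-centre −D²/2,
eigendecompose); only positive-eigenvalue axes are returned, scaled by
√eigenvalue, and each axis is sign-fixed so its largest-magnitude coordinate
is positive — coordinates are then reproducible across runs and platforms up
to that convention.

## NMR preprocessing

The enforced stage order is **baseline → align → bucket → total integral →
PQN**, recorded in the bucket matrix's provenance list.

* *Rolling-ball baseline*: grey-scale opening (erosion then dilation, flat
  window of 2·radius+1 points) followed by a moving-average smooth of the
  same width; the default radius of 50 grid points is wide relative to peak
  widths at typical digital resolutions, so peak areas are preserved to ~1%
  while ramps and broad humps are removed.
* *Alignment*: per-spectrum integer-grid shift (bounded by `max_shift_ppm`)
  maximizing Pearson correlation with the cohort median spectrum;
  correlation is scale-free, so intensity differences do not bias the lag.
* *Bucketing*: trapezoidal integration over half-open [lo, lo+0.02) ppm
  windows aligned to multiples of the width. Default exclusion windows are
  the conventional ones — residual water 4.50–5.20 ppm, the reference/TSP
  region below 0.50 ppm, and the downfield extreme above 9.00 ppm. These
  bounds are configuration, not assertions: the exact bucket count of a real
  study depends on its (usually unreported) exclusion limits.
* *Total-integral normalization* scales each row to sum 1000.
* *PQN*: reference = per-bucket median spectrum (all samples by default;
  group-median optional); per-sample quotient = median of bucket-wise ratios
  to the reference over buckets where the reference is positive; the row is
  divided by the quotient.

A point worth making explicit: total-integral normalization removes a pure
per-sample dilution *exactly*, so after it the PQN quotients are ≈ 1 and
carry no dilution information. PQN recovers planted dilution factors only
when applied to the raw matrix (`enforce_total=False`), which is how the
dilution-recovery benchmark runs. On real spectra, where composition changes
make total-integral normalization imperfect, running PQN after it (the
default order) is the standard and correct practice.

## Synthetic cohorts

The generator emulates a faecal case-control cohort (default 35 + 14
samples) with coupled 16S, NMR and clinical outputs and known ground truth.

**Latent layer.** Each of `n_blocks` functional communities has a
standard-normal per-sample factor; factors share a weak common component
(`block_factor_corr`, default 0.5) representing shared host physiology. A
regular feature in block *b* has latent
z = √ρ·g_b + √(1−ρ)·ε with ρ = `block_corr`. A keystone bridge loads
equally on two factors: z = √ρ·(g_b1 + g_b2)/√(2(1+c)) + √(1−ρ)·ε.

The factor coupling is not cosmetic. If blocks were independent, a bridge
could correlate with either side at most 1/√2 ≈ 0.707 (positive
semi-definiteness of the correlation matrix), so a strict |r| > 0.7 edge
threshold would sit exactly on the theoretical ceiling and no keystone could
reliably acquire edges to both communities. With c = 0.5 the bridge-member
latent correlation is ρ·√((1+c)/2) ≈ 0.82 while cross-block member pairs
stay near ρ·c ≈ 0.5·ρ — far below threshold after observation noise — so
bridges are detectable and blocks remain separable.

**Taxa.** Structured taxa receive log-normal baseline weights summing to
(1 − `background_share`) of community mass and are perturbed per sample by
exp(latent_scale·z); an unstructured background of `n_background_taxa` rare,
overdispersed taxa carries the remaining mass. Counts are multinomial at
library sizes drawn from `depth_range` (default 3101–30000 reads). The
background is essential: the retained ≥ 0.5% features of a real study are a
small subcomposition of a ~2000-OTU community, and without a dominant
unstructured remainder the softmax closure forces near-perfect spurious
anti-correlation between any two planted blocks (each block's relative
abundances are then functions of the same factor contrast), making planted
structure unrecoverable by *any* correlation threshold. Keystones are
planted as metabolites for the analogous reason: the lognormal/multinomial
channel attenuates taxon-side correlations by enough (~10%) to push a
borderline 0.7 bridge under threshold, and a taxon can also drop out at the
abundance filter.

**Metabolites.** Structured buckets are linear images 10 + z + noise;
`n_background_buckets` stable buckets (5% multiplicative noise) model the
unannotated bulk of the spectrum. Their steadiness matters twice: it keeps
the PQN median ratio anchored on pure dilution rather than on block signal,
and it prevents the background from forming a constant-over-total clique
after normalization. All buckets are scaled by per-sample dilution factors
drawn uniformly from `dilution_range`.

**Labels.** HE ~ Bernoulli(logistic(intercept + Σ β_f·z_f)) with the
intercept defaulting to logit(8/46), the emulated cohort's HE prevalence.
The clinical table adds a severity score tracking the first block factor
(r = 0.8 on the latent scale) and independent nuisance parameters.

**Randomness.** One master seed; independent child streams (numpy
SeedSequence) for structure, counts, NMR, clinical and labels, so adding an
output never perturbs the others. All outputs are byte-identical per seed.

## Network stage

Pearson correlations use n−2-df t-distribution p-values; constant features
give NaN rows flagged with a warning and never create edges. Edges require
strictly |r| > 0.7. Betweenness is the unnormalized Brandes value on the
unweighted thresholded graph (a path centre A–B–C scores 1; a 4-leaf star
centre scores 6), matching the magnitude convention of typical
network-visualization tools; a weighted variant is deliberately not the
default. Louvain runs on |r| edge weights — standard modularity is undefined
for negative weights, and a competitive edge is still evidence of
association — with resolution 1 and the best of 20 seeded restarts;
community labels are relabelled contiguously, largest community first.
Summary percentages print to 1 decimal, ratios to 2, density/modularity to
3 (all configurable). Keystone ties break toward higher mean relative
abundance, then lexical id; keystones are reported jointly and per pool
(taxa / metabolites), since either ranking may be wanted.

Cluster validation embeds features as their correlation profiles: silhouette
on the 1 − r distance, Calinski-Harabasz on the profile vectors.

## Cross-correlation and group tests

All feature × parameter tests are pooled into a single BH family (the most
conservative reading of a matrix-wide FDR star), with pairwise-complete
handling of missing clinical values and q ≤ α stars (inclusive). BH is the
5-line step-up computed directly and cross-checked in the tests against a
brute-force application of its definition. Mann-Whitney U uses scipy's
`method="auto"`: the exact null for small tie-free samples, the normal
approximation otherwise.

## Consensus HE risk ranking

Logistic β is fit **per feature** by default: a per-row β → OR = 2^β
transform is only coherent univariately, and the published risk tables mix
features from different habitats that were never in one design matrix. A
joint fit is available (`joint_logistic=True`). The base-2 odds-ratio
convention is kept exactly as the source pipeline defined it; log2(OR)
recovers β to 1e-12.

Randomized lasso is stability selection: B = 200 subsamples of half the
data, per-feature penalty randomization (columns scaled by w ∈ {0.5, 1},
equivalent to per-coefficient penalty rescaling), L1 logistic fits, score =
selection frequency. The L1 strength is set to the largest C whose full-data
fit keeps at most ~√(m/2) features. A cross-validated strength was tried and
rejected: under a null it selects a weak penalty, every coefficient is
always non-zero, and all scores saturate at 1 — the selection frequency only
ranks features when the base fit is sparse. With the sparsity rule, null
features score ≈ 0.08 on average and a planted β = +2 feature is top-ranked
in ~100% of replicates.

Elastic net uses logistic loss with mixing 0.5 and cross-validated strength;
SGD uses logistic loss, L2 penalty, 1000 epochs, seed-controlled shuffling.
The consensus sign is the sign shared by all non-zero signed coefficients
(logistic, elastic net, SGD), else 0; the randomized-lasso score is
magnitude-only and does not vote.

## Benchmark conditions and what they show

The recovery studies run the full pipeline on 50 seeded cohorts with two
blocks at block_corr = 0.95, noise 0.05, 20 taxa + 13 metabolites + one
keystone (≈ the size of the real faecal networks). Observed rates: FMC
detection ARI ≥ 0.9 in ~100% of seeds (ARI computed over non-keystone
structured features — a bridge has no unique true block); the keystone in
the top-5 betweenness in ~92%; PQN-estimated dilutions correlate ≥ 0.995
with truth; the planted HE feature tops the randomized-lasso ranking in
~100% of 50 replicates (n = 200 design) and in ~95% through the full cohort
generator at n = 100 and moderate collinearity. The end-to-end HE benchmark
uses block_corr = 0.5 deliberately: at 0.9+, near-collinear block-mates of
the causal feature are statistically exchangeable with it at these sample
sizes, and single-feature attribution is ill-posed for any method.

What passing these benchmarks does **not** show: the generator's blocks are
linear-Gaussian underneath, its background is exchangeable, and its
metabolites respond linearly — real data have heavier tails, structural
zeros, batch effects and nonlinear couplings. The benchmarks validate the
machinery (thresholding, community detection, centrality, normalization,
selection), not the biological truth of any particular network.

## Numerical conventions and limitations

* Writers use a fixed float format (`%.10g`); reruns with one seed are
  byte-identical, which the pipeline manifest (seeds + config hash) makes
  checkable.
* Degenerate inputs fail loudly: all-zero samples, shallow samples at
  rarefaction, single-class labels, edgeless networks at community
  detection, constant features (dropped or NaN-flagged with warnings).
* Good's coverage is not implemented (its definition in the emulated
  workflow is not stated); the exact published bucket count (418) is treated
  as configuration-dependent and never asserted.
* Signed-network modularity, graph layout, OTU picking, taxonomy assignment
  and metagenome prediction are out of scope; externally derived gene
  (KEGG-orthologue) features enter simply as additional feature columns.
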