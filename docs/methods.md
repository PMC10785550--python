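# Methods

This note documents the statistical model, the estimation choices, the
synthetic-data generator, and the numerical decisions behind `nichede`,
at the level of detail a user needs to judge what results mean and where
they stop generalizing.

## Model and assumptions

The object of inference is the set of coefficients β^g_{σ,i,n}: the
log-scale change of gene g's expression *within index cell type i* per
unit kernel-smoothed enrichment of *niche cell type n* at bandwidth σ.
The model assumes

- counts are negative binomial given the cell-type composition and the
  effective niche, with a per-gene dispersion;
- the mean depends on the niche only through the linear predictor
  Σ_n N_{σ,·,n} β^g — no interactions between niche types, no spatial
  random effects;
- for spot data, an external deconvolution supplies per-spot proportions
  that are treated as known. Deconvolution error propagates directly
  into the effective niche, which is the model's covariate; results are
  only as good as the composition estimates.

The spot-level model is the single-cell model aggregated within spots
under a first-order (log(1+x) ≈ x) approximation, which is accurate when
per-cell niche effects are small relative to baseline expression. The
coefficients retain their single-cell interpretation; on one-cell spots
the two code paths produce bit-identical designs (verified to 1e-8 in
the test suite).

## Estimation pipeline

Stages, in order: cap each gene at its 99.5th-percentile count
(linear-interpolation quantile, floored to an integer); threshold
deconvolution proportions below 0.05 (per-type overrides available) and
renormalize; estimate cells per spot N̂_s = L_s / Σ_t π_{s,t} L_t from
the observed library size and reference mean libraries; form expected
expression μ_{s,g} = Σ_t n_{s,t} A_{t,g} and expression-source
proportions p_{s,t,g} = n_{s,t} A_{t,g} / μ_{s,g} (entries < 0.05 zeroed
and *not* renormalized); compute the effective niche per bandwidth
(self-inclusive, Euclidean distances) and standardize each column to
mean 0, sd 1 (zero-variance columns are excluded and their coefficients
fixed at 0); fit each gene.

A triple (g, i, n) enters the regression only if (1) gene g's total
capped count exceeds C (strictly; default 100 at fixture scale — the
appropriate C grows with dataset size and is exposed as
`filters.min_total_count`), (2) strictly more than M = 30 observations
both contain type i and have type n in their raw effective niche, and
(3) g lies in the top 80% of reference expression for type i (at or
above the 20th percentile of A_{i,·}, inclusive). Collinear design
columns are detected by pivoted QR and dropped (reported as untested),
not regularized.

### Fitting and standard errors

Coefficients are estimated by Poisson IRLS with offset log μ (max 25
iterations, relative tolerance 1e-8; |β̂| > 20 is treated as separation
and the gene is excluded). Holding β̂ fixed, the NB size parameter is
estimated by bounded 1-D likelihood optimization of log size over
[1e-4, 1e4]; "overdispersion 1" corresponds to size 1 (variance
μ + μ²). Because β̂ is the *Poisson* MLE, its asymptotic covariance
under NB truth is the sandwich A⁻¹BA⁻¹ with A the Poisson information
and B built from the estimated NB variance μ + μ²/size. Simulation shows
the plain NB Fisher information at the Poisson estimate is badly
anti-conservative (null z-sd ≈ 1.5 under a wide μ range) while the
sandwich calibrates (≈ 0.97); an optional full NB refit
(`fit.refit_nb`) uses the NB information at the NB optimum instead,
with nearly identical calibration and roughly twice the cost. Observed
null z-statistics in the full pipeline have sd ≈ 0.95 — slightly
conservative, mainly because the offset is built from observed library
sizes whose noise the model does not represent. One-sided p-values are
normal Wald tails, treating GLM z-scores as asymptotically normal.

### Combination and FDR control

Within a gene, one-sided p-values are combined by Brown's method: the
statistic −2Σ log p is referred to a scaled chi-square with moments
matched using the Kost–McDermott cubic for the covariance of −2 log p
between correlated one-sided normal statistics (verified against Monte
Carlo at ρ = 0.5 to within 2 MC standard errors; accurate for signed ρ).
The statistic correlations are read off the per-gene sandwich
covariance. Untested hypotheses simply reduce k. Under the heavy
collinearity induced by strongly colocalizing (or contamination-
smoothed) compositions, the scaled-chi-square shape makes the combined
p-values mildly conservative in the mid-range; tails stay accurate.

Across bandwidths, p-values are pooled by the Cauchy combination test
with weights w_j = L_j / Σ_k L_k taken literally from the per-gene
regression log-likelihoods. For counts models the L_j are large,
negative, and similar across bandwidths, so these weights are close to
uniform — a property we found essential: any strongly adaptive variant
(softmax, max-shifted ratios) effectively selects the best-fitting
bandwidth's p-value and inflates the pooled null tail (measured ≈ 1.7×
nominal at p < 1e-3, null interaction FDP 0.25 instead of ≤ 0.1).
Mixed-sign log-likelihood vectors (not observed in practice) fall back
to exactly uniform weights. P-values are clipped to
[1e-300, 1 − 1e-16] before the tangent transform.

The two one-sided families (β > 0, β ≤ 0 and the reverse) run as two
parallel hierarchies at level α each: BH on pooled gene-level p-values;
within surviving genes, BH across cell types; within surviving (g, i),
BH across niche types. The reported bound is α(D + F)/(D + 1) where D
counts all BH rejections and F every parent node at which a BH family
was actually run (the root counts once per direction).

### Multi-sample analysis

Samples are put on a common scale by rescaling query coordinates to
equal physical pixel size, multiplying the query niche by
(N_r q²)/(N_q r²) (sequencing-depth and spot-area correction), and
adding per-sample intercept columns to every gene's design.

### Niche-LR

For each ligand, the bandwidth maximizing its own niche-DE regression
log-likelihood is selected (ties to the smaller bandwidth; ligands
absent from the fitted gene set fall back to the bandwidth with the
highest total log-likelihood). Its top-K prior targets among measured
genes give weights W_j ∝ A_{l,g_j}; the activity score is
T = Σ W_j B_j / √(Σ W_j²) with untested targets contributing B = 0
(conservative; `lr.drop_untested` renormalizes instead). Candidates
need T > max(1.64, T_(M)); when fewer than M ligands are scored only
the 1.64 floor applies. Confirmation regresses observed ligand
(receptor) counts on the composition matrix plus an intercept by
Poisson IRLS — the intercept is warm-started at log ȳ, without which
the exponential model diverges on high-count ligands — restricted to
observations with the index (niche) type in their effective niche at
σ*, with one-sided tests and BH across candidates. At single-cell
resolution the regressions are replaced by top-α% expression-rank
filters (boundary rank inclusive). Defaults (K, M, α) = (50, 50, 0.05);
a Visium-style profile (25, 50, 0.5) is selectable.

## Synthetic data generator

The generator emulates a deconvolved spot (or labelled single-cell)
sample: log-normal reference profiles with per-type marker blocks
(markers guaranteed ≥ 5× every other type's mean), mean cell library
1000 counts spread over the gene panel, compositions drawn by softmax
over sums of spatial Gaussian bumps (three per type, scale a quarter of
the field) plus logit noise — so types form coherent, partially
overlapping territories with non-trivial colocalization — coordinates on
a unit grid with ±0.3 jitter, about 4 cells per spot (Poisson + 1), and
independent NB counts with size 1. Everything derives deterministically
from one root seed; multi-replicate benchmarks spawn child seeds via
`numpy.random.SeedSequence`.

What it does *not* emulate: deconvolution error (compositions are
exact), segmentation error, spatial covariance of expression beyond
composition, platform-specific capture biases, zero inflation, or
realistic gene-gene correlation. Passing the benchmarks therefore
demonstrates the statistical machinery is correct under its own model,
not that real-data compositions estimated by any particular
deconvolution method are adequate.

Benchmark-specific notes:

- **Spike-ins** multiply μ by exp(p·β·N_std) for the planted genes. The
  planted set is kept a minor fraction of the panel (200 of 1000–5000
  genes) as in the original validation design; because cells-per-spot is
  estimated from observed library sizes, planting effects on a large
  share of the transcriptome is partially absorbed into the offset and
  attenuates β̂ (measured: ≈ 0 recovered when all genes are planted,
  ≈ 0.43–0.55 of 0.5 at a 4% share).
- **Bleeding** follows the destination-normalized kernel mixture with
  α = 0.25 and τ at the 1st pairwise-distance percentile; it conserves
  each gene's total expected count to machine precision. For
  contaminated runs the composition handed to the pipeline is obtained
  by applying the same bleeding operator to per-type transcript mass
  n_{s,t}L_t — what an idealized marker-based deconvolution of the
  contaminated counts would report, and the mechanism by which spot
  swapping is absorbed upstream of the regression. Without this
  re-deconvolution step the null FDP under bleeding rises to ≈ 0.6.
- **Bootstrap** enlargement resamples (niche row, expected-expression
  row) pairs with replacement and redraws NB counts.
- **Pseudo-spots** aggregate counts and cell counts on square grids;
  kernel bandwidths are recomputed from each coarsened dataset's own
  distance distribution, as they would be for any new dataset.
- **Degradation scoring** uses the original-resolution discovery set as
  gold standard and the coarse run's tested universe as the specificity
  complement; reported curves average six replicate fixtures of 2500
  cells with 80 planted genes at β = 1.2.

## Problem sizes

The validation designs run at desk scale on one CPU: null calibration
at 800 spots × 300 genes × 4 types × 2 bandwidths × 20 replicates
(≈ 1.5 min), power on a 1000-gene panel bootstrapped to 1000/5000 rows
(≈ 2 min), coefficient recovery on a 5000-gene panel at 2000 spots
(≈ 0.5 min), and the remaining designs under a minute each. Uniformity
of null p-values is assessed per replicate (Kolmogorov–Smirnov at
n ≈ 300, the scale of one dataset's gene panel); the spot-swapping
robustness comparison uses the median per-replicate KS statistic, which
is stable where a single pooled statistic is dominated by its own
sampling noise.

## Known limitations

- The Wald/Brown/Cauchy chain is asymptotic; with < ~300 usable
  observations per gene the mid-range of the null p distribution is
  visibly (a few percent) conservative.
- Colocalization-induced collinearity is handled by reporting at the
  gene or cell-type level rather than resolving the niche partner;
  i-niche genes are exactly the cases where the partner is
  unidentifiable.
- The LR confirmation step tests *expression*, not causal signaling;
  ligands genuinely expressed by the niche type pass it even when their
  activity score was a fluke of shared prior targets.
- Per-gene fits loop in Python over genes; the design targets panels of
  10³–10⁴ genes and a few thousand observations per sample.
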