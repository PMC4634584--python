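# Methods

This note documents the models, algorithms and numerical choices behind
the package, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## Count model and testing

Per-gene counts are modeled as negative binomial (NB) with mean *μ* and
dispersion *Φ*, so the variance is *V* = *μ* + *Φμ*².  The one-way GLM
uses a log link with per-sample offsets equal to the log effective
library size (raw library size × normalization factor, factors rescaled
to geometric mean 1 for every method).  The full model fits one mean
parameter per group; the null model one overall mean.  The test
statistic is LR = 2(ℓ_full − ℓ_null) against χ² with G − 1 degrees of
freedom (the ANOVA-like test for a one-way layout), with
Benjamini–Hochberg adjustment (via `statsmodels`) for multiplicity.

Fitting is a vectorized Newton iteration on the NB score equation
Σ_j (y_j − μ_j)/(1 + Φμ_j) = 0 per group, initialized at the
offset-corrected group mean, with steps clipped to ±5, at most 50
iterations and a relative tolerance of 1e-10 on the mean parameter.
Groups whose counts are all zero take the parameter floor (−50 on the
log scale); genes with zero counts in *every* sample are the only ones
excluded from testing (they carry p = q = 1 and rank after all tested
genes).  Ranks ascend in p with ties broken by descending LR and then
input order; p-value rankings are invariant to rescaling all offsets by
a constant.

## Dispersion estimation

The common dispersion maximizes the summed Cox–Reid adjusted profile
likelihood (APL): the per-gene NB log-likelihood at the fitted one-way
means minus ½·log of the Fisher information, which for the one-way
layout is block diagonal with one term Σ_j μ/(1 + Φμ) per group.  The
maximization uses a 25-point log-spaced grid on [1e-6, 10] followed by
bounded scalar refinement; for matrices above 2,000 genes a
deterministic random subset of 2,000 expressed genes is used, which is
ample for a single genome-wide value.

Tagwise (per-gene) dispersions maximize APL_g(Φ) + w·APL_shared(Φ),
where APL_shared is the across-gene mean APL and w = prior_df/residual
df.  The default prior_df = 10 gives moderate shrinkage at Nrep = 3
(w ≈ 1.7); prior_df → ∞ recovers the common value, prior_df = 0 the
noisy gene-wise maxima.  Maximization is per gene over the same grid
with parabolic refinement in log-Φ.

No trended (mean-dependent) dispersion component is fitted.  Because
the simulator's dispersion pool decreases with the mean, a single
shared anchor slightly under-shrinks high-dispersion genes; on DEG-free
data the observed fraction of p < 0.05 is ≈ 0.065–0.07 rather than
0.05.  This is a known, documented cost of the simpler dispersion
model.

Designs without replicates (residual df = 0) cannot separate biological
variation from DE, so dispersion is estimated "blind", treating all
samples as one group.  DE then inflates Φ and the downstream test is
conservative by construction: on no-replicate data with an actual
P_DEG of 25%, the estimated P_DEG at 10% FDR rounds to 0%.

## The DEGES pipeline

`run_deges` executes *X*-(*Y*-*X*)_n-*Z*:

1. compute *X* factors on all genes;
2. *n* times (default 3): run the *Y* test with the current factors,
   flag potential DEGs, recompute *X* on the unflagged genes of the
   full raw matrix (no cascading subsetting; library sizes always come
   from the full matrix), apply the factors to all genes;
3. run the final *Z* test.

Flagging uses BH q < 0.10.  If fewer than round(0.05·n_tested) genes
qualify (round half up), the top-ranked 5% are removed instead
(`flag_source = "floor"`); exact equality at the boundary keeps the
FDR-based set.  The floor guarantees the iteration does something even
when the test is too conservative to flag anything, which is exactly
the no-replicate situation above.  The recorded `estimated_pdeg` always
reports the FDR-based proportion.

Letter codes map `E` to TMM normalization and `D`/`S` to
median-of-ratios; `Y` and `Z` both use the package's single NB-LRT
engine (blind mode engages automatically without replicates).  The
original distinction between the edgeR-, DESeq- and DESeq2-flavored
tests is therefore preserved at the normalization level and in the
no-replicate dispersion mode only; with one engine, codes such as
`DED-E` and `DDD-E` coincide.

## Normalization methods

*TMM*: per sample against a reference (the sample whose
upper-quartile/library-size ratio is closest to the across-sample
mean), M = log2 ratios and A = average log2 abundances are computed
over genes positive in both samples; the central bands after trimming
30% (by M) and 5% (by A) from each tail are kept, and the factor is
2^(weighted mean M) with inverse-asymptotic-variance weights
(N−y)/(Ny) summed over the pair.  An empty post-trim set falls back to
the untrimmed weighted mean with a warning.  TMM is only approximately
invariant to scaling one sample's depth (the weights couple the two
samples of a pair); median-of-ratios is exactly invariant.

*Median-of-ratios (RLE)*: size factor = median over genes positive in
all samples of y_gj/(geometric mean of gene g); converted to factors by
dividing by library size so all methods share one contract.

*Upper quartile*: factor ∝ 75th percentile (linear interpolation) of
the sample's nonzero counts over library size.  *None*: unit factors.

All methods accept a gene mask (the DEGES subset) and report the
subset size used.

## Simulator

`simulate_counts` draws, per gene, a (μ, Φ) pair with replacement from
a parameter pool, multiplies the mean of the up-regulated group by the
gene's fold change if the gene is a DEG, and samples counts through the
gamma–Poisson mixture (gamma shape 1/Φ, scale Φμ), which honors
V = μ + Φμ² exactly; Φ = 0 short-circuits to Poisson.  Exactly
round(Ngene·P_DEG) genes are DEGs — the first rows of the matrix, with
explicit truth emitted — partitioned among groups by largest-remainder
apportionment of (P_G1, …, P_GG).  Fold changes are either fixed
(default 4.0) or 1.2 + Gamma(shape 2.0, scale 0.5), mean 2.2.  Because
the pool pair is drawn before the fold-change multiplication, DEG and
non-DEG marginals share the same shape.

The default pool is synthetic: log-normal means with median 60 and
log-sd 1.5 (clipped to [1, 5·10⁴]), dispersions following the
power-law trend 0.15·(μ/60)^−0.3 with log-normal scatter (sd 0.5 on
the log scale), clipped to [0.005, 1.0].  This reproduces the
qualitative features the benchmark needs — heavy-tailed means, a
decreasing dispersion–mean trend, realistic bulk-RNA-seq dispersion
magnitudes — but it is *not* an empirical distribution: it has no
zero-inflation, no correlated genes, no count outliers, and its exact
tail weights are choices, not measurements.  Absolute AUC values under
this pool (≈ 98% at the default conditions) are therefore higher than
under an empirically derived pool; conclusions should be read from
*paired contrasts* (DEGES vs. plain, method orderings), which are
robust to the pool, not from absolute levels.  An externally estimated
pool can be supplied as a two-column (mu, phi) TSV via `load_pool` for
fidelity runs.

## Evaluation

AUC is computed from ranks only (midrank-tied Mann–Whitney), equal to
the trapezoidal ROC area, and reported in percent.  Studies evaluate
every pipeline on the *same* per-trial dataset (seed = base_seed +
trial), so cross-pipeline comparisons are paired; this is a design
choice — whether the original benchmark shared datasets across
pipelines within a condition is not documented — and it sharpens
small-trial comparisons considerably.  Reproducibility utilities
provide top-k overlap counts and POG, Jaccard coefficients
(|A∩B|/|A∪B|, two empty sets → 1), Spearman list similarity, and
replicate-subset splitting.

## Expression patterns and clustering

Each gene is assigned an expression pattern by fitting the five
group-equality partitions of three groups ({123}, {1|23}, {2|13},
{3|12}, {1|2|3}) as constrained one-way NB models with a supplied
dispersion, selecting by BIC = −2ℓ + k·log(n_samples), and naming the
pattern by the descending order of the fitted block means (ties broken
by group index).  Equality between groups thus emerges from model
selection, not from a numeric threshold.  The ten commonly tabulated
labels cover the flat pattern, the three singleton-up patterns and the
six total orders; a two-block partition with the *pair* above the
singleton (e.g. G2=G3>G1) has no slot in that list, and this classifier
emits such labels as written rather than forcing them into the ten.
Posterior-probability classification in the style of empirical-Bayes
packages is out of scope; the 10-label output space is preserved.

Sample clustering drops all-zero genes, collapses duplicate count rows
to unique expression patterns, uses 1 − Spearman correlation as the
pairwise sample distance and average linkage (SciPy), and returns the
dendrogram as a scikit-bio tree for Newick output.  Spearman is
rank-based per sample pair, so the dendrogram is invariant to
per-sample depth scaling.

## Problem sizes used by the test suite

The benchmark-style tests run at the standard study scale — 10,000
genes, three groups, three replicates (or one, for the no-replicate
checks), four-fold DE — with 20 paired trials per condition, which
gives sub-0.1-point Monte-Carlo error on paired AUC contrasts.  The
full suite completes in a few minutes on one CPU; the vectorized GLM
fits one dataset's full pipeline in ≈ 1–3 s.

## Known limitations

- No trended dispersion (slightly liberal type-I error, see above).
- No count outliers, correlated genes, or transcript-level structure in
  the simulator.
- One NB test engine: pipeline letters differing only in Y/Z collapse.
- The "unique expression patterns" clustering filter is interpreted as
  duplicate-row collapsing.
- Blind-mode no-replicate inference is deliberately conservative and
  should be read as ranking, not as calibrated significance.
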