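# Methods

This note documents the statistical conventions of the package: the models it
fits, the estimators and their defaults, what the synthetic-data generator
emulates, and the numerical choices made where the design was genuinely open.

## Variance model and estimators

For gene *g*, animal *i* = 1..n and replicate *k* = 1..K the one-way
random-effects model is

    y_ikg = mu_g + b_ig + w_ikg,  b ~ N(0, s2_bg),  w ~ N(0, s2_wg).

For a balanced layout the package uses the closed-form ANOVA estimators

    MSW = SSW / (n(K-1)),  MSB = K * sum_i (ybar_i - ybar)^2 / (n-1),
    s2_w = MSW,            s2_b = max(0, (MSB - MSW) / K),

which coincide with REML at the interior and with the non-negativity
constraint at the boundary.  Unbalanced designs fall back to per-gene numeric
REML (Nelder–Mead on the restricted likelihood, boundary compared explicitly);
a warning is emitted because the closed form no longer applies.  Negative
component estimates are truncated at zero, and estimates below 1e-4 are
flagged in a `near_zero_between` column — a reporting convention for the
point mass that truncation creates at zero.

The intraclass correlation `c = s2_b / (s2_b + s2_w)` lies in [0, 1] and is 0
whenever MSB <= MSW.  Note that `mean(c-hat)` is biased slightly below the true
`c` at n = 12, K = 2 (truncation plus the nonlinearity of the ratio); the
package reports the estimator as-is rather than attempting a bias correction.

The nested cage model `y = mu + c_cage + d_mouse(cage) + w` is estimated by
balanced nested ANOVA with mean squares MS_cage, MS_mouse(cage), MS_within on
(C-1), (M-C), (M(K-1)) degrees of freedom.  The cage effect is tested by
F = MS_cage / MS_mouse(cage) and the mouse-within-cage effect by
F = MS_mouse(cage) / MS_within against the analytic F reference.  When a cage
component is present, the one-way between-mouse mean square absorbs it with
coefficient mpc(C-1)/(M-1) < 1, so the one-way `s2_b` slightly understates
cage-driven variance; the nested model is the right tool in that case.

## Excess-variance (chi-square) test and variable genes

Under H0: s2_g = s2 for all genes, `nu * s2_g / s2` is chi-square with
nu = (total samples - 1) degrees of freedom (23 in the modelled design).  The
common scale is estimated by the bias-corrected geometric mean

    s2_pool = exp( mean_g ln s2_g - (psi(nu/2) - ln(nu/2)) ),

since E[ln(s^2/sigma^2)] = psi(nu/2) - ln(nu/2) for a chi-square-scaled
variance.  The log-scale geometric mean bounds the influence of any single
outlying gene by a factor `outlier^(1/G)`, which is the robustness property
wanted from a pooled scale.  The test refers `nu * s2_g / s2_pool` to the
analytic chi-square upper tail; a Monte-Carlo reference sample would estimate
the same tail with extra noise, so the analytic form is used.

*Variable genes* are the top-N genes by total variance (default N = 2500,
capped at the expressed-gene count), ranked among expressed genes only:
ranking unexpressed probes would promote background noise into the network.

## Shrunken F and permutation p-values

Between-mouse significance uses a moderated F statistic,
`F_g = MSB_g / s2_tilde_g`, where `s2_tilde_g` is a James–Stein estimate of
the within-mouse variance: with `z_g = ln MSW_g - (psi(d/2) - ln(d/2))`,
d = n(K-1), known sampling variance psi'(d/2), and Lindley shrink factor

    B = min(1, (G-3) * psi'(d/2) / sum_g (z_g - zbar)^2),

`s2_tilde_g = exp(zbar + (1-B)(z_g - zbar))`.  With fewer than 4 genes no
shrinkage is applied.  Because the exact shrinkage constant affects only the
statistic's null distribution, p-values come from permutations: residuals
(values minus the per-gene mean) are relabelled by one random permutation of
the sample positions per round, applied to every gene, and the statistic is
recomputed.  By default the null statistics of all genes are pooled into one
reference distribution — this matches the shrinkage-F literature, gives
p-value resolution below 1/n_perm, and is calibrated under the global null
because genes are exchangeable there; a per-gene mode is available (note that
per-gene nulls for genes with real effects contain the effect in their
permuted residuals, so pooled mode is also the better default for pi0
estimation).  p = (1 + #null >= observed) / (1 + #null), so the minimum
attainable per-gene p with 99 permutations is 1/100.

Multiple-testing adjustment offers Šidák step-down (family-wise error),
Benjamini–Hochberg (FDR), and Storey q-values (pi0-weighted BH).  pi0 is
estimated by the single-lambda counting estimator `#{p > 0.5} / (m * 0.5)`
capped at 1; a lambda-grid variant with a cubic-polynomial smoother
extrapolated to lambda = 1 is available.

## Coexpression network and modules

The network over variable genes is unsigned with adjacency `a_ij = r_ij^2`
(the square is the soft power; no further thresholding).  Topological overlap
is

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with connectivity `k_i = sum_{u != i} a_iu` and unit diagonal.  Genes are
clustered by average linkage on 1 - TOM.  Module extraction uses a
deterministic hybrid cut: joins above `cut_quantile` (default 0.99) times the
root height are always broken — average linkage chains loosely connected
stragglers onto the topmost merges, and these should not glue branches
together — and below that height a branch splits only when both children have
more than `min_size` members and the join-height gap is at least `gap_frac`
of the branch height.  `gap_frac` maps from a deep-split level
{0: 0.15, 1: 0.10, 2: 0.05, 3: 0.02}, default level 2.  Clusters with
`min_size` (default 25) or fewer members dissolve to unassigned.  Modules
whose eigengenes correlate above `merge_threshold` (default 0.8) are merged
iteratively, largest correlation first.  Labels follow the conventional
colour order by decreasing size (turquoise, blue, brown, gold, ...), with
"gold" in the slot usually called yellow; unassigned genes are "grey".

Known limitation: on data dominated by unstructured genes, the loosely
connected bulk below the cut can survive as one large low-cohesion module
(its low variance-explained flags it); the published dynamic-cut variants
behave similarly under static cutting, and the eigengene diagnostics are the
intended guard.

The module eigengene is the first right singular vector of the
gene-standardized module submatrix.  Its sign makes the majority of member
genes positively correlated (a tie takes the sign of the correlation sum,
which is deterministic), and it is rescaled so its variance equals the median
per-gene variance of the members, keeping eigengene plots on the scale of a
typical member gene.  Variance explained is the leading squared singular
value's share.  A one-gene module returns that gene's centred profile with
variance explained 1.

## Profile similarity

With K = 2 the split into the between part `B_i = (y_i1 + y_i2)/2` and the
within part `W_i = y_i1 - B_i = (y_i1 - y_i2)/2` is an exact linear bijection.
`r_b` is the Pearson correlation of two profiles' between parts and `r_w` of
their within parts; `r_w` is only defined within one tissue because replicate
labels do not correspond across tissues, and the API enforces this via a
tissue tag.  Significance uses the Fisher transformation
`z = atanh(r), se = 1/sqrt(n-3)` with, by default, a Student-t quantile with
9 degrees of freedom as reference and the conventions n = n_mice - 1 for
`r_b` and n = n_mice for `r_w`: these reproduce the conventional printed
thresholds |r_b| > 0.66 and |r_w| > 0.64 at alpha = 0.05 for a 12-mouse
design.  The textbook standard-normal reference (thresholds 0.57/0.55 there)
is available via `reference="normal"`; the t9 default is a documented
convention, not a claim of exact distribution theory.

## Enrichment and cross-platform comparison

Enrichment of a module (or its positively/negatively correlated subset) in a
gene set is the upper-tail hypergeometric probability P(X >= overlap) with
population the user-defined universe — by default the variable genes present
in the collection — after collapsing probes to one per gene symbol (keeping
the probe with the largest total variance).  Symbols compare case-insensitively
with no alias resolution.  An EASE-style variant (overlap reduced by one) is a
flag.  Cross-tissue module overlap uses the same tail with a Bonferroni
factor supplied by the caller (how many pairs constitute the family is a
study-level decision).  Two modules share enrichment for a category when each
contains at least 4 genes of it and both enrichment p-values are below 0.01.

Cross-platform comparison maps each probe to the same-symbol probe on the
second platform with the highest Pearson correlation over shared samples,
after excluding second-platform probes with mean intensity below 7 (log2
units); module eigengenes are recomputed on the second platform from the
mapped members (at least 3 required) and correlated with the originals, each
platform using its own majority-sign convention.

## Synthetic-data generator

The generator runs the nested model forward under the modelled design:
6 cages x 2 mice x 2 replicates (24 arrays), Gaussian cage, mouse-within-cage
and within-mouse components (scalars or per-gene vectors), planted modules
driven by standard-normal latent factors (per mouse for between-mouse
modules, per sample for within-mouse modules) entering member genes with a
fixed loading, additive per-gene batch shifts over two processing blocks of
three cages, and background rows — negative controls and non-expressed
genes — drawn as a per-probe baseline N(background_mean, background_sd^2)
(the spread of probe affinities) plus per-sample technical noise.

Defaults, chosen once as plausible magnitudes for log2 microarray data:
55% of genes expressed with baseline means uniform on (7, 13) against a
background at 6.0 (sd 0.3 across probes, 0.1 within a probe);
sigma2_within = 0.05, sigma2_mouse = 0.02, sigma2_cage = 0.01 (log2 units
squared; replicate noise dominating a smaller animal effect);
batch_effect_sd = 0.1.  No effect sizes for the latent module structure are
published for the motivating study, so no default modules are planted —
each analysis states its `module_spec` explicitly, and the recovery analyses
use loading 0.9 over within-noise 0.1 (within-module r ≈ 0.89) for module
recovery and sigma2_mouse = sigma2_within = 0.5 for component recovery.

What the generator does **not** emulate: bead-level intensities, probe
cross-hybridization, intensity-dependent (heteroskedastic) noise, correlated
error across genes beyond the planted factors, and platform-specific noise
shapes.  Passing recovery tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those artefacts.

## Numerical conventions

- Percentiles use linear interpolation between order statistics (the common
  "type 7" convention), e.g. the detection threshold at the 95th percentile
  of negative-control per-mouse means.
- Quantile normalization maps each column to the across-sample mean of order
  statistics; tied entries within a column receive the mean of the quantile
  values they span.  The transform is idempotent to machine precision.
- Batch correction removes a per-gene per-batch robust location (median by
  default; a Huber M-estimator via the `estimator="huber"` hook) and restores
  the per-gene global robust location; single-sample batches are skipped with
  a warning.
- Detection rules: `"mouse-mean"` (default) calls a gene expressed when some
  mouse's replicate mean exceeds the threshold; `"both-samples"` requires
  both replicates of some mouse to exceed it.  Both are exposed because both
  wordings are in circulation for this design; both use the same
  negative-control threshold statistic.
- Maximal fold change is `2^(max_i mean_i - min_i mean_i)` over per-mouse
  means of log2 values; count thresholds are strict (>).
- Permutations, simulation and the pipeline all draw from
  `numpy.random.default_rng` seeded from a single top-level seed; identical
  config and seed give byte-identical pipeline outputs.
- Degenerate inputs: constant genes are rejected by network construction
  (named in the error), reported as missing p-values by the permutation test,
  and excluded with a warning from the pooled scale.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use G = 2000 genes for null
calibration (200 permutations) and component recovery, G = 5000 for the pi0
estimate, 50 genes for the REML-oracle comparison, and 60–80 genes for module
recovery and cross-platform checks; each reflects the smallest size at which
the Monte-Carlo error is comfortably inside the stated tolerances.
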