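"""Per-gene variance decomposition and significance machinery.

For gene g, mouse i and replicate k the model is

    y_ikg = mu_g + b_ig + w_ikg,    b ~ N(0, sigma2_bg),  w ~ N(0, sigma2_wg)

For a balanced one-way layout (n mice, k replicates each) the truncated ANOVA
estimators

    s2_within  = MSW,   s2_between = max(0, (MSB - MSW) / k)

coincide with REML.  The intraclass correlation c = s2_b / (s2_b + s2_w)
measures the between-animal share of total variance.

Excess total variability is tested per gene against the null that all genes
share one variance: the statistic nu * s2_g / sigma2_pool is referred to the
chi-square distribution with nu = (total samples - 1) degrees of freedom,
where sigma2_pool is a bias-corrected geometric-mean ("James-Stein type")
pooled estimate.  Between-mouse significance uses a shrunken F statistic
(MSB over a per-gene within-variance shrunk toward the across-gene mean on the
bias-corrected log scale) with permutation p-values from relabelled residuals,
followed by Sidak step-down / Benjamini-Hochberg adjustment and a pi0
estimate.  A nested cage model splits the between-mouse component into
between-cage and mouse-within-cage parts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionStudy


def chi2_log_bias(nu: float) -> float:
    """E[ln(s^2 / sigma^2)] when nu * s^2 / sigma^2 ~ chi^2_nu."""
    return float(digamma(nu / 2.0) - np.log(nu / 2.0))


@dataclass
class PooledScale:
    """Bias-corrected geometric-mean pooled variance (the common-scale null)."""

    sigma2_pool: float
    nu: int
    bias_correction: float


def pooled_scale(s2_total, nu: int) -> PooledScale:
    """Pool per-gene total variances on the log scale with chi-square bias correction.

    sigma2_pool = exp( mean_g ln s2_g - (psi(nu/2) - ln(nu/2)) ).
    Zero or negative variances are excluded with a warning.
    """
    s2 = np.asarray(s2_total, dtype=float)
    if s2.size == 0:
        raise ValueError("pooled_scale: empty variance vector")
    ok = s2 > 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} genes with zero variance")
        s2 = s2[ok]
        if s2.size == 0:
            raise ValueError("pooled_scale: all variances are zero")
    bias = chi2_log_bias(nu)
    return PooledScale(
        sigma2_pool=float(np.exp(np.mean(np.log(s2)) - bias)),
        nu=int(nu),
        bias_correction=bias,
    )


def excess_variance_test(s2_total, scale: PooledScale) -> pd.DataFrame:
    """Chi-square excess-variance test of H0: sigma2_g = sigma2 for every gene.

    Returns a DataFrame with ``chi2_stat = nu * s2 / sigma2_pool`` and its
    upper-tail chi-square p-value.
    """
    s2 = pd.Series(s2_total, dtype=float)
    stat = scale.nu * s2 / scale.sigma2_pool
    p = stats.chi2.sf(stat, df=scale.nu)
    return pd.DataFrame({"chi2_stat": stat, "chi2_p": p})


def variable_genes(s2_total: pd.Series, n: int = 2500, eligible=None) -> pd.Index:
    """Top-``n`` genes by total variance, ranked among ``eligible`` genes only.

    ``n`` is capped at the eligible count.  Ties are broken by index order
    (stable sort) for determinism.
    """
    s2 = pd.Series(s2_total, dtype=float)
    if eligible is not None:
        s2 = s2.loc[pd.Index(eligible)]
    n = min(int(n), len(s2))
    order = s2.sort_values(ascending=False, kind="stable").index
    return order[:n]


def alpha_counts(pvals, alphas=(0.05, 0.01, 1e-4)) -> dict:
    p = np.asarray(pvals, dtype=float)
    return {a: int((p < a).sum()) for a in alphas}


# ---------------------------------------------------------------------------
# one-way (mouse) decomposition
# ---------------------------------------------------------------------------

def _balanced_layout(study: ExpressionStudy):
    """Column permutation grouping samples by mouse; returns (order, n, k)."""
    groups = study.samples.groupby("mouse", sort=False).indices
    n = len(groups)
    k = study.reps_per_mouse
    order = np.concatenate([np.asarray(ix) for ix in groups.values()])
    return order, n, k


def decompose_variance(study: ExpressionStudy, near_zero: float = 1e-4) -> pd.DataFrame:
    """Per-gene one-way random-effects decomposition into mouse and residual parts.

    Balanced designs use the closed-form ANOVA/REML estimator; unbalanced
    designs fall back to numeric REML per gene (with a warning).  Negative
    between-mouse estimates are truncated at zero, and genes whose estimate
    falls below ``near_zero`` are flagged in the ``near_zero_between`` column
    (a reporting convention for the near-zero spike).
    """
    X = study.values.to_numpy(dtype=float)
    idx = study.values.index
    mu = X.mean(axis=1)
    s2_total = X.var(axis=1, ddof=1)

    if study.balanced and study.reps_per_mouse >= 2:
        order, n, k = _balanced_layout(study)
        Y = X[:, order].reshape(X.shape[0], n, k)
        mouse_mean = Y.mean(axis=2)
        grand = mouse_mean.mean(axis=1)
        msw = ((Y - mouse_mean[:, :, None]) ** 2).sum(axis=(1, 2)) / (n * (k - 1))
        msb = k * ((mouse_mean - grand[:, None]) ** 2).sum(axis=1) / (n - 1)
        s2w = msw
        s2b = np.maximum(0.0, (msb - msw) / k)
    else:
        warnings.warn("unbalanced design: using numeric REML per gene")
        labels = study.samples["mouse"].to_numpy()
        est = np.array([_reml_oneway(row, labels) for row in X])
        s2w, s2b = est[:, 0], est[:, 1]
        msw = s2w
        msb = np.full_like(s2w, np.nan)

    denom = s2b + s2w
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, s2b / denom, 0.0)
    return pd.DataFrame(
        {
            "mu": mu,
            "s2_total": s2_total,
            "msb": msb,
            "msw": msw,
            "s2_between": s2b,
            "s2_within": s2w,
            "icc": icc,
            "near_zero_between": s2b < near_zero,
        },
        index=idx,
    )


def _reml_oneway(y: np.ndarray, mouse_labels: np.ndarray) -> tuple[float, float]:
    """Numeric REML for a one-way random-effects model, possibly unbalanced."""
    groups = pd.Series(y).groupby(pd.Series(mouse_labels))
    sizes = groups.size().to_numpy(dtype=float)
    means = groups.mean().to_numpy()
    ssw = float(((y - groups.transform("mean").to_numpy()) ** 2).sum())
    tot = y.var(ddof=1) if y.size > 1 else 1.0
    if tot <= 0:
        return 0.0, 0.0

    def neg2_reml(theta):
        sw2, sb2 = np.exp(theta[0]), np.exp(theta[1])
        lam = sw2 + sizes * sb2
        w = sizes / lam
        mu_hat = (w * means).sum() / w.sum()
        logdet = (sizes - 1).sum() * np.log(sw2) + np.log(lam).sum()
        quad = ssw / sw2 + (sizes * (means - mu_hat) ** 2 / lam).sum()
        return logdet + np.log(w.sum()) + quad

    best = None
    for sb0 in (tot * 0.5, tot * 0.05):
        res = optimize.minimize(
            neg2_reml,
            x0=[np.log(max(tot * 0.5, 1e-8)), np.log(max(sb0, 1e-8))],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    sw2, sb2 = np.exp(best.x)
    # compare against the boundary sb2 = 0
    res0 = optimize.minimize_scalar(
        lambda t: neg2_reml([t, np.log(1e-12)]),
        bounds=(np.log(tot * 1e-6), np.log(tot * 1e3)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if res0.fun <= best.fun:
        return float(np.exp(res0.x)), 0.0
    return float(sw2), float(sb2)


# ---------------------------------------------------------------------------
# shrunken F and permutation p-values
# ---------------------------------------------------------------------------

def shrunken_within_variance(msw, d: int) -> tuple[np.ndarray, float]:
    """James-Stein shrinkage of log within-mouse variances toward their mean.

    z_g = ln MSW_g - (psi(d/2) - ln(d/2)) is an unbiased estimate of
    ln sigma2_wg with known sampling variance psi'(d/2); the Lindley-type
    shrink factor B = min(1, (G-3) psi'(d/2) / sum (z_g - mean)^2) pulls each
    z toward the across-gene mean.  Returns (sigma2_tilde, B).
    """
    msw = np.asarray(msw, dtype=float)
    if (msw <= 0).any():
        raise ValueError("shrunken_within_variance: non-positive within variance")
    z = np.log(msw) - chi2_log_bias(d)
    G = z.size
    m = z.mean()
    if G < 4:
        warnings.warn("fewer than 4 genes: no shrinkage applied (B = 0)")
        B = 0.0
    else:
        ss = ((z - m) ** 2).sum()
        B = 1.0 if ss == 0 else min(1.0, (G - 3) * float(polygamma(1, d / 2.0)) / ss)
    return np.exp(m + (1.0 - B) * (z - m)), B


def shrunken_f(msb, msw, d: int, shrink: bool = True) -> np.ndarray:
    """Modified F statistic: MSB over the shrunken within-mouse variance."""
    msb = np.asarray(msb, dtype=float)
    msw = np.asarray(msw, dtype=float)
    ok = msw > 0
    f = np.full(msb.shape, np.nan)
    if not ok.any():
        return f
    if shrink:
        sigma_tilde, _ = shrunken_within_variance(msw[ok], d)
    else:
        sigma_tilde = msw[ok]
    f[ok] = msb[ok] / sigma_tilde
    return f


def _mean_squares(X: np.ndarray, n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    Y = X.reshape(X.shape[0], n, k)
    mouse_mean = Y.mean(axis=2)
    grand = mouse_mean.mean(axis=1)
    msw = ((Y - mouse_mean[:, :, None]) ** 2).sum(axis=(1, 2)) / (n * (k - 1))
    msb = k * ((mouse_mean - grand[:, None]) ** 2).sum(axis=1) / (n - 1)
    return msb, msw


def permutation_pvalues(
    study: ExpressionStudy,
    n_perm: int = 1000,
    seed: int = 0,
    pooling: str = "pooled",
    shrink: bool = True,
) -> pd.Series:
    """Permutation p-values for the (shrunken) F statistic on mouse effects.

    Residuals (values minus the per-gene mean) are relabelled by one random
    permutation of the sample positions per round, applied to every gene, and
    the statistic is recomputed on the permuted layout.  With
    ``pooling="pooled"`` (default) the null statistics of all genes form one
    reference distribution; ``pooling="per-gene"`` compares each gene to its
    own permutations.  p = (1 + #null >= observed) / (1 + #null).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if pooling not in ("pooled", "per-gene"):
        raise ValueError(f"unknown pooling {pooling!r}")
    if not study.balanced or study.reps_per_mouse < 2:
        raise ValueError("permutation test requires a balanced design with k >= 2")
    order, n, k = _balanced_layout(study)
    X = study.values.to_numpy(dtype=float)[:, order]
    constant = X.var(axis=1) == 0
    resid = X - X.mean(axis=1, keepdims=True)

    def stat(mat):
        msb, msw = _mean_squares(mat, n, k)
        with np.errstate(invalid="ignore", divide="ignore"):
            return shrunken_f(msb, msw, n * (k - 1), shrink=shrink)

    obs = stat(X)
    obs[constant] = np.nan
    rng = np.random.default_rng(seed)
    S = X.shape[1]
    null = np.empty((X.shape[0], n_perm))
    for r in range(n_perm):
        null[:, r] = stat(resid[:, rng.permutation(S)])
    null[constant, :] = np.nan

    if pooling == "pooled":
        pool = np.sort(null[~constant].ravel())
        pool = pool[np.isfinite(pool)]
        n_null = pool.size
        cnt_ge = n_null - np.searchsorted(pool, obs, side="left")
        p = (1.0 + cnt_ge) / (1.0 + n_null)
    else:
        cnt_ge = np.nansum(null >= obs[:, None], axis=1)
        p = (1.0 + cnt_ge) / (1.0 + n_perm)
    p = np.where(constant, np.nan, p)
    return pd.Series(p, index=study.values.index, name="p_perm")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

@dataclass
class MultipleTestingResult:
    method: str
    adjusted: pd.Series
    pi0: float | None = None


def adjust_pvalues(p, method: str = "bh") -> MultipleTestingResult:
    """Adjust p-values: Sidak step-down, Benjamini-Hochberg, or Storey q-values."""
    p_ser = pd.Series(p, dtype=float)
    arr = p_ser.to_numpy()
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    ok = np.isfinite(arr)
    adj = np.full(arr.shape, np.nan)
    pi0 = None
    if method == "sidak_stepdown":
        adj[ok] = multipletests(arr[ok], method="holm-sidak")[1]
    elif method == "bh":
        adj[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    elif method == "qvalue":
        pi0 = estimate_pi0(arr[ok])
        adj[ok] = np.minimum(1.0, pi0 * multipletests(arr[ok], method="fdr_bh")[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return MultipleTestingResult(
        method=method, adjusted=pd.Series(adj, index=p_ser.index), pi0=pi0
    )


def estimate_pi0(p, lam: float = 0.5, grid: bool = False) -> float:
    """Estimate the null proportion pi0.

    Default: the single-lambda estimator #{p > lam} / (m (1 - lam)), capped at
    1.  With ``grid=True`` a lambda grid 0.05..0.90 is evaluated and a cubic
    polynomial smoother is extrapolated to lambda -> 1.
    """
    arr = np.asarray(p, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("estimate_pi0: empty p-value vector")
    if grid:
        lams = np.arange(0.05, 0.91, 0.05)
        pi0s = np.array([(arr > l).mean() / (1 - l) for l in lams])
        coef = np.polyfit(lams, pi0s, deg=3)
        return float(np.clip(np.polyval(coef, 1.0), 0.0, 1.0))
    return float(min(1.0, (arr > lam).mean() / (1.0 - lam)))


# ---------------------------------------------------------------------------
# nested cage model
# ---------------------------------------------------------------------------

def decompose_cage(study: ExpressionStudy) -> pd.DataFrame:
    """Nested ANOVA: cage, mouse-within-cage and within-mouse components.

    Requires a balanced nested design (equal mice per cage, equal replicates
    per mouse).  The cage effect is tested by F = MS_cage / MS_mouse(cage) and
    the mouse-within-cage effect by F = MS_mouse(cage) / MS_within, each with
    the analytic F reference.
    """
    if "cage" not in study.samples.columns:
        raise ValueError("sample table lacks a cage column")
    cages = list(dict.fromkeys(study.samples["cage"]))
    C = len(cages)
    if C < 2:
        raise ValueError("nested cage model needs at least 2 cages")
    mice_by_cage = study.samples.groupby("cage", sort=False)["mouse"].nunique()
    if mice_by_cage.nunique() != 1 or not study.balanced:
        raise ValueError("nested cage model requires a balanced nested design")
    mpc = int(mice_by_cage.iloc[0])
    k = study.reps_per_mouse
    M = C * mpc

    # order columns cage-by-cage, mouse-by-mouse
    samp = study.samples.reset_index()
    samp["_pos"] = np.arange(len(samp))
    order = (
        samp.sort_values(["cage", "mouse", "replicate"], kind="stable")["_pos"].to_numpy()
    )
    X = study.values.to_numpy(dtype=float)[:, order].reshape(-1, C, mpc, k)

    mouse_mean = X.mean(axis=3)
    cage_mean = mouse_mean.mean(axis=2)
    grand = cage_mean.mean(axis=1)
    ms_within = ((X - mouse_mean[..., None]) ** 2).sum(axis=(1, 2, 3)) / (M * (k - 1))
    ms_mouse = k * ((mouse_mean - cage_mean[..., None]) ** 2).sum(axis=(1, 2)) / (M - C)
    ms_cage = mpc * k * ((cage_mean - grand[:, None]) ** 2).sum(axis=1) / (C - 1)

    s2w = ms_within
    s2m = np.maximum(0.0, (ms_mouse - ms_within) / k)
    s2c = np.maximum(0.0, (ms_cage - ms_mouse) / (mpc * k))
    with np.errstate(invalid="ignore", divide="ignore"):
        f_cage = np.where(ms_mouse > 0, ms_cage / ms_mouse, np.nan)
        f_mouse = np.where(ms_within > 0, ms_mouse / ms_within, np.nan)
    p_cage = stats.f.sf(f_cage, C - 1, M - C)
    p_mouse = stats.f.sf(f_mouse, M - C, M * (k - 1))
    return pd.DataFrame(
        {
            "ms_cage": ms_cage,
            "ms_mouse_in_cage": ms_mouse,
            "ms_within": ms_within,
            "s2_cage": s2c,
            "s2_mouse_in_cage": s2m,
            "s2_within": s2w,
            "f_cage": f_cage,
            "p_cage": p_cage,
            "f_mouse_in_cage": f_mouse,
            "p_mouse_in_cage": p_mouse,
        },
        index=study.values.index,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def variance_analysis(
    study: ExpressionStudy,
    expressed: pd.Index | None = None,
    n_variable: int = 2500,
    n_perm: int = 1000,
    seed: int = 0,
    pooling: str = "pooled",
) -> pd.DataFrame:
    """Full per-gene variance table: decomposition, chi2 test, shrunken F,
    permutation p, Sidak/BH adjustments, and the variable-gene flag."""
    decomp = decompose_variance(study)
    nu = study.n_samples - 1
    scale = pooled_scale(decomp["s2_total"].to_numpy(), nu)
    chi2 = excess_variance_test(decomp["s2_total"], scale)
    d = study.n_mice * (study.reps_per_mouse - 1)
    f = shrunken_f(decomp["msb"].to_numpy(), decomp["msw"].to_numpy(), d)
    p_perm = permutation_pvalues(study, n_perm=n_perm, seed=seed, pooling=pooling)
    out = decomp.join(chi2)
    out["f_shrunk"] = f
    out["p_perm"] = p_perm
    out["p_sidak"] = adjust_pvalues(p_perm, "sidak_stepdown").adjusted
    out["q_bh"] = adjust_pvalues(p_perm, "bh").adjusted
    eligible = expressed if expressed is not None else out.index
    var_idx = variable_genes(out["s2_total"], n=n_variable, eligible=eligible)
    out["is_variable"] = out.index.isin(var_idx)
    return out
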