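"""Between- vs within-animal decomposition of expression profiles.

Any profile over samples (a gene or a module eigengene) splits, for a design
with two replicates per mouse, into a between-mouse part B_i (the mouse's
replicate mean) and a within-mouse part W_i = y_i1 - B_i = (y_i1 - y_i2) / 2.
The split is an exact linear bijection: y_i1 = B_i + W_i, y_i2 = B_i - W_i.

Similarity of two profiles is quantified by Pearson correlations of the parts,
r_b (between) and r_w (within); within-part comparisons are only meaningful
for profiles of the same tissue, because replicate labels correspond only
there.  Significance uses a Fisher z threshold; the default reference is a
Student-t quantile with 9 degrees of freedom, which reproduces the printed
conventions |r_b| > 0.66 (n = 11) and |r_w| > 0.64 (n = 12) at alpha = 0.05,
with the textbook standard-normal reference available as an option.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProfilePair:
    """A profile's between-mouse and within-mouse parts."""

    between: pd.Series  # indexed by mouse
    within: pd.Series | None  # None unless exactly 2 replicates per mouse
    tissue: str | None = None

    @property
    def n_mice(self) -> int:
        return len(self.between)


@dataclass
class CorrelationTest:
    r: float
    n: int
    critical: float
    significant: bool
    reference: str
    alpha: float


def split_profiles(profile: pd.Series, samples: pd.DataFrame) -> ProfilePair:
    """Split a per-sample profile into between- and within-mouse parts.

    ``samples`` must be indexed by sample_id with ``mouse`` and ``replicate``
    columns.  The within part is defined from replicate 1:
    W_i = y_i1 - mean_i = (y_i1 - y_i2) / 2.  For designs with other replicate
    counts only the between part is defined.
    """
    meta = samples.loc[profile.index]
    grouped = profile.groupby(meta["mouse"], sort=False)
    between = grouped.mean()
    between.name = "between"
    counts = grouped.size()
    within = None
    if (counts == 2).all():
        rep1 = profile[meta["replicate"] == sorted(meta["replicate"].unique())[0]]
        rep1.index = meta.loc[rep1.index, "mouse"]
        within = rep1.reindex(between.index) - between
        within.name = "within"
    tissue = None
    if "tissue" in meta.columns:
        tissues = meta["tissue"].unique()
        if len(tissues) == 1:
            tissue = tissues[0]
    return ProfilePair(between=between, within=within, tissue=tissue)


def reconstruct(pair: ProfilePair) -> pd.DataFrame:
    """Invert the split (k = 2 only): columns ``rep1 = B + W``, ``rep2 = B - W``."""
    if pair.within is None:
        raise ValueError("within part undefined: reconstruction needs k = 2")
    return pd.DataFrame(
        {"rep1": pair.between + pair.within, "rep2": pair.between - pair.within}
    )


def _pearson(a: pd.Series, b: pd.Series) -> float:
    b = b.reindex(a.index)
    x, y = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def profile_correlations(x: ProfilePair, y: ProfilePair) -> tuple[float, float]:
    """(r_b, r_w) between two profiles' parts; r_w is NaN when undefined.

    Raises when the within comparison is requested across tissues (the
    replicate labels of different tissues do not correspond).
    """
    if not x.between.index.equals(y.between.index):
        y_b = y.between.reindex(x.between.index)
        if y_b.isna().any():
            raise ValueError("profiles have different mouse sets")
    r_b = _pearson(x.between, y.between)
    r_w = float("nan")
    if x.within is not None and y.within is not None:
        if x.tissue is not None and y.tissue is not None and x.tissue != y.tissue:
            raise ValueError(
                "within-mouse correlation is only meaningful within one tissue"
            )
        r_w = _pearson(x.within, y.within)
    return r_b, r_w


def fisher_critical(n: int, alpha: float = 0.05, reference: str = "t9") -> float:
    """Critical |r| at level ``alpha`` from the Fisher z transformation.

    z = atanh(r) has standard error 1/sqrt(n - 3); the critical value is
    tanh(q / sqrt(n - 3)) where q is the two-sided 1 - alpha/2 quantile of the
    reference distribution (``"normal"`` or ``"t9"``, a t with 9 df).
    """
    if n <= 3:
        raise ValueError("fisher_critical requires n >= 4")
    if reference == "normal":
        q = stats.norm.ppf(1 - alpha / 2)
    elif reference == "t9":
        q = stats.t.ppf(1 - alpha / 2, df=9)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return float(np.tanh(q / np.sqrt(n - 3)))


def correlation_test(
    r: float, n: int, alpha: float = 0.05, reference: str = "t9"
) -> CorrelationTest:
    crit = fisher_critical(n, alpha, reference)
    return CorrelationTest(
        r=float(r),
        n=int(n),
        critical=crit,
        significant=bool(abs(r) > crit),
        reference=reference,
        alpha=alpha,
    )


def module_icc(icc: pd.Series, module_genes) -> float:
    """Median intraclass correlation over module members."""
    genes = list(module_genes)
    if len(genes) == 0:
        raise ValueError("empty module")
    vals = icc.loc[genes]
    if vals.isna().any():
        raise ValueError("module contains genes absent from the decomposition")
    return float(vals.median())


def eigengene_correlation_table(
    module_sets: dict,
    samples_by_set: dict,
    alpha: float = 0.05,
    reference: str = "t9",
) -> pd.DataFrame:
    """Pairwise r_b / r_w between module eigengenes across one or more studies.

    ``module_sets`` maps a study key (e.g. tissue name) to a ModuleSet;
    ``samples_by_set`` maps the same key to its sample table.  r_b uses
    n = n_mice - 1 and r_w uses n = n_mice (the conventions under which the
    default t9 reference reproduces the printed 0.66 / 0.64 thresholds for 12
    mice).
    """
    pairs = []
    keys = list(module_sets)
    entries = [
        (key, label, split_profiles(mod.eigengene, samples_by_set[key]))
        for key in keys
        for label, mod in module_sets[key].modules.items()
    ]
    for a in range(len(entries)):
        for b in range(a + 1, len(entries)):
            key_a, lab_a, pa = entries[a]
            key_b, lab_b, pb = entries[b]
            r_b, _ = profile_correlations(
                ProfilePair(pa.between, None, None), ProfilePair(pb.between, None, None)
            )
            same_tissue = pa.tissue == pb.tissue
            r_w = float("nan")
            if same_tissue and pa.within is not None and pb.within is not None:
                r_w = _pearson(pa.within, pb.within)
            n_mice = pa.n_mice
            tb = correlation_test(r_b, n_mice - 1, alpha, reference)
            row = {
                "set_a": key_a,
                "module_a": lab_a,
                "set_b": key_b,
                "module_b": lab_b,
                "r_b": r_b,
                "r_b_significant": tb.significant,
                "r_w": r_w,
                "r_w_significant": False,
            }
            if np.isfinite(r_w):
                tw = correlation_test(r_w, n_mice, alpha, reference)
                row["r_w_significant"] = tw.significant
            pairs.append(row)
    return pd.DataFrame(pairs)
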