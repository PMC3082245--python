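"""Data model, I/O and preprocessing for replicated expression studies.

The central container is :class:`ExpressionStudy`: a log2 expression matrix
(probes x samples) together with a sample table describing the nested animal
design (cage / mouse / replicate / batch / tissue) and a probe table carrying
gene symbols and negative-control flags.  Preprocessing operations — quantile
normalization, robust per-gene batch correction, detection of expressed genes
against the negative-control distribution, and maximal fold change between
animals — all consume and return this container.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("mouse", "cage", "replicate", "batch", "tissue")
PROBE_COLUMNS = ("gene_symbol", "is_negative_control")


class StudyValidationError(ValueError):
    """Raised when a study's matrix and metadata do not agree."""


@dataclass
class ExpressionStudy:
    """Log2 expression matrix with nested design metadata.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, rows indexed by probe_id, columns by
        sample_id.
    samples
        DataFrame indexed by sample_id with columns ``mouse``, ``cage``,
        ``replicate``, ``batch``, ``tissue`` (``batch`` may be absent).
    probes
        DataFrame indexed by probe_id with columns ``gene_symbol`` and
        ``is_negative_control`` (0/1).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame
    balanced: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        if len(self.probes) == 0:
            raise StudyValidationError("no probes: the probe table is empty")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise StudyValidationError(f"duplicate sample_id {dup!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise StudyValidationError(f"duplicate probe_id {dup!r}")
        missing_meta = [c for c in self.values.columns if c not in self.samples.index]
        if missing_meta:
            raise StudyValidationError(
                f"matrix column {missing_meta[0]!r} not present in sample table"
            )
        missing_mat = [s for s in self.samples.index if s not in self.values.columns]
        if missing_mat:
            raise StudyValidationError(
                f"sample {missing_mat[0]!r} in metadata missing from matrix"
            )
        for col in ("mouse", "replicate"):
            if col not in self.samples.columns:
                raise StudyValidationError(f"sample table lacks column {col!r}")
        for col in PROBE_COLUMNS:
            if col not in self.probes.columns:
                raise StudyValidationError(f"probe table lacks column {col!r}")
        if not self.probes.index.equals(self.values.index):
            extra = self.values.index.difference(self.probes.index)
            if len(extra):
                raise StudyValidationError(
                    f"matrix probe {extra[0]!r} not present in probe table"
                )
            self.probes = self.probes.loc[self.values.index]
        # align sample table to matrix column order
        self.samples = self.samples.loc[list(self.values.columns)]
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise StudyValidationError("expression values must be finite")
        # replicate labels within a mouse must be distinct
        for mouse, grp in self.samples.groupby("mouse", sort=False):
            if grp["replicate"].duplicated().any():
                raise StudyValidationError(
                    f"mouse {mouse!r} has duplicated replicate labels"
                )
        counts = self.samples.groupby("mouse", sort=False).size()
        self.balanced = counts.nunique() == 1
        if not self.balanced:
            warnings.warn("unbalanced design: unequal replicate counts per mouse")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def mice(self) -> list:
        return list(dict.fromkeys(self.samples["mouse"]))

    @property
    def n_mice(self) -> int:
        return len(self.mice)

    @property
    def reps_per_mouse(self) -> int:
        counts = self.samples.groupby("mouse", sort=False).size()
        return int(counts.iloc[0])

    def control_index(self) -> pd.Index:
        mask = self.probes["is_negative_control"].astype(int) == 1
        return self.probes.index[mask]

    def gene_index(self) -> pd.Index:
        """Probes that are not negative controls."""
        mask = self.probes["is_negative_control"].astype(int) == 0
        return self.probes.index[mask]

    def subset_probes(self, probe_ids) -> "ExpressionStudy":
        probe_ids = pd.Index(probe_ids)
        return ExpressionStudy(
            self.values.loc[probe_ids], self.samples.copy(), self.probes.loc[probe_ids]
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionStudy":
        return ExpressionStudy(values, self.samples.copy(), self.probes.copy())

    def mouse_means(self) -> pd.DataFrame:
        """Per-mouse replicate means, probes x mice (column order = first appearance)."""
        return self.values.T.groupby(self.samples["mouse"], sort=False).mean().T


@dataclass
class DetectionCall:
    """Expression detection against the negative-control distribution."""

    threshold: float
    expressed: pd.Series  # bool, indexed by non-control probe_id
    rule: str

    @property
    def n_expressed(self) -> int:
        return int(self.expressed.sum())


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_study(matrix_path, samples_path, probes_path) -> ExpressionStudy:
    """Read an :class:`ExpressionStudy` from the three standard TSV files."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    probes = pd.read_csv(probes_path, sep="\t", index_col=0)
    values.columns.name = samples.index.name
    if "gene_symbol" in probes.columns:
        probes["gene_symbol"] = probes["gene_symbol"].fillna("").astype(str)
    return ExpressionStudy(values, samples, probes)


def write_study(study: ExpressionStudy, directory) -> None:
    """Write matrix.tsv / samples.tsv / probes.tsv under ``directory``."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study.values.to_csv(directory / "matrix.tsv", sep="\t", index_label="probe_id")
    study.samples.to_csv(directory / "samples.tsv", sep="\t", index_label="sample_id")
    study.probes.to_csv(directory / "probes.tsv", sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Quantile-normalize all columns to the mean of the order statistics.

    After normalization every sample shares the same sorted values.  Tied
    entries within a column receive the mean of the quantile values they span.
    """
    X = study.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    order = np.argsort(X, axis=0, kind="stable")
    target = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        tq = np.empty(n)
        tq[order[:, j]] = target
        col = pd.Series(X[:, j])
        out[:, j] = pd.Series(tq).groupby(col, sort=False).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=study.values.index, columns=study.values.columns)
    return study.with_values(values)


def _huber_location(x: np.ndarray) -> float:
    from statsmodels.robust.scale import Huber

    try:
        loc, _ = Huber()(x)
        return float(loc)
    except Exception:  # degenerate spread: fall back to the median
        return float(np.median(x))


def correct_batch(study: ExpressionStudy, estimator: str = "median") -> ExpressionStudy:
    """Remove per-gene batch location shifts, restoring the global robust level.

    ``estimator`` is ``"median"`` (default, deterministic) or ``"huber"``
    (Huber M-estimator of location).  Batches with a single sample are skipped
    with a warning.
    """
    if "batch" not in study.samples.columns or study.samples["batch"].isna().all():
        warnings.warn("no batch column: batch correction is the identity")
        return study.with_values(study.values.copy())
    if estimator not in ("median", "huber"):
        raise ValueError(f"unknown estimator {estimator!r}")
    X = study.values.to_numpy(dtype=float).copy()
    batches = study.samples["batch"]
    locfun = np.median if estimator == "median" else None
    global_loc = (
        np.median(X, axis=1)
        if estimator == "median"
        else np.array([_huber_location(row) for row in X])
    )
    for b, idx in batches.groupby(batches).groups.items():
        cols = [study.values.columns.get_loc(s) for s in idx]
        if len(cols) < 2:
            warnings.warn(f"batch {b!r} has a single sample; skipped")
            continue
        sub = X[:, cols]
        if estimator == "median":
            loc = np.median(sub, axis=1)
        else:
            loc = np.array([_huber_location(row) for row in sub])
        X[:, cols] = sub - loc[:, None] + global_loc[:, None]
    values = pd.DataFrame(X, index=study.values.index, columns=study.values.columns)
    return study.with_values(values)


def detect_expressed(
    study: ExpressionStudy,
    rule: str = "mouse-mean",
    threshold: float | None = None,
    percentile: float = 95.0,
) -> DetectionCall:
    """Call genes expressed relative to the negative-control distribution.

    The threshold is the ``percentile`` (linear interpolation) of the pooled
    per-mouse mean intensities of the negative-control probes.  Under the
    default ``"mouse-mean"`` rule a gene is expressed when the replicate mean
    of at least one mouse exceeds the threshold; under ``"both-samples"`` both
    replicates of at least one mouse must exceed it individually.
    """
    if rule not in ("mouse-mean", "both-samples"):
        raise ValueError(f"unknown detection rule {rule!r}")
    controls = study.control_index()
    if threshold is None:
        if len(controls) == 0:
            raise ValueError(
                "no negative-control probes: supply an explicit threshold"
            )
        ctrl_means = study.subset_probes(controls).mouse_means().to_numpy().ravel()
        threshold = float(np.percentile(ctrl_means, percentile))
    genes = study.gene_index()
    gene_study = study.subset_probes(genes)
    if rule == "mouse-mean":
        best = gene_study.mouse_means().max(axis=1)
        expressed = best > threshold
    else:
        mins = gene_study.values.T.groupby(study.samples["mouse"], sort=False).min().T
        expressed = mins.max(axis=1) > threshold
    return DetectionCall(threshold=float(threshold), expressed=expressed, rule=rule)


def max_fold_change(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene maximal fold change between animals, on the antilog scale.

    ``max_fc = 2 ** (max_i mean_i - min_i mean_i)`` over per-mouse replicate
    means of the log2 values.
    """
    if study.n_mice < 2:
        raise ValueError("maximal fold change needs at least 2 mice")
    mm = study.mouse_means()
    log_range = mm.max(axis=1) - mm.min(axis=1)
    return pd.DataFrame({"max_fc": np.exp2(log_range)}, index=study.values.index)


def count_fold_changes(fc: pd.DataFrame, thresholds=(1.5, 2.0, 3.0)) -> dict:
    """Counts of genes whose maximal fold change strictly exceeds each threshold."""
    return {t: int((fc["max_fc"] > t).sum()) for t in thresholds}
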