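"""Simulator for nested replicate expression studies with known ground truth.

Emulates the design of a co-housed inbred mouse study: C cages x M mice per
cage x k tissue samples per mouse (default 6 x 2 x 2 = 24 arrays), with
per-gene Gaussian variance components for cage, mouse-within-cage and
within-mouse variation, planted coexpression modules driven by shared latent
factors, negative-control probes, non-expressed background genes, and an
additive two-batch layout.

The generative model for an expressed gene g in sample (cage c, mouse i,
replicate k) is

    y = mu_g + cage_cg + mouse_ig + lambda_g * f + batch_bg + w_ikg

where cage_cg ~ N(0, sigma2_cage), mouse_ig ~ N(0, sigma2_mouse),
w ~ N(0, sigma2_within), batch_bg ~ N(0, batch_effect_sd^2), and f is a
standard-normal latent factor shared by the gene's module (drawn per mouse for
mouse-level modules, per sample for sample-level modules) entering with
loading lambda_g.  Negative controls and non-expressed genes are background
rows: a per-probe baseline drawn N(background_mean, background_sd^2) — the
spread of probe affinities — plus per-sample technical noise with sd
background_noise_sd, plus the batch shift.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data_io import ExpressionStudy, read_study, write_study

LATENT_LEVELS = ("mouse", "sample")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted coexpression module: member count, loading, latent level."""

    size: int
    loading: float
    level: str = "mouse"

    def __post_init__(self):
        if self.level not in LATENT_LEVELS:
            raise ValueError(f"latent level must be one of {LATENT_LEVELS}")
        if self.size < 1:
            raise ValueError("module size must be positive")


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for :func:`simulate_study`.

    Defaults mirror the motivating design: 12 mice in 6 cages, 2 samples per
    mouse (24 arrays), 55% of genes expressed, two processing batches of three
    cages each.  Variances are in log2 units squared and may be scalars or
    per-gene vectors over the expressed genes.
    """

    n_genes: int = 5000
    n_cages: int = 6
    mice_per_cage: int = 2
    reps_per_mouse: int = 2
    sigma2_cage: float | Sequence[float] = 0.01
    sigma2_mouse: float | Sequence[float] = 0.02
    sigma2_within: float | Sequence[float] = 0.05
    gene_mean_range: tuple[float, float] = (7.0, 13.0)
    frac_expressed: float = 0.55
    n_negative_controls: int = 400
    background_mean: float = 6.0
    background_sd: float = 0.3
    background_noise_sd: float = 0.1
    module_spec: tuple[ModuleSpec, ...] = ()
    batch_assignment: dict | None = None  # sample_id -> batch label
    batch_effect_sd: float = 0.1
    tissue: str = "liver"
    seed: int = 0

    @property
    def n_mice(self) -> int:
        return self.n_cages * self.mice_per_cage

    @property
    def n_samples(self) -> int:
        return self.n_mice * self.reps_per_mouse

    @property
    def n_expressed(self) -> int:
        return int(round(self.n_genes * self.frac_expressed))

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_cages < 1 or self.mice_per_cage < 1:
            raise ValueError("counts must be positive")
        if self.reps_per_mouse < 2:
            raise ValueError(
                "reps_per_mouse must be >= 2 for the within component to be identifiable"
            )
        if not 0.0 <= self.frac_expressed <= 1.0:
            raise ValueError("frac_expressed must lie in [0, 1]")
        for name in ("sigma2_cage", "sigma2_mouse", "sigma2_within"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if (v < 0).any():
                raise ValueError(f"{name} must be non-negative")
            if v.size not in (1, self.n_genes):
                raise ValueError(
                    f"{name} must be a scalar or a length-{self.n_genes} vector"
                )
        if self.background_sd < 0 or self.batch_effect_sd < 0 or self.background_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        total_module = sum(m.size for m in self.module_spec)
        if total_module > self.n_expressed:
            raise ValueError(
                f"module sizes sum to {total_module}, exceeding the "
                f"{self.n_expressed} expressed genes"
            )


@dataclass
class SimulatedStudy:
    """An :class:`ExpressionStudy` plus per-probe ground truth."""

    study: ExpressionStudy
    truth: pd.DataFrame  # one row per probe
    config: SimulationConfig | None = None


def _per_gene(v, n: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    return np.full(n, arr[0]) if arr.size == 1 else arr.copy()


def _default_batches(config: SimulationConfig, samples: pd.DataFrame) -> pd.Series:
    """Two processing blocks: first half of the cages vs the second half."""
    cages = list(dict.fromkeys(samples["cage"]))
    first = set(cages[: (len(cages) + 1) // 2])
    return samples["cage"].map(lambda c: "B1" if c in first else "B2")


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the nested generative model forward; see the module docstring."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    C, mpc, k = config.n_cages, config.mice_per_cage, config.reps_per_mouse
    n_mice, n_samp = config.n_mice, config.n_samples
    G, n_expr, n_ctrl = config.n_genes, config.n_expressed, config.n_negative_controls

    # --- sample metadata --------------------------------------------------
    rows = []
    for c in range(C):
        for m in range(mpc):
            mouse_idx = c * mpc + m
            for r in range(k):
                rows.append(
                    {
                        "sample_id": f"m{mouse_idx + 1:02d}_r{r + 1}",
                        "mouse": f"m{mouse_idx + 1:02d}",
                        "cage": f"c{c + 1}",
                        "replicate": r + 1,
                        "batch": "",
                        "tissue": config.tissue,
                    }
                )
    samples = pd.DataFrame(rows).set_index("sample_id")
    if config.batch_assignment is not None:
        samples["batch"] = samples.index.map(config.batch_assignment)
        if samples["batch"].isna().any():
            missing = samples.index[samples["batch"].isna()][0]
            raise ValueError(f"batch_assignment lacks sample {missing!r}")
    else:
        samples["batch"] = _default_batches(config, samples)

    mouse_of = np.repeat(np.arange(n_mice), k)
    cage_of = np.repeat(np.arange(C), mpc * k)
    batch_labels = list(dict.fromkeys(samples["batch"]))
    batch_of = samples["batch"].map({b: i for i, b in enumerate(batch_labels)}).to_numpy()

    # --- probe metadata ---------------------------------------------------
    gene_ids = [f"P{i + 1:05d}" for i in range(G)]
    ctrl_ids = [f"NC{i + 1:04d}" for i in range(n_ctrl)]
    probes = pd.DataFrame(
        {
            "gene_symbol": [f"G{i + 1:05d}" for i in range(G)] + [""] * n_ctrl,
            "is_negative_control": [0] * G + [1] * n_ctrl,
        },
        index=pd.Index(gene_ids + ctrl_ids, name="probe_id"),
    )

    s2c = _per_gene(config.sigma2_cage, G)
    s2m = _per_gene(config.sigma2_mouse, G)
    s2w = _per_gene(config.sigma2_within, G)

    expressed = np.zeros(G + n_ctrl, dtype=bool)
    expressed[:n_expr] = True

    # --- expression values ------------------------------------------------
    X = np.empty((G + n_ctrl, n_samp))
    lo, hi = config.gene_mean_range
    mu = rng.uniform(lo, hi, size=n_expr)
    cage_eff = rng.normal(0.0, 1.0, size=(n_expr, C)) * np.sqrt(s2c[:n_expr, None])
    mouse_eff = rng.normal(0.0, 1.0, size=(n_expr, n_mice)) * np.sqrt(s2m[:n_expr, None])
    noise = rng.normal(0.0, 1.0, size=(n_expr, n_samp)) * np.sqrt(s2w[:n_expr, None])
    X[:n_expr] = (
        mu[:, None] + cage_eff[:, cage_of] + mouse_eff[:, mouse_of] + noise
    )
    # background rows: a per-probe baseline (probe affinity) with sd
    # background_sd across probes, plus per-sample technical noise
    n_bg = (G - n_expr) + n_ctrl
    baseline = rng.normal(config.background_mean, config.background_sd, n_bg)
    X[n_expr:] = baseline[:, None] + rng.normal(
        0.0, config.background_noise_sd, (n_bg, n_samp)
    )

    # --- planted modules --------------------------------------------------
    module_label = np.array([None] * (G + n_ctrl), dtype=object)
    loading = np.zeros(G + n_ctrl)
    latent_level = np.array([""] * (G + n_ctrl), dtype=object)
    start = 0
    for j, spec in enumerate(config.module_spec):
        members = slice(start, start + spec.size)
        if spec.level == "mouse":
            f = rng.normal(0.0, 1.0, size=n_mice)[mouse_of]
        else:
            f = rng.normal(0.0, 1.0, size=n_samp)
        X[members] += spec.loading * f[None, :]
        module_label[members] = f"mod{j + 1}"
        loading[members] = spec.loading
        latent_level[members] = spec.level
        start += spec.size

    # --- batch shifts (technical: applied to every probe) -----------------
    if config.batch_effect_sd > 0 and len(batch_labels) > 1:
        shifts = rng.normal(0.0, config.batch_effect_sd, (G + n_ctrl, len(batch_labels)))
        X += shifts[:, batch_of]

    values = pd.DataFrame(X, index=probes.index, columns=samples.index)
    truth = pd.DataFrame(
        {
            "sigma2_cage": np.where(expressed, np.concatenate([s2c, np.zeros(n_ctrl)]), 0.0),
            "sigma2_mouse": np.where(expressed, np.concatenate([s2m, np.zeros(n_ctrl)]), 0.0),
            "sigma2_within": np.where(
                expressed,
                np.concatenate([s2w, np.zeros(n_ctrl)]),
                config.background_noise_sd ** 2,
            ),
            "module": module_label,
            "loading": loading,
            "latent_level": latent_level,
            "expressed": expressed,
        },
        index=probes.index,
    )
    study = ExpressionStudy(values, samples, probes)
    return SimulatedStudy(study=study, truth=truth, config=config)


def ground_truth_summary(sim: SimulatedStudy) -> pd.DataFrame:
    """Per-probe true totals and intraclass correlation implied by the truth table.

    A mouse-level latent factor contributes ``loading**2`` to the between-mouse
    variance, a sample-level factor to the within-mouse variance.  The true
    intraclass correlation is between / (between + within); probes with zero
    total variance get NaN.
    """
    t = sim.truth
    mouse_load = np.where(t["latent_level"] == "mouse", t["loading"] ** 2, 0.0)
    sample_load = np.where(t["latent_level"] == "sample", t["loading"] ** 2, 0.0)
    between = t["sigma2_cage"] + t["sigma2_mouse"] + mouse_load
    within = t["sigma2_within"] + sample_load
    total = between + within
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(total > 0, between / total, np.nan)
    return pd.DataFrame(
        {
            "true_between": between,
            "true_within": within,
            "true_total": total,
            "true_icc": icc,
            "module": t["module"],
            "expressed": t["expressed"],
        },
        index=t.index,
    )


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["module_spec"] = [[m.size, m.loading, m.level] for m in config.module_spec]
    d["gene_mean_range"] = list(config.gene_mean_range)
    for name in ("sigma2_cage", "sigma2_mouse", "sigma2_within"):
        v = d[name]
        if isinstance(v, np.ndarray):
            d[name] = [float(x) for x in v]
    return d


def _config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["module_spec"] = tuple(
        ModuleSpec(int(s), float(l), str(lv)) for s, l, lv in d.get("module_spec", [])
    )
    d["gene_mean_range"] = tuple(d.get("gene_mean_range", (7.0, 13.0)))
    return SimulationConfig(**d)


def write_fixture(sim: SimulatedStudy, directory) -> None:
    """Write matrix/samples/probes/truth TSVs (and config.yaml) to a directory."""
    directory = Path(directory)
    write_study(sim.study, directory)
    sim.truth.to_csv(directory / "truth.tsv", sep="\t", index_label="probe_id")
    if sim.config is not None:
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(_config_to_dict(sim.config), fh, sort_keys=False)


TRUTH_COLUMNS = (
    "sigma2_cage",
    "sigma2_mouse",
    "sigma2_within",
    "module",
    "loading",
    "latent_level",
    "expressed",
)


def read_fixture(directory) -> SimulatedStudy:
    """Read a fixture directory back into a :class:`SimulatedStudy`."""
    directory = Path(directory)
    study = read_study(
        directory / "matrix.tsv", directory / "samples.tsv", directory / "probes.tsv"
    )
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", index_col=0)
    for col in TRUTH_COLUMNS:
        if col not in truth.columns:
            raise ValueError(f"truth.tsv is missing column {col!r}")
    truth["module"] = truth["module"].where(truth["module"].notna(), None)
    truth["latent_level"] = truth["latent_level"].fillna("")
    config = None
    cfg_path = directory / "config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = _config_from_dict(yaml.safe_load(fh))
    return SimulatedStudy(study=study, truth=truth, config=config)
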