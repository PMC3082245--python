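"""End-to-end pipeline: ingest/simulate -> normalize -> detect -> variance
analysis -> coexpression modules -> profile similarity -> enrichment, with
summary tables of study-wide variability and per-module highlights.

Stage order is fixed: quantile normalization, batch correction, expression
detection, total-variance ranking / variable genes, variance decomposition and
significance, network + module detection, eigengene profile correlations, and
gene-set enrichment.  All randomness flows from one top-level seed, so a given
config produces byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import UNASSIGNED, build_network, detect_modules
from .data_io import (
    ExpressionStudy,
    correct_batch,
    count_fold_changes,
    detect_expressed,
    max_fold_change,
    quantile_normalize,
    read_study,
)
from .enrichment_overlap import collapse_probes, hypergeom_enrich, read_gmt
from .profile_similarity import (
    eigengene_correlation_table,
    module_icc,
)
from .synthetic_data import SimulationConfig, _config_from_dict, simulate_study
from .variance_components import (
    alpha_counts,
    decompose_cage,
    estimate_pi0,
    variance_analysis,
)

logger = logging.getLogger("nestvar")


@dataclass
class PipelineConfig:
    """Everything :func:`run_pipeline` needs; read from YAML via :meth:`from_yaml`."""

    # input: either three TSV paths or a simulation config
    matrix: str | None = None
    samples: str | None = None
    probes: str | None = None
    simulation: SimulationConfig | None = None
    # preprocessing
    quantile_normalize: bool = True
    batch_correct: bool = True
    detection_rule: str = "mouse-mean"
    # analysis
    n_variable: int = 2500
    alphas: tuple = (0.05, 0.01, 1e-4)
    fc_thresholds: tuple = (1.5, 2.0, 3.0)
    n_perm: int = 1000
    seed: int = 0
    min_module_size: int = 25
    merge_threshold: float = 0.8
    deep_split: int = 2
    fisher_reference: str = "t9"
    gmt_paths: dict = field(default_factory=dict)  # source tag -> path
    output_dir: str = "nestvar_out"

    def validate(self) -> None:
        if self.simulation is None and not (self.matrix and self.samples and self.probes):
            raise ValueError("config needs either input paths or a simulation block")
        if list(self.fc_thresholds) != sorted(self.fc_thresholds) or min(
            self.fc_thresholds
        ) <= 0:
            raise ValueError("fold-change thresholds must be positive and increasing")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = _config_from_dict(sim)
        for name in ("alphas", "fc_thresholds"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _fmt_count_pct(count: int, total: int) -> str:
    pct = _round_half_away(100.0 * count / total) if total else 0
    return f"{count}({pct}%)"


def table1_summary(
    detection,
    varcomp: pd.DataFrame,
    fold_changes: pd.DataFrame,
    total_probes: int,
    alphas=(0.05, 0.01, 1e-4),
    fc_thresholds=(1.5, 2.0, 3.0),
) -> pd.DataFrame:
    """Study-wide variability summary: expressed genes, variable genes by
    chi-square level, between-mouse significance (FWER / FDR / 1 - pi0), and
    maximal fold change counts.  Percentages are relative to the probe total,
    rounded half away from zero."""
    rows = []
    rows.append(("A", "expressed_genes", _fmt_count_pct(detection.n_expressed, total_probes)))
    expressed_idx = detection.expressed.index[detection.expressed]
    chi2_p = varcomp.loc[varcomp.index.isin(expressed_idx), "chi2_p"]
    for a, cnt in alpha_counts(chi2_p, alphas).items():
        rows.append(("B", f"variable_alpha_{a:g}", _fmt_count_pct(cnt, total_probes)))
    fwer = int((varcomp["p_sidak"] < 0.05).sum())
    fdr = int((varcomp["q_bh"] < 0.10).sum())
    rows.append(("C", "fwer_p<0.05", _fmt_count_pct(fwer, total_probes)))
    rows.append(("C", "fdr_p<0.10", _fmt_count_pct(fdr, total_probes)))
    pi0 = estimate_pi0(varcomp["p_perm"].dropna())
    rows.append(("C", "1-pi0", f"{_round_half_away(100 * (1 - pi0))}%"))
    for t, cnt in count_fold_changes(fold_changes, fc_thresholds).items():
        rows.append(("D", f"max_fc>{t:g}", _fmt_count_pct(cnt, total_probes)))
    return pd.DataFrame(rows, columns=["block", "row", "value"])


def table2_summary(
    module_set,
    enrichment: pd.DataFrame | None,
    icc: pd.Series,
) -> pd.DataFrame:
    """Per-module highlights: top enrichment category per module (across all
    collections) and the median intraclass correlation ``c``."""
    rows = []
    for label, mod in module_set.modules.items():
        c = module_icc(icc, mod.genes)
        row = {
            "module": label,
            "size": len(mod.genes),
            "varexp": mod.varexp,
            "database": "",
            "category": "no enrichment",
            "in_module": len(mod.genes),
            "in_category": 0,
            "overlap": 0,
            "percent": 0.0,
            "p_value": np.nan,
            "c": c,
        }
        if enrichment is not None and not enrichment.empty:
            sub = enrichment[
                (enrichment["module"] == label) & (enrichment["overlap"] >= 1)
            ]
            if not sub.empty:
                best = sub.sort_values(
                    ["p_hyper", "category"], kind="stable"
                ).iloc[0]
                row.update(
                    {
                        "database": best["source"],
                        "category": best["category"],
                        "in_module": int(best["in_module"]),
                        "in_category": int(best["in_category"]),
                        "overlap": int(best["overlap"]),
                        "percent": float(best["percent"]),
                        "p_value": float(best["p_hyper"]),
                    }
                )
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the report directory; returns its path."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> Path:
    logger.info("nestvar %s, seed %d", __version__, config.seed)
    logger.info("config: %s", dataclasses.asdict(config))

    # --- ingest -----------------------------------------------------------
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        study = simulate_study(sim_cfg).study
        logger.info("simulated study: %d probes x %d samples", study.n_probes, study.n_samples)
    else:
        study = read_study(config.matrix, config.samples, config.probes)
        logger.info("read study: %d probes x %d samples", study.n_probes, study.n_samples)

    # --- preprocess ---------------------------------------------------------
    if config.quantile_normalize:
        study = quantile_normalize(study)
        logger.info("quantile normalization applied")
    if config.batch_correct:
        study = correct_batch(study)
        logger.info("batch correction applied (median estimator)")

    # --- detection ----------------------------------------------------------
    detection = detect_expressed(study, rule=config.detection_rule)
    logger.info(
        "detection rule %s: threshold %.4f, %d expressed",
        detection.rule, detection.threshold, detection.n_expressed,
    )
    expressed_idx = detection.expressed.index[detection.expressed]

    # --- variance analysis ---------------------------------------------------
    gene_study = study.subset_probes(study.gene_index())
    n_variable = config.n_variable
    if n_variable > len(expressed_idx):
        logger.warning(
            "n_variable %d exceeds expressed count %d: clamped",
            n_variable, len(expressed_idx),
        )
        n_variable = len(expressed_idx)
    varcomp = variance_analysis(
        gene_study,
        expressed=expressed_idx,
        n_variable=n_variable,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    try:
        cage = decompose_cage(gene_study)
        varcomp = varcomp.join(cage[["s2_cage", "s2_mouse_in_cage", "p_cage", "p_mouse_in_cage"]])
    except ValueError as exc:
        logger.warning("cage decomposition skipped: %s", exc)
    varcomp.to_csv(outdir / "varcomp.tsv", sep="\t", index_label="probe_id")

    fc = max_fold_change(gene_study)
    t1 = table1_summary(
        detection, varcomp, fc, gene_study.n_probes, config.alphas, config.fc_thresholds
    )
    t1.to_csv(outdir / "summary_table1.tsv", sep="\t", index=False)

    # --- network / modules ---------------------------------------------------
    variable_idx = varcomp.index[varcomp["is_variable"]]
    network = build_network(study.values.loc[variable_idx])
    module_set = detect_modules(
        network,
        study.values.loc[variable_idx],
        min_size=config.min_module_size,
        merge_threshold=config.merge_threshold,
        deep_split=config.deep_split,
    )
    logger.info("detected %d modules over %d variable genes", len(module_set.modules), len(variable_idx))

    mod_rows = []
    for label, mod in module_set.modules.items():
        for g in mod.genes:
            x = study.values.loc[g].to_numpy(dtype=float)
            e = mod.eigengene.to_numpy(dtype=float)
            r = float(np.corrcoef(x, e)[0, 1]) if x.std() > 0 else np.nan
            mod_rows.append({"gene": g, "module": label, "r_eigengene": r})
    for g in module_set.assignment.index[module_set.assignment == UNASSIGNED]:
        mod_rows.append({"gene": g, "module": UNASSIGNED, "r_eigengene": np.nan})
    pd.DataFrame(mod_rows).to_csv(outdir / "modules.tsv", sep="\t", index=False)

    eig = pd.DataFrame(
        {label: mod.eigengene for label, mod in module_set.modules.items()}
    ).T
    eig.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="module")

    pd.DataFrame(
        [
            {
                "module": label,
                "size": len(mod.genes),
                "varexp": mod.varexp,
                "median_icc": module_icc(varcomp["icc"], mod.genes),
            }
            for label, mod in module_set.modules.items()
        ]
    ).to_csv(outdir / "module_summary.tsv", sep="\t", index=False)

    # --- profile similarity ----------------------------------------------------
    tissue = study.samples["tissue"].iloc[0] if "tissue" in study.samples.columns else "study"
    pair_table = eigengene_correlation_table(
        {tissue: module_set}, {tissue: study.samples}, reference=config.fisher_reference
    )
    pair_table.to_csv(outdir / "eigengene_correlations.tsv", sep="\t", index=False)

    # --- enrichment -------------------------------------------------------------
    enrichment = None
    if config.gmt_paths:
        symbol_map = collapse_probes(gene_study.probes, varcomp["s2_total"])
        variable_symbols = symbol_map.loc[symbol_map.index.isin(variable_idx)]
        frames = []
        for source, path in sorted(config.gmt_paths.items()):
            coll = read_gmt(path, source=source)
            db_genes = set().union(*coll.sets.values()) if coll.sets else set()
            universe = [s for s in variable_symbols if s in db_genes]
            if not universe:
                logger.warning("no variable genes present in collection %s", source)
                continue
            for label, mod in module_set.modules.items():
                subsets = {
                    "": mod.genes,
                    "+": mod.positive_set,
                    "-": mod.negative_set,
                }
                for tag, members in subsets.items():
                    syms = [
                        variable_symbols[g] for g in members if g in variable_symbols.index
                    ]
                    syms = [s for s in syms if s in db_genes]
                    if not syms:
                        continue
                    res = hypergeom_enrich(
                        syms, universe, coll, label=label + tag
                    )
                    frames.append(res)
        if frames:
            enrichment = pd.concat(frames, ignore_index=True)
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    if enrichment is None:
        pd.DataFrame(
            columns=["module", "source", "category", "in_module", "in_category",
                     "overlap", "percent", "p_hyper"]
        ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    base_enrich = None
    if enrichment is not None:
        base_enrich = enrichment[~enrichment["module"].str.endswith(("+", "-"))]
    t2 = table2_summary(module_set, base_enrich, varcomp["icc"])
    t2.to_csv(outdir / "summary_table2.tsv", sep="\t", index=False)

    logger.info("pipeline complete: %s", outdir)
    return outdir
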