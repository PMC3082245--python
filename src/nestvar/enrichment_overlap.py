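"""Hypergeometric gene-set enrichment, module overlap, and cross-platform maps.

Enrichment of a module (or its positively / negatively correlated subset) in a
gene-set collection uses the upper-tail hypergeometric probability
P(X >= overlap) with population the user-defined universe, after collapsing
probes to one per gene symbol (the probe with the largest total variance).
Module overlap across tissues uses the same test with a Bonferroni correction.
Cross-platform comparison maps each probe to the same-symbol probe on the
other platform with the highest correlation over shared samples (after an
intensity filter) and correlates module eigengenes recomputed on the second
platform against the originals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ModuleSet, eigengene
from .data_io import ExpressionStudy


@dataclass
class GeneSetCollection:
    sets: dict  # name -> frozenset of uppercase symbols
    descriptions: dict = field(default_factory=dict)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def _norm(genes) -> frozenset:
    return frozenset(str(g).upper() for g in genes if str(g))


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = _norm(fields[2:])
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=source)


def collapse_probes(probes: pd.DataFrame, s2_total: pd.Series) -> pd.Series:
    """One probe per gene symbol: keep the probe with the largest total variance.

    Returns a Series mapping the retained probe_id to its uppercase symbol;
    probes without a symbol are dropped.
    """
    symbols = probes["gene_symbol"].astype(str).str.upper()
    df = pd.DataFrame({"symbol": symbols, "s2": s2_total.reindex(probes.index)})
    df = df[df["symbol"] != ""]
    df = df.sort_values(["symbol", "s2"], ascending=[True, False], kind="stable")
    kept = df[~df["symbol"].duplicated()]
    return kept["symbol"]


def hypergeom_enrich(
    genes,
    universe,
    collection: GeneSetCollection,
    label: str = "",
    ease: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``genes`` within ``universe``.

    Columns mirror the conventional layout: in_module, in_category, overlap,
    percent (overlap / in_category * 100) and p_hyper.  ``ease=True`` applies
    the conservative EASE variant (overlap reduced by one).
    """
    uni = _norm(universe)
    if not uni:
        raise ValueError("empty universe")
    g = _norm(genes) & uni
    N, n = len(uni), len(g)
    rows = []
    for name, raw_members in collection.sets.items():
        members = _norm(raw_members)
        K = len(members & uni)
        ov = len(members & g)
        eff = max(ov - 1, 0) if ease else ov
        p = 1.0 if K == 0 else float(stats.hypergeom.sf(eff - 1, N, K, n))
        rows.append(
            {
                "module": label,
                "source": collection.source,
                "category": name,
                "in_module": n,
                "in_category": K,
                "overlap": ov,
                "percent": 100.0 * ov / K if K else 0.0,
                "p_hyper": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)


def module_overlap(genes_a, genes_b, universe, n_tests: int = 1) -> dict:
    """Hypergeometric overlap test of two gene sets with Bonferroni correction."""
    uni = _norm(universe)
    if not uni:
        raise ValueError("empty universe")
    a, b = _norm(genes_a) & uni, _norm(genes_b) & uni
    ov = len(a & b)
    p = float(stats.hypergeom.sf(ov - 1, len(uni), len(a), len(b)))
    p = min(p, 1.0)
    p_adj = min(1.0, p * n_tests)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "overlap": ov,
        "p_hyper": p,
        "p_bonferroni": p_adj,
        "significant": p_adj < 0.05,
    }


def shared_enrichment(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    category: str,
    min_overlap: int = 4,
    p_cut: float = 0.01,
) -> tuple[bool, str]:
    """Shared-enrichment rule: >= ``min_overlap`` genes of the category in each
    module and enrichment p < ``p_cut`` in both.  Returns (flag, note)."""
    rows = []
    for res, tag in ((results_a, "A"), (results_b, "B")):
        hit = res[res["category"] == category]
        if hit.empty:
            return False, f"category {category!r} missing from result {tag}"
        rows.append(hit.iloc[0])
    ok = all(r["overlap"] >= min_overlap and r["p_hyper"] < p_cut for r in rows)
    return ok, ""


# ---------------------------------------------------------------------------
# cross-platform comparison
# ---------------------------------------------------------------------------

@dataclass
class CrossPlatformMap:
    pairs: pd.DataFrame  # probe_a, probe_b, gene_symbol, r
    exclusions: pd.DataFrame  # probe_a, reason


def map_platforms(
    study_a: ExpressionStudy,
    study_b: ExpressionStudy,
    min_intensity_b: float = 7.0,
) -> CrossPlatformMap:
    """Map each platform-A probe to one same-symbol platform-B probe.

    Platform-B candidates with mean intensity below ``min_intensity_b`` are
    excluded; among the rest the candidate with the highest Pearson
    correlation to the A probe across shared samples wins, ties broken by
    probe identifier order.
    """
    shared = [s for s in study_a.values.columns if s in study_b.values.columns]
    if not shared:
        raise ValueError("studies share no samples")
    sym_b = study_b.probes["gene_symbol"].astype(str).str.upper()
    mean_b = study_b.values[shared].mean(axis=1)
    bright = mean_b >= min_intensity_b
    by_symbol: dict = {}
    for pid, sym in sym_b.items():
        if sym:
            by_symbol.setdefault(sym, []).append(pid)
    Xb = study_b.values[shared]
    pairs, exclusions = [], []
    for pid_a, sym in study_a.probes["gene_symbol"].astype(str).str.upper().items():
        if study_a.probes.loc[pid_a, "is_negative_control"]:
            continue
        cands = sorted(by_symbol.get(sym, []))
        if not sym or not cands:
            exclusions.append({"probe_a": pid_a, "reason": "no symbol match"})
            continue
        cands = [c for c in cands if bright[c]]
        if not cands:
            exclusions.append({"probe_a": pid_a, "reason": "intensity filter"})
            continue
        xa = study_a.values.loc[pid_a, shared].to_numpy(dtype=float)
        best, best_r = None, -np.inf
        for c in cands:
            xb = Xb.loc[c].to_numpy(dtype=float)
            if xa.std() == 0 or xb.std() == 0:
                r = -np.inf
            else:
                r = float(np.corrcoef(xa, xb)[0, 1])
            if r > best_r:
                best, best_r = c, r
        pairs.append(
            {"probe_a": pid_a, "probe_b": best, "gene_symbol": sym, "r": best_r}
        )
    return CrossPlatformMap(
        pairs=pd.DataFrame(pairs, columns=["probe_a", "probe_b", "gene_symbol", "r"]),
        exclusions=pd.DataFrame(exclusions, columns=["probe_a", "reason"]),
    )


def cross_platform_eigengenes(
    cpmap: CrossPlatformMap,
    modules: ModuleSet,
    study_b: ExpressionStudy,
    min_mapped: int = 3,
) -> pd.DataFrame:
    """Recompute each module's eigengene on platform B and correlate with A's.

    Modules with fewer than ``min_mapped`` mapped member genes are skipped
    (noted in the output).  The correlation is computed over shared samples
    with each platform's own majority-sign convention.
    """
    mapping = dict(zip(cpmap.pairs["probe_a"], cpmap.pairs["probe_b"]))
    rows = []
    for label, mod in modules.modules.items():
        mapped = [mapping[g] for g in mod.genes if g in mapping]
        mapped = list(dict.fromkeys(mapped))
        if len(mapped) < min_mapped:
            rows.append(
                {"module": label, "n_mapped": len(mapped), "r": np.nan,
                 "note": "skipped: too few mapped genes"}
            )
            continue
        shared = [s for s in mod.eigengene.index if s in study_b.values.columns]
        prof_b, _, _, _ = eigengene(study_b.values[shared], mapped)
        ea = mod.eigengene.loc[shared].to_numpy(dtype=float)
        eb = prof_b.to_numpy(dtype=float)
        r = float(np.corrcoef(ea, eb)[0, 1])
        rows.append({"module": label, "n_mapped": len(mapped), "r": r, "note": ""})
    return pd.DataFrame(rows, columns=["module", "n_mapped", "r", "note"])
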