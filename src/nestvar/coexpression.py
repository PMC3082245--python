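"""Weighted coexpression network, module detection and module eigengenes.

Gene pairs are connected by the square of their Pearson correlation across all
samples (an unsigned network with soft power 2).  Node similarity is the
unsigned topological overlap

    TOM_ij = ( sum_{u != i,j} a_iu a_uj + a_ij ) / ( min(k_i, k_j) + 1 - a_ij )

with k_i the connectivity of node i.  Modules are branches of an
average-linkage dendrogram on 1 - TOM, extracted by a deterministic
branch-adaptive cut, filtered by a minimum size, and merged while any two
module eigengenes correlate above a threshold.  The module eigengene is the
first principal component of the gene-standardized module submatrix, signed so
that the majority of member genes correlate positively with it, and rescaled
to the median per-gene variance of the members.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

#: Conventional module colour order by decreasing size.  "gold" takes the
#: slot usually called "yellow".
MODULE_COLOURS = (
    "turquoise", "blue", "brown", "gold", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange",
)

UNASSIGNED = "grey"

#: Required relative height gap for splitting a dendrogram branch, by
#: deep-split level (larger level = more aggressive splitting).
DEEP_SPLIT_GAP = {0: 0.15, 1: 0.10, 2: 0.05, 3: 0.02}


@dataclass
class CoexpressionNetwork:
    genes: pd.Index
    adjacency: np.ndarray  # squared Pearson correlation, diag 1
    tom: np.ndarray  # topological overlap, diag 1


@dataclass
class Module:
    label: str
    genes: list
    eigengene: pd.Series  # profile over samples
    varexp: float
    positive_set: list
    negative_set: list


@dataclass
class ModuleSet:
    assignment: pd.Series  # gene -> colour label or UNASSIGNED
    modules: dict = field(default_factory=dict)  # label -> Module

    @property
    def labels(self) -> list:
        return list(self.modules)

    def members(self, label: str) -> list:
        return self.modules[label].genes


def build_network(values: pd.DataFrame) -> CoexpressionNetwork:
    """Adjacency (r^2) and topological overlap over genes (rows of ``values``)."""
    X = values.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("network construction needs at least 3 samples")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = values.index[np.where(sd == 0)[0][0]]
        raise ValueError(f"constant gene {bad!r}: remove before network construction")
    r = np.corrcoef(X)
    adj = np.clip(r * r, 0.0, 1.0)
    np.fill_diagonal(adj, 1.0)
    return CoexpressionNetwork(
        genes=values.index, adjacency=adj, tom=topological_overlap(adj)
    )


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Unsigned TOM of an adjacency matrix with unit diagonal."""
    a = adj.copy()
    np.fill_diagonal(a, 1.0)
    shared = a @ a - 2.0 * a  # sum over u != i,j of a_iu * a_uj
    k = a.sum(axis=1) - 1.0
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# eigengene
# ---------------------------------------------------------------------------

def eigengene(values: pd.DataFrame, module_genes) -> tuple[pd.Series, float, list, list]:
    """First principal component of a module with sign and scale conventions.

    Returns ``(profile, varexp, positive_set, negative_set)``.  The profile is
    signed so that the (strict) majority of member genes correlate positively
    with it — a tie takes the sign that makes the sum of correlations
    positive — and rescaled so its variance equals the median per-gene variance
    of the members.
    """
    genes = list(module_genes)
    if len(genes) == 0:
        raise ValueError("empty module")
    X = values.loc[genes].to_numpy(dtype=float)
    var = X.var(axis=1, ddof=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    if len(genes) == 1:
        prof = pd.Series(Xc[0], index=values.columns)
        return prof, 1.0, genes, []
    sd = np.sqrt(var)
    if (sd == 0).any():
        raise ValueError("constant gene in module")
    Xs = Xc / sd[:, None]
    _, s, vt = np.linalg.svd(Xs, full_matrices=False)
    profile = vt[0]
    varexp = float(s[0] ** 2 / (s ** 2).sum())
    # correlations of members with the profile
    pc = profile - profile.mean()
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(pc)
    corr = (Xc @ pc) / denom
    npos, nneg = int((corr > 0).sum()), int((corr < 0).sum())
    flip = nneg > npos or (nneg == npos and corr.sum() < 0)
    if flip:
        profile, corr = -profile, -corr
    med_var = float(np.median(var))
    pvar = profile.var(ddof=1)
    if pvar > 0 and med_var > 0:
        profile = profile * np.sqrt(med_var / pvar)
    prof = pd.Series(profile, index=values.columns)
    positive = [g for g, c in zip(genes, corr) if c >= 0]
    negative = [g for g, c in zip(genes, corr) if c < 0]
    return prof, varexp, positive, negative


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _adaptive_cut(
    Z: np.ndarray, min_size: int, gap_frac: float, cut_quantile: float = 0.99
):
    """Hybrid top-down dendrogram cut.

    Joins above ``cut_quantile`` times the root height are always broken (this
    detaches top-level stragglers, which average linkage chains onto the last
    merges); below that height a branch is split only when both children
    exceed ``min_size`` members and the join-height gap is at least
    ``gap_frac`` of the branch height (so homogeneous branches stay whole).
    """
    root = to_tree(Z)
    h0 = cut_quantile * root.dist
    clusters = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            clusters.append([node.id])
            continue
        left, right = node.get_left(), node.get_right()
        child_h = max(left.dist, right.dist)
        splittable = node.dist > h0 or (
            min(left.get_count(), right.get_count()) > min_size
            and node.dist > 0
            and (node.dist - child_h) >= gap_frac * node.dist
        )
        if splittable:
            stack.extend([left, right])
        else:
            clusters.append(node.pre_order(lambda x: x.id))
    return clusters


def detect_modules(
    network: CoexpressionNetwork,
    values: pd.DataFrame,
    min_size: int = 25,
    merge_threshold: float = 0.8,
    deep_split: int = 2,
    gap_frac: float | None = None,
    cut_quantile: float = 0.99,
) -> ModuleSet:
    """Detect coexpression modules on the TOM dendrogram.

    Average-linkage clustering on 1 - TOM; branches are extracted by the
    adaptive cut, clusters with ``min_size`` or fewer members are dissolved to
    unassigned, and modules whose eigengenes correlate above
    ``merge_threshold`` are merged iteratively.  Labels follow the
    conventional colour order by decreasing module size.  Deterministic for
    identical input and parameters.
    """
    genes = network.genes
    if len(genes) <= min_size:
        warnings.warn("fewer genes than min_size: no modules")
        return ModuleSet(
            assignment=pd.Series(UNASSIGNED, index=genes, name="module"), modules={}
        )
    if gap_frac is None:
        gap_frac = DEEP_SPLIT_GAP[int(deep_split)]
    diss = 1.0 - network.tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    Z = linkage(squareform(diss, checks=False), method="average")
    clusters = _adaptive_cut(Z, min_size, gap_frac, cut_quantile)
    groups = [list(genes[c]) for c in clusters if len(c) > min_size]

    # iterative eigengene merge
    values = values.loc[genes]
    while len(groups) > 1:
        eigs = np.array([eigengene(values, g)[0].to_numpy() for g in groups])
        R = np.corrcoef(eigs)
        np.fill_diagonal(R, -np.inf)
        i, j = np.unravel_index(np.argmax(R), R.shape)
        if R[i, j] <= merge_threshold:
            break
        a, b = sorted((i, j))
        groups[a] = groups[a] + groups[b]
        del groups[b]

    groups.sort(key=lambda g: (-len(g), str(g[0])))
    assignment = pd.Series(UNASSIGNED, index=genes, name="module")
    modules: dict[str, Module] = {}
    for rank, members in enumerate(groups):
        label = (
            MODULE_COLOURS[rank]
            if rank < len(MODULE_COLOURS)
            else f"module{rank + 1}"
        )
        prof, varexp, pos, neg = eigengene(values, members)
        modules[label] = Module(
            label=label,
            genes=members,
            eigengene=prof,
            varexp=varexp,
            positive_set=pos,
            negative_set=neg,
        )
        assignment.loc[members] = label
    return ModuleSet(assignment=assignment, modules=modules)
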