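"""Weighted co-expression network analysis: soft threshold, TOM, modules, eigengenes.

The adjacency between genes i and j is |Pearson r|^beta (unsigned
network).  The topological overlap measure (TOM) augments adjacency with
shared-neighbor structure,

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu * a_uj,

and 1 - omega is the dissimilarity clustered (average linkage, static
tree cut) into modules.  Each module is summarized by its eigengene, the
first principal component of the standardized member-gene expression,
sign-oriented so its mean correlation with the member genes is positive.
Modules whose eigengenes are highly correlated are merged; eigengenes
are then correlated against sample traits such as the GMT score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy import stats

from .core_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SoftThresholdReport",
    "ModuleAssignment",
    "EigengeneMatrix",
    "pick_soft_threshold",
    "compute_adjacency",
    "compute_tom",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "module_trait_correlation",
    "top_module_for_trait",
]


@dataclass
class SoftThresholdReport:
    table: pd.DataFrame  # columns: beta, r2, mean_connectivity
    selected_beta: float
    reached_target: bool


@dataclass
class ModuleAssignment:
    """Gene -> integer module label; 0 marks unassigned ('grey') genes."""

    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)

    @property
    def module_ids(self) -> list[int]:
        return sorted(l for l in self.labels.unique() if l != 0)

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}


@dataclass
class EigengeneMatrix:
    """Module x sample eigengene values, unit variance, sign-oriented."""

    data: pd.DataFrame


def _gene_correlation(expr: ExpressionMatrix) -> np.ndarray:
    X = expr.values
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
        raise ValueError(f"constant-expression genes (correlation undefined): {bad[:10]}")
    return np.corrcoef(X)


def compute_adjacency(expr: ExpressionMatrix, beta: float) -> np.ndarray:
    """Unsigned weighted adjacency |cor|^beta with unit diagonal."""
    a = np.abs(_gene_correlation(expr)) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(freq) vs log10(k) over connectivity bins (scale-free fit)."""
    counts, edges = np.histogram(k, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = (counts > 0) & (centers > 0)
    if keep.sum() < 3:
        return 0.0
    x = np.log10(centers[keep])
    y = np.log10(counts[keep])
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    betas=tuple(range(1, 21)),
    target_r2: float = 0.8,
) -> SoftThresholdReport:
    """Scan candidate powers and pick the smallest reaching the scale-free target.

    When no candidate reaches ``target_r2`` the argmax is returned with a
    warning — the typical outcome on structureless data.
    """
    if expr.shape[0] < 20:
        raise ValueError("need >=20 genes for soft-threshold selection")
    corr = np.abs(_gene_correlation(expr))
    rows = []
    for beta in betas:
        a = corr ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append({"beta": beta, "r2": _scale_free_r2(k), "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["r2"] >= target_r2]
    if len(ok):
        selected = float(ok.iloc[0]["beta"])
        reached = True
    else:
        selected = float(table.loc[table["r2"].idxmax(), "beta"])
        reached = False
        logger.warning(
            "no candidate power reached scale-free R2 %.2f; falling back to beta=%g "
            "(R2=%.3f)", target_r2, selected, table["r2"].max(),
        )
    return SoftThresholdReport(table=table, selected_beta=selected, reached_target=reached)


def compute_tom(expr: ExpressionMatrix, beta: float) -> pd.DataFrame:
    """Topological overlap matrix (unit diagonal), as a gene x gene frame."""
    a = compute_adjacency(expr, beta)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    l = a0 @ a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    tom = (l + a0) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=expr.gene_ids, columns=expr.gene_ids)


def detect_modules(
    tom_dissimilarity: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.995,
) -> ModuleAssignment:
    """Average-linkage clustering of 1-TOM, static cut, small clusters unassigned.

    Module labels are integers ordered by decreasing module size; label 0
    marks genes in clusters smaller than ``min_module_size``.
    """
    d = tom_dissimilarity.to_numpy()
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    genes = list(tom_dissimilarity.index)
    link = average(squareform(d, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(0, index=genes, dtype=int)
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    # relabel kept clusters 1..K by decreasing size (ties by original id)
    ordered = sorted(keep, key=lambda c: (-sizes[c], c))
    for new, old in enumerate(ordered, start=1):
        labels[np.asarray(raw) == old] = new
    return ModuleAssignment(labels)


def _first_pc(block: np.ndarray) -> np.ndarray:
    """First right singular vector (across samples) of a genes x samples block."""
    u, s, vt = np.linalg.svd(block, full_matrices=False)
    return vt[0]


def module_eigengenes(expr: ExpressionMatrix, assignment: ModuleAssignment) -> EigengeneMatrix:
    """Eigengene per module: first PC of standardized member expression.

    Eigengenes are scaled to unit variance and sign-oriented so the mean
    Pearson correlation with their member genes is positive.  A module of
    one gene degrades to the standardized gene itself (with a warning).
    """
    rows = {}
    for module in assignment.module_ids:
        genes = assignment.genes_in(module)
        block = expr.data.loc[genes].to_numpy()
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError(f"constant gene in module {module}")
        z = (block - mu) / sd
        if len(genes) == 1:
            logger.warning("module %d has a single gene; eigengene = standardized gene", module)
            eig = z[0]
        else:
            eig = _first_pc(z)
        eig = eig / eig.std(ddof=1)
        corrs = [np.corrcoef(eig, row)[0, 1] for row in z]
        if np.mean(corrs) < 0:
            eig = -eig
        rows[module] = eig
    data = pd.DataFrame.from_dict(rows, orient="index", columns=expr.sample_ids)
    data.index.name = "module"
    return EigengeneMatrix(data)


def merge_modules(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    merge_height: float = 0.25,
) -> tuple[ModuleAssignment, EigengeneMatrix]:
    """Merge modules whose eigengene dissimilarity (1 - cor) falls below the cut.

    Average-linkage clustering of eigengene dissimilarity; clusters formed
    strictly below ``merge_height`` are unioned and eigengenes recomputed.
    Idempotent: re-running at the same height changes nothing.
    """
    eig = module_eigengenes(expr, assignment)
    modules = list(eig.data.index)
    if len(modules) < 2:
        return assignment, eig
    corr = np.corrcoef(eig.data.to_numpy())
    diss = 1.0 - corr
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2, 0.0, None)
    link = average(squareform(diss, checks=False))
    groups = fcluster(link, t=merge_height - 1e-12, criterion="distance")
    labels = assignment.labels.copy()
    new_of_old = {}
    for grp in sorted(set(groups)):
        members = [m for m, g in zip(modules, groups) if g == grp]
        for m in members:
            new_of_old[m] = min(members)
    labels = labels.map(lambda l: new_of_old.get(l, 0))
    # renumber by size
    merged = ModuleAssignment(labels)
    sizes = merged.sizes
    ordered = sorted(sizes, key=lambda m: (-sizes[m], m))
    remap = {old: new for new, old in enumerate(ordered, start=1)}
    merged = ModuleAssignment(merged.labels.map(lambda l: remap.get(l, 0)))
    return merged, module_eigengenes(expr, merged)


def module_trait_correlation(
    eigengenes: EigengeneMatrix,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each trait.

    ``traits`` is a sample x trait frame (a GMT score vector, an EMT
    enrichment vector, ...).  Returns a long-format frame with columns
    module, trait, r, p (two-sided t test with n-2 df).
    """
    common = [s for s in eigengenes.data.columns if s in traits.index]
    if len(common) < 3:
        raise ValueError("need >=3 overlapping samples for module-trait correlation")
    eg = eigengenes.data[common]
    tr = traits.loc[common]
    rows = []
    n = len(common)
    for module in eg.index:
        for trait in tr.columns:
            r = float(np.corrcoef(eg.loc[module], tr[trait])[0, 1])
            r_c = min(max(r, -0.9999999999), 0.9999999999)
            t = r_c * np.sqrt((n - 2) / (1 - r_c * r_c))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
            rows.append({"module": module, "trait": trait, "r": r, "p": p})
    return pd.DataFrame(rows)


def top_module_for_trait(corr_table: pd.DataFrame, trait: str) -> int:
    """Module with the strongest positive correlation with the given trait."""
    sub = corr_table[corr_table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not in correlation table")
    return int(sub.loc[sub["r"].idxmax(), "module"])
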