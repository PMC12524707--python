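"""Single-sample gene-set scoring and two-group GSEA.

The glial-mesenchymal-transition (GMT) score of a tumor sample is the
difference between its mesenchymal and proneural single-sample enrichment
scores.  Cohorts are stratified at the median GMT score and the two strata
compared by a permutation-based, weighted Kolmogorov-Smirnov gene-set
enrichment test.

The single-sample statistic is the rank-based ssGSEA running sum: genes
are ranked by expression within each sample, rank positions are weighted
by ``(N - i + 1)**alpha`` and the score is the sum over positions of the
difference between the weighted in-set and unweighted out-of-set
cumulative fractions.  Being rank-based, it is invariant under any
strictly monotone transform of a sample's expression vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "SampleScores",
    "GseaResult",
    "ssgsea_es_single",
    "ssgsea_scores",
    "gmt_score",
    "stratify_by_median",
    "gsea_two_group",
    "immune_enrichment",
]


@dataclass
class SampleScores:
    """Per-sample enrichment scores for one gene set (or derived score)."""

    scores: pd.Series  # indexed by sample id
    set_name: str
    method: str = "ssgsea"

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError(f"non-finite scores for set {self.set_name!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr_q: float
    direction: str  # label of the group the set is enriched in

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.fdr_q <= 1.0):
            raise ValueError("p and q must lie in [0,1]")
        if self.es * self.nes < 0:
            raise ValueError("NES must carry the sign of ES")


def _rank_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices ordering genes by value descending, ties by gene id ascending."""
    return np.lexsort((gene_ids, -values))


def ssgsea_es_single(values: pd.Series, genes, alpha: float = 0.25) -> float:
    """ssGSEA enrichment score of one expression vector for one gene set.

    Genes are ranked descending (ties broken lexicographically by id);
    position ``i`` (1-based) carries weight ``(N - i + 1)**alpha``.  The
    score sums, over all positions, the weighted cumulative in-set
    fraction minus the unweighted cumulative out-of-set fraction.
    """
    gene_ids = np.asarray(values.index.astype(str).str.upper())
    vals = values.to_numpy(dtype=float)
    n = len(vals)
    members = np.isin(gene_ids, [str(g).upper() for g in genes])
    m = int(members.sum())
    if m == 0:
        raise ValueError("gene set does not intersect the expression vector")
    if m == n:
        raise ValueError("gene set covers every gene; out-of-set fraction undefined")
    order = _rank_order(vals, gene_ids)
    hits = members[order]
    weights = (n - np.arange(n)).astype(float) ** alpha  # position i=1..N -> (N-i+1)^alpha
    hit_w = np.where(hits, weights, 0.0)
    p_in = np.cumsum(hit_w) / hit_w.sum()
    p_out = np.cumsum(~hits) / (n - m)
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    rescale: bool = False,
    min_intersect: int = 2,
) -> pd.DataFrame:
    """Score every sample against every gene set; returns a set x sample frame.

    ``rescale=True`` divides all scores by (max - min) over all samples and
    sets, putting cohorts on a comparable scale before subtraction.
    """
    gene_ids = np.asarray(expr.gene_ids)
    n = len(gene_ids)
    missing_report = {}
    masks = {}
    for name, genes in sets.sets.items():
        mask = np.isin(gene_ids, genes)
        m = int(mask.sum())
        if m < min_intersect:
            missing = sorted(set(genes) - set(gene_ids))
            missing_report[name] = missing
            raise ValueError(
                f"set {name!r}: only {m} genes present in matrix "
                f"(need >= {min_intersect}); missing: {missing[:10]}"
            )
        if m == n:
            raise ValueError(f"set {name!r} covers all matrix genes")
        masks[name] = mask

    weights_by_pos = (n - np.arange(n)).astype(float) ** alpha
    out = pd.DataFrame(index=list(sets.sets), columns=expr.sample_ids, dtype=float)
    X = expr.values
    for j, sample in enumerate(expr.sample_ids):
        order = _rank_order(X[:, j], gene_ids)
        for name, mask in masks.items():
            hits = mask[order]
            hit_w = np.where(hits, weights_by_pos, 0.0)
            p_in = np.cumsum(hit_w) / hit_w.sum()
            p_out = np.cumsum(~hits) / (n - hits.sum())
            out.loc[name, sample] = float(np.sum(p_in - p_out))
    if rescale:
        span = out.to_numpy().max() - out.to_numpy().min()
        if span > 0:
            out = out / span
    return out


def gmt_score(
    expr: ExpressionMatrix,
    mes_set,
    pn_set,
    alpha: float = 0.25,
    rescale: bool = False,
) -> SampleScores:
    """GMT score per sample: mesenchymal minus proneural enrichment score."""
    coll = GeneSetCollection({"MES": list(mes_set), "PN": list(pn_set)})
    scored = ssgsea_scores(expr, coll, alpha=alpha, rescale=rescale)
    diff = scored.loc["MES"] - scored.loc["PN"]
    return SampleScores(scores=diff, set_name="GMT", method="ssgsea-diff")


def stratify_by_median(scores: SampleScores) -> pd.Series:
    """Split samples into 'high' (strictly above the median) and 'low' groups."""
    s = scores.scores
    if len(s) < 2:
        raise ValueError("need >=2 samples to stratify")
    if s.nunique() == 1:
        raise ValueError("degenerate stratification: all scores identical")
    med = s.median()
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")


# ---------------------------------------------------------------------------
# two-group GSEA with permutation null
# ---------------------------------------------------------------------------


def _signal_to_noise(X: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Per-gene signal-to-noise ratio (mean_A - mean_B)/(sd_A + sd_B).

    Standard deviations are floored at 0.2*|mean| (0.2 when the mean is
    zero), the classic GSEA stabilization for low-variance genes.
    """
    a, b = X[:, in_a], X[:, ~in_a]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    sa, sb = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    sa = np.maximum(sa, np.where(ma == 0, 0.2, 0.2 * np.abs(ma)))
    sb = np.maximum(sb, np.where(mb == 0, 0.2, 0.2 * np.abs(mb)))
    return (ma - mb) / (sa + sb)


def _batch_es(metric: np.ndarray, set_masks: np.ndarray, gene_ids: np.ndarray,
              weight_p: float) -> np.ndarray:
    """Weighted-KS enrichment score of every set against one ranked metric."""
    order = _rank_order(metric, gene_ids)
    w = np.abs(metric[order]) ** weight_p
    m_ord = set_masks[:, order]
    hit_w = m_ord * w
    sums = hit_w.sum(axis=1, keepdims=True)
    sums = np.where(sums == 0, 1.0, sums)
    p_hit = np.cumsum(hit_w, axis=1) / sums
    sizes = m_ord.sum(axis=1, keepdims=True)
    p_miss = np.cumsum(~m_ord, axis=1) / (len(metric) - sizes)
    dev = p_hit - p_miss
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(dev.shape[0]), idx]


def gsea_two_group(
    expr: ExpressionMatrix,
    labels: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> list[GseaResult]:
    """Two-group GSEA: signal-to-noise ranking, weighted-KS ES, permutation null.

    Phenotype labels are permuted when both groups have >=3 samples;
    otherwise random gene sets of matching size are drawn (gene-set
    permutation).  NES is ES divided by the mean magnitude of same-sign
    permutation scores; nominal p and FDR q follow the same-sign
    convention.  The whole permutation stream is a function of ``seed``.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    labels = labels.reindex(expr.sample_ids)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    X = expr.values
    gene_ids = np.asarray(expr.gene_ids)
    in_a = (labels == groups[0]).to_numpy()
    if np.all(X[:, in_a].std(axis=1) == 0) or np.all(X[:, ~in_a].std(axis=1) == 0):
        raise ValueError("one group has zero variance in every gene")

    set_names = list(sets.sets)
    masks = np.stack([np.isin(gene_ids, sets[name]) for name in set_names])
    if (masks.sum(axis=1) == 0).any():
        empty = [n for n, m in zip(set_names, masks) if m.sum() == 0]
        raise ValueError(f"sets with no genes in the matrix: {empty}")

    metric = _signal_to_noise(X, in_a)
    es_obs = _batch_es(metric, masks, gene_ids, weight_p)

    rng = np.random.default_rng(seed)
    phenotype_perm = in_a.sum() >= 3 and (~in_a).sum() >= 3
    es_perm = np.empty((n_perm, len(set_names)))
    if phenotype_perm:
        for t in range(n_perm):
            perm = rng.permutation(len(labels))
            es_perm[t] = _batch_es(_signal_to_noise(X, in_a[perm]), masks, gene_ids, weight_p)
    else:
        sizes = masks.sum(axis=1)
        n_genes = len(gene_ids)
        for t in range(n_perm):
            rand_masks = np.zeros_like(masks)
            for s, size in enumerate(sizes):
                rand_masks[s, rng.choice(n_genes, size=size, replace=False)] = True
            es_perm[t] = _batch_es(metric, rand_masks, gene_ids, weight_p)

    # same-sign normalization per set
    nes_obs = np.empty_like(es_obs)
    p_vals = np.empty_like(es_obs)
    nes_perm = np.full_like(es_perm, np.nan)
    for s in range(len(set_names)):
        for sign in (1.0, -1.0):
            sel = np.sign(es_perm[:, s]) == sign
            denom = np.abs(es_perm[sel, s]).mean() if sel.any() else np.abs(es_perm[:, s]).mean()
            if denom == 0:
                denom = 1.0
            nes_perm[sel, s] = es_perm[sel, s] / denom
            if np.sign(es_obs[s]) == sign:
                nes_obs[s] = es_obs[s] / denom
                n_same = sel.sum()
                if n_same == 0:
                    p_vals[s] = 1.0 / n_perm
                else:
                    p_vals[s] = np.mean(np.abs(es_perm[sel, s]) >= abs(es_obs[s]))
        if es_obs[s] == 0:
            nes_obs[s] = 0.0
            p_vals[s] = 1.0

    flat_perm = nes_perm[np.isfinite(nes_perm)]
    results = []
    for s, name in enumerate(set_names):
        nes = nes_obs[s]
        if nes > 0:
            num_pool = flat_perm[flat_perm > 0]
            obs_pool = nes_obs[nes_obs > 0]
            num = np.mean(num_pool >= nes) if len(num_pool) else 0.0
            den = np.mean(obs_pool >= nes) if len(obs_pool) else 1.0
        elif nes < 0:
            num_pool = flat_perm[flat_perm < 0]
            obs_pool = nes_obs[nes_obs < 0]
            num = np.mean(num_pool <= nes) if len(num_pool) else 0.0
            den = np.mean(obs_pool <= nes) if len(obs_pool) else 1.0
        else:
            num, den = 1.0, 1.0
        q = min(1.0, num / den) if den > 0 else 1.0
        direction = groups[0] if es_obs[s] >= 0 else groups[1]
        results.append(GseaResult(name, float(es_obs[s]), float(nes), float(p_vals[s]),
                                  float(q), direction))
    return results


def immune_enrichment(
    expr: ExpressionMatrix,
    immune_sets: GeneSetCollection,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Sample x cell-type single-sample enrichment matrix over immune signatures."""
    scores = ssgsea_scores(expr, immune_sets, alpha=alpha)
    return scores.T
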