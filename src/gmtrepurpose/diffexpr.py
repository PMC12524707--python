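"""Two-condition differential expression on counts: NB Wald test, Bonferroni.

A deliberately simple negative-binomial Wald test: library sizes are
normalized by median-of-ratios size factors, per-gene dispersion is a
method-of-moments estimate pooled across the two conditions, and the
log2 fold change is tested with a delta-method standard error against
the standard normal.  Genes pass when the Bonferroni-adjusted p-value is
below 0.05 and log2FC >= 1 (the "upregulated" funnel input).

Dispersion shrinkage, independent filtering and outlier handling of
full-featured DE frameworks are intentionally absent: downstream stages
consume only the up-regulated gene list, and the test is validated by
null calibration and planted-fold-change recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix

__all__ = ["size_factors", "de_test", "select_upregulated"]

LN2 = float(np.log(2.0))


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples, computed
    on genes expressed in every sample; each sample's factor is the
    median ratio of its counts to the reference.
    """
    mat = counts.data.to_numpy(dtype=float)
    expressed_everywhere = (mat > 0).all(axis=1)
    if not expressed_everywhere.any():
        raise ValueError(
            "no gene expressed in all samples; use a pseudo-reference fallback"
        )
    sub = mat[expressed_everywhere]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def _pooled_dispersion(norm: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion alpha by method of moments, pooled within condition.

    For each condition c: alpha_c = (s2_c - mean_c)/mean_c^2; the two
    estimates are averaged weighted by degrees of freedom.  With a
    handful of replicates the per-gene estimate is far too noisy for
    Bonferroni-scale tails, so each gene's dispersion is floored at the
    common (across-gene mean) dispersion — a deliberately conservative
    moderation — and clipped to at most 10.
    """
    alphas = np.zeros(norm.shape[0])
    weights = np.zeros(norm.shape[0])
    for mask in (in_a, ~in_a):
        x = norm[:, mask]
        n = mask.sum()
        mu = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu) / np.square(mu)
        a = np.where(np.isfinite(a), a, 0.0)
        alphas += a * (n - 1)
        weights += n - 1
    per_gene = alphas / weights
    expressed = norm.mean(axis=1) > 0
    common = float(np.clip(per_gene[expressed].mean(), 1e-8, 10.0)) if expressed.any() else 1e-8
    return np.clip(np.maximum(per_gene, common), 1e-8, 10.0)


def de_test(counts: CountMatrix, condition_a: str | None = None) -> pd.DataFrame:
    """NB Wald differential expression of condition A over B.

    ``condition_a`` names the numerator condition (default: first label in
    sorted order).  Genes with all-zero counts are excluded from testing
    and from the Bonferroni denominator; they are returned with
    ``tested=False``.  Returns a frame indexed by gene with columns
    log2fc, se, wald_z, p, padj, base_mean, flag, tested, half_shifted.
    """
    labels = counts.condition_labels
    conds = sorted(labels.unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    cond_a = condition_a if condition_a is not None else conds[0]
    if cond_a not in conds:
        raise ValueError(f"unknown condition {cond_a!r}")
    cond_b = [c for c in conds if c != cond_a][0]
    in_a = (labels == cond_a).to_numpy()

    factors = size_factors(counts).to_numpy()
    norm = counts.data.to_numpy(dtype=float) / factors

    genes = np.asarray(counts.gene_ids)
    nonzero = counts.data.sum(axis=1).to_numpy() > 0
    m = int(nonzero.sum())

    mu_a = norm[:, in_a].mean(axis=1)
    mu_b = norm[:, ~in_a].mean(axis=1)
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    alpha = _pooled_dispersion(norm, in_a)

    log2fc = np.log2((mu_a + 0.5) / (mu_b + 0.5))
    se2 = (1.0 / LN2) ** 2 * (
        (1.0 / n_a) * (1.0 / (mu_a + 0.5) + alpha)
        + (1.0 / n_b) * (1.0 / (mu_b + 0.5) + alpha)
    )
    se = np.sqrt(se2)
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = np.minimum(1.0, p * m)

    half_shifted = (mu_a == 0) | (mu_b == 0)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "wald_z": z,
            "p": p,
            "padj": padj,
            "base_mean": norm.mean(axis=1),
            "tested": nonzero,
            "half_shifted": half_shifted & nonzero,
        },
        index=genes,
    )
    out.loc[~nonzero, ["log2fc", "se", "wald_z", "p", "padj"]] = np.nan
    flag = np.where(
        nonzero & (padj < 0.05) & (log2fc >= 1.0), "up",
        np.where(nonzero & (padj < 0.05) & (log2fc <= -1.0), "down", "ns"),
    )
    out["flag"] = flag
    out.loc[~nonzero, "flag"] = "untested"
    out.index.name = "gene"
    return out


def select_upregulated(
    results: pd.DataFrame,
    padj_threshold: float = 0.05,
    log2fc_threshold: float = 1.0,
) -> list[str]:
    """Genes with Bonferroni-adjusted p below threshold and log2FC at or above it.

    Ordered by adjusted p ascending, ties broken by gene id.
    """
    tested = results[results["tested"].astype(bool)]
    hits = tested[(tested["padj"] < padj_threshold) & (tested["log2fc"] >= log2fc_threshold)]
    order = np.lexsort((hits.index.to_numpy(), hits["padj"].to_numpy()))
    return list(hits.index[order])
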