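"""Connectivity-map scoring: weighted-KS enrichment, WTCS, NCS, tau, reversers.

A query gene signature (here: the hub-gene GMT signature, an up-only
set) is scored against every perturbagen's differential-expression
z-score profile.  Per perturbagen:

* ES — signed maximum deviation of a weighted Kolmogorov-Smirnov running
  sum over the z-ranked gene list (hits weighted by |z|^p, misses by
  1/(N - m));
* WTCS — (ES_up - ES_down)/2 when the up and down scores disagree in
  sign, else 0; for an up-only query WTCS = ES_up;
* NCS — WTCS normalized by the mean magnitude of same-sign WTCS values
  within the same (cell line, perturbagen type) group;
* tau — signed percentile of |NCS| against a reference NCS distribution
  (here: all NCS values computed for the same query);
* summary tau per compound across cell lines — the more extreme of the
  33rd and 67th percentiles of its taus.

Compounds with summary tau <= -90 are called signature reversers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import PerturbagenLibrary

__all__ = [
    "weighted_ks_es",
    "wtcs",
    "normalize_ncs",
    "tau_percentile",
    "summarize_across_cells",
    "query_library",
    "select_reversers",
]


def weighted_ks_es(signature_zscores: pd.Series, query_set, weight_p: float = 1.0) -> float:
    """Weighted-KS enrichment score of a query gene set in a z-ranked profile.

    Genes are ranked by z descending (ties by gene id); a hit at position
    i adds |z_i|^p normalized over all hits, a miss subtracts 1/(N - m).
    ES is the running sum's signed maximum deviation from zero.
    """
    gene_ids = np.asarray(signature_zscores.index.astype(str).str.upper())
    z = signature_zscores.to_numpy(dtype=float)
    query = {str(g).upper() for g in query_set}
    members = np.isin(gene_ids, list(query))
    m = int(members.sum())
    n = len(z)
    if m == 0:
        raise ValueError("query set does not intersect the signature genes")
    if m == n:
        raise ValueError("query set covers every signature gene")
    order = np.lexsort((gene_ids, -z))
    hits = members[order]
    w = np.abs(z[order]) ** weight_p
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all query z-scores exactly zero: fall back to unweighted hits
        hit_w = hits.astype(float)
        denom = float(m)
    running = np.cumsum(hit_w / denom - (~hits) / (n - m))
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx])


def wtcs(
    signature_zscores: pd.Series,
    up_set,
    down_set=None,
    weight_p: float = 1.0,
) -> float:
    """Weighted two-sided connectivity score; up-only queries return ES_up."""
    if down_set is not None:
        up = {str(g).upper() for g in up_set}
        down = {str(g).upper() for g in down_set}
        overlap = up & down
        if overlap:
            raise ValueError(f"up and down sets overlap: {sorted(overlap)[:5]}")
        es_up = weighted_ks_es(signature_zscores, up, weight_p)
        es_down = weighted_ks_es(signature_zscores, down, weight_p)
        if np.sign(es_up) != np.sign(es_down):
            return (es_up - es_down) / 2.0
        return 0.0
    return weighted_ks_es(signature_zscores, up_set, weight_p)


def normalize_ncs(wtcs_values: pd.Series, grouping: pd.DataFrame) -> pd.Series:
    """Normalize WTCS within (cell line, perturbagen type) groups.

    NCS = w / mean(|w'|) over the same-sign members of w's group; zero
    WTCS maps to zero.  A degenerate group (single sign-mate) yields
    NCS = sign(w).
    """
    df = grouping[["cell_line", "pert_type"]].copy()
    df["w"] = wtcs_values
    ncs = pd.Series(0.0, index=wtcs_values.index)
    for _, sub in df.groupby(["cell_line", "pert_type"], sort=False):
        for sign in (1.0, -1.0):
            sel = np.sign(sub["w"]) == sign
            if not sel.any():
                continue
            denom = sub.loc[sel, "w"].abs().mean()
            ncs.loc[sub.index[sel]] = sub.loc[sel, "w"] / denom
    return ncs


def tau_percentile(ncs_query: float, reference_ncs: np.ndarray) -> float:
    """Signed percentile of |NCS| against the reference distribution."""
    ref = np.abs(np.asarray(reference_ncs, dtype=float))
    if ref.size == 0:
        raise ValueError("empty reference NCS distribution")
    frac = float(np.mean(ref < abs(ncs_query)))
    return float(np.sign(ncs_query) * 100.0 * frac)


def summarize_across_cells(taus) -> float:
    """Maximum-quantile summary across cell lines (67th vs 33rd percentile)."""
    arr = np.asarray(list(taus), dtype=float)
    if arr.size == 0:
        raise ValueError("no taus to summarize")
    q_hi = float(np.percentile(arr, 67))
    q_lo = float(np.percentile(arr, 33))
    return q_hi if abs(q_hi) >= abs(q_lo) else q_lo


@dataclass
class ConnectivityReport:
    """Per-perturbagen and per-compound connectivity scores for one query."""

    per_perturbagen: pd.DataFrame  # wtcs, ncs, tau + metadata, indexed by pert id
    per_compound: pd.DataFrame  # summary_tau, n_cell_lines, indexed by compound


def query_library(
    library: PerturbagenLibrary,
    up_set,
    down_set=None,
    weight_p: float = 1.0,
) -> ConnectivityReport:
    """Score a query signature against every perturbagen in the library.

    The tau reference distribution is the full set of NCS values computed
    for this query (a self-referential stand-in for an external reference
    panel).  The per-compound table carries the cross-cell-line summary
    tau, sorted ascending (strongest reversers first).
    """
    w_values = pd.Series(
        {
            pid: wtcs(library.zscores.loc[pid], up_set, down_set, weight_p)
            for pid in library.perturbagen_ids
        }
    )
    ncs = normalize_ncs(w_values, library.meta)
    ref = ncs.to_numpy()
    tau = pd.Series({pid: tau_percentile(ncs[pid], ref) for pid in w_values.index})
    per_pert = library.meta.copy()
    per_pert["wtcs"] = w_values
    per_pert["ncs"] = ncs
    per_pert["tau"] = tau
    rows = []
    for compound, sub in per_pert.groupby("compound", sort=False):
        rows.append(
            {
                "compound": compound,
                "summary_tau": summarize_across_cells(sub["tau"]),
                "n_cell_lines": sub["cell_line"].nunique(),
                "pert_type": sub["pert_type"].iloc[0],
            }
        )
    per_compound = pd.DataFrame(rows).set_index("compound")
    order = np.lexsort((per_compound.index.to_numpy(), per_compound["summary_tau"].to_numpy()))
    per_compound = per_compound.iloc[order]
    return ConnectivityReport(per_perturbagen=per_pert, per_compound=per_compound)


def select_reversers(report: ConnectivityReport, threshold: float = -90.0) -> list[str]:
    """Compounds whose summary tau is at or below the threshold, most negative first."""
    pc = report.per_compound
    hits = pc[(pc["summary_tau"] <= threshold) & (pc["pert_type"] == "compound")]
    return list(hits.index)
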