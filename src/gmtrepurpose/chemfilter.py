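"""The drug funnel: BBB filtering, P-gp consensus, co-occurrence, Tanimoto, assembly.

Candidate signature reversers from the connectivity-map stage are pushed
through a fixed-order funnel:

    connectivity (tau <= -90)
      -> blood-brain-barrier permeability (two predictor platforms)
      -> literature co-occurrence annotation
      -> P-glycoprotein non-substrate consensus (three predictors)
      -> structural similarity to known GBM drugs (Tanimoto, annotation)

Predictor outputs are consumed as score tables; the predictive models
themselves are external.  Two BBB rules are supported: scores on both
platforms at least those of a reference drug (temozolomide), or
membership in the top-k of both platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import PGP_CATEGORIES, FingerprintSet, ScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "tanimoto",
    "similarity_matrix",
    "bbb_filter",
    "pgp_consensus",
    "cooccurrence_filter",
    "FunnelConfig",
    "run_funnel",
]

FUNNEL_STAGES = ["cmap", "bbb", "text", "pgp", "similarity"]


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length bit vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        logger.warning("both fingerprints empty; Tanimoto defined as 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def similarity_matrix(
    fps: FingerprintSet,
    reference_fps: FingerprintSet,
    threshold: float = 0.7,
) -> tuple[pd.DataFrame, pd.Series]:
    """All-pairs Tanimoto between query and reference fingerprints.

    Returns the similarity matrix (query x reference) and a boolean
    'similar' flag per query compound (max similarity >= threshold).
    """
    if fps.n_bits != reference_fps.n_bits:
        raise ValueError("query and reference fingerprints differ in length")
    mat = pd.DataFrame(
        [
            [tanimoto(fps.bits(q), reference_fps.bits(r)) for r in reference_fps.data.index]
            for q in fps.data.index
        ],
        index=fps.data.index,
        columns=reference_fps.data.index,
    )
    flags = (mat.max(axis=1) >= threshold).rename("similar")
    return mat, flags


def bbb_filter(
    scores: ScoreTable,
    score_columns: tuple[str, str],
    mode: str = "at_least_reference",
    reference_compound: str | None = None,
    k: int = 30,
    tolerance: float = 0.0,
) -> set[str]:
    """Blood-brain-barrier permeability filter over two predictor platforms.

    ``at_least_reference``: pass iff both scores are >= the reference
    compound's (minus ``tolerance``).  ``top_k_intersection``: pass iff
    in the top-k of both columns (descending; ties by average rank, then
    compound id).
    """
    col_a, col_b = score_columns
    df = scores.data
    for col in (col_a, col_b):
        if col not in df.columns:
            raise ValueError(f"score column {col!r} missing")
    if mode == "at_least_reference":
        if reference_compound is None or reference_compound not in df.index:
            raise ValueError(f"reference compound {reference_compound!r} not in table")
        ref = df.loc[reference_compound]
        ok = (df[col_a] >= ref[col_a] - tolerance) & (df[col_b] >= ref[col_b] - tolerance)
        return set(df.index[ok])
    if mode == "top_k_intersection":
        passing = None
        for col in (col_a, col_b):
            ranks = rankdata(-df[col].to_numpy(), method="average")
            order = np.lexsort((df.index.to_numpy(), ranks))
            top = set(df.index.to_numpy()[order][:k])
            passing = top if passing is None else passing & top
        return passing
    raise ValueError(f"unknown BBB mode {mode!r}")


def pgp_consensus(calls: ScoreTable, predictor_columns: list[str]) -> set[str]:
    """Compounds called non-substrate by every P-gp predictor."""
    df = calls.data
    if len(predictor_columns) != 3:
        raise ValueError("P-gp consensus expects exactly three predictor columns")
    ok = pd.Series(True, index=df.index)
    for col in predictor_columns:
        if col not in df.columns:
            raise ValueError(f"P-gp column {col!r} missing")
        vals = df[col].astype(str)
        unknown = set(vals) - PGP_CATEGORIES
        if unknown:
            raise ValueError(f"unknown P-gp category values in {col!r}: {sorted(unknown)}")
        ok &= vals == "non-substrate"
    return set(df.index[ok])


def cooccurrence_filter(counts: ScoreTable, entity_kind: str) -> pd.DataFrame:
    """Literature co-occurrence flags per term.

    Gene mode: related iff the article count exceeds 3; drug mode:
    related iff the sentence count exceeds 5 (both strict inequalities).
    """
    thresholds = {"gene": 3, "drug": 5}
    if entity_kind not in thresholds:
        raise ValueError(f"entity_kind must be 'gene' or 'drug', got {entity_kind!r}")
    df = counts.data
    if (df.to_numpy() < 0).any():
        raise ValueError("negative co-occurrence counts")
    return df > thresholds[entity_kind]


@dataclass
class FunnelConfig:
    tau_threshold: float = -90.0
    bbb_mode: str = "at_least_reference"
    bbb_columns: tuple[str, str] = ("bbb_score_a", "bbb_score_b")
    bbb_reference: str | None = None
    bbb_top_k: int = 30
    pgp_columns: list[str] = field(default_factory=lambda: ["pgp_call_1", "pgp_call_2", "pgp_call_3"])
    similarity_threshold: float = 0.7
    stage_order: tuple[str, ...] = tuple(FUNNEL_STAGES)


def run_funnel(
    connectivity: pd.DataFrame,
    bbb_scores: ScoreTable | None,
    pgp_calls: ScoreTable | None,
    cooccurrence: ScoreTable | None,
    fingerprints: FingerprintSet | None,
    reference_fps: FingerprintSet | None,
    config: FunnelConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the fixed-order drug funnel and report per-stage survivor counts.

    ``connectivity`` is the per-compound table from the cmap stage
    (summary_tau column, compound index).  Compounds missing from a
    required table are carried with stage verdict 'unknown' and excluded
    from that stage's pass set.  Returns (records, stage_counts); the
    records frame has one row per compound entering the funnel with
    per-stage verdicts, the stage reached, and annotations.
    """
    config = config or FunnelConfig()
    if tuple(config.stage_order) != tuple(FUNNEL_STAGES):
        raise ValueError(f"funnel stage order is fixed: {FUNNEL_STAGES}")
    comp = connectivity[connectivity.get("pert_type", "compound") == "compound"] \
        if "pert_type" in connectivity.columns else connectivity
    records = pd.DataFrame(index=comp.index.copy())
    records["summary_tau"] = comp["summary_tau"]
    counts: dict[str, int] = {}

    # stage 1: connectivity
    alive = set(records.index[records["summary_tau"] <= config.tau_threshold])
    records["cmap_pass"] = records.index.isin(alive)
    counts["cmap"] = len(alive)

    # stage 2: BBB
    if bbb_scores is not None:
        known = set(bbb_scores.data.index)
        missing = alive - known
        if missing:
            logger.warning("compounds without BBB scores: %s", sorted(missing)[:10])
        passing = bbb_filter(
            bbb_scores, config.bbb_columns, mode=config.bbb_mode,
            reference_compound=config.bbb_reference, k=config.bbb_top_k,
        )
        records["bbb_pass"] = [
            (c in passing) if c in known else None for c in records.index
        ]
        alive = alive & passing
    else:
        records["bbb_pass"] = None
    counts["bbb"] = len(alive)

    # stage 3: literature co-occurrence (annotation; related-to-any-term keeps)
    if cooccurrence is not None:
        flags = cooccurrence_filter(cooccurrence, "drug")
        known = set(flags.index)
        records["text_related"] = [
            bool(flags.loc[c].any()) if c in known else None for c in records.index
        ]
        alive = alive & {c for c in known if flags.loc[c].any()}
    else:
        records["text_related"] = None
    counts["text"] = len(alive)

    # stage 4: P-gp consensus
    if pgp_calls is not None:
        known = set(pgp_calls.data.index)
        passing = pgp_consensus(pgp_calls, config.pgp_columns)
        records["pgp_nonsubstrate"] = [
            (c in passing) if c in known else None for c in records.index
        ]
        alive = alive & passing
    else:
        records["pgp_nonsubstrate"] = None
    counts["pgp"] = len(alive)

    # stage 5: structural similarity (annotation, not a hard filter)
    if fingerprints is not None and reference_fps is not None:
        present = [c for c in records.index if c in fingerprints.data.index]
        if present:
            sub = FingerprintSet(fingerprints.data.loc[present].copy())
            mat, flags = similarity_matrix(sub, reference_fps, config.similarity_threshold)
            max_sim = mat.max(axis=1)
            records["max_tanimoto"] = [
                float(max_sim[c]) if c in present else np.nan for c in records.index
            ]
            records["similar_to_known_drug"] = [
                bool(flags[c]) if c in present else None for c in records.index
            ]
        else:
            records["max_tanimoto"] = np.nan
            records["similar_to_known_drug"] = None
    else:
        records["max_tanimoto"] = np.nan
        records["similar_to_known_drug"] = None
    counts["similarity"] = len(alive)

    gate_cols = [("cmap", "cmap_pass"), ("bbb", "bbb_pass"),
                 ("text", "text_related"), ("pgp", "pgp_nonsubstrate")]
    stage_of = []
    for c in records.index:
        reached = "none"
        for stage, col in gate_cols:
            v = records.loc[c, col]
            if v is not None and not pd.isna(v) and bool(v):
                reached = stage
            else:
                break
        else:  # survived every gating stage
            reached = "similarity"
        stage_of.append(reached)
    records["stage_reached"] = stage_of
    records["final_pass"] = records.index.isin(alive)
    return records, counts
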