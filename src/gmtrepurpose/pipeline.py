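"""End-to-end orchestration: GMT signature discovery through drug ranking.

Stages run in a fixed order:

1.  GMT score per sample (mesenchymal minus proneural ssGSEA score) and
    median stratification.
2.  Two-group GSEA of annotation gene sets between GMT-high and GMT-low
    strata (annotation only — feeds interpretation, not selection).
3.  Co-expression modules (TOM + static tree cut + merge); the module
    whose eigengene correlates most positively with the GMT score is the
    GMT-associated module.
4.  Differential expression on the two-condition count experiment;
    up-regulated genes (Bonferroni p < 0.05, log2FC >= 1).
5.  Intersection of the GMT module with the up-regulated genes.
6.  Hub ranking of the intersection genes in the interaction network
    (six-metric composite centrality), top-k hubs = the GMT signature.
7.  Univariate Cox prognosis screen of the hubs (annotation).
8.  Connectivity-map query of the hub signature against the perturbagen
    library; compounds with summary tau <= -90 are candidate reversers.
9.  Chemoinformatic funnel (BBB, literature, P-gp, similarity).
10. Final report, sorted by summary tau.

Every stage's artifact is a plain table; a provenance record (input
hashes, parameters, seed, survivor counts) accompanies the run.  With a
fixed config and seed the whole run is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemfilter, cmap, coexpression, diffexpr, enrichment, netrank, survival
from .core_io import (
    CountMatrix,
    ExpressionMatrix,
    FingerprintSet,
    GeneSetCollection,
    InteractionGraph,
    PerturbagenLibrary,
    ScoreTable,
    SurvivalTable,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineInputs", "PipelineResult", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    alpha: float = 0.25
    soft_power: float = 12.0
    min_module_size: int = 30
    cut_height: float = 0.995
    merge_height: float = 0.25
    padj_threshold: float = 0.05
    log2fc_threshold: float = 1.0
    k_hubs: int = 20
    tau_threshold: float = -90.0
    epc_trials: int = 200
    epc_retain: float = 0.5
    n_perm: int = 200
    gsea_weight_p: float = 1.0
    bbb_mode: str = "at_least_reference"
    bbb_reference: str | None = "TEMOZOLOMIDE"
    bbb_top_k: int = 30
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineInputs:
    expr: ExpressionMatrix
    surv: SurvivalTable
    mes_set: list[str]
    pn_set: list[str]
    counts: CountMatrix
    network: InteractionGraph
    library: PerturbagenLibrary
    bbb: ScoreTable | None = None
    pgp: ScoreTable | None = None
    cooc: ScoreTable | None = None
    fingerprints: FingerprintSet | None = None
    reference_fps: FingerprintSet | None = None
    annotation_sets: GeneSetCollection | None = None


@dataclass
class PipelineResult:
    gmt_scores: pd.Series
    groups: pd.Series
    gsea: pd.DataFrame | None
    modules: coexpression.ModuleAssignment
    eigengenes: coexpression.EigengeneMatrix
    module_trait: pd.DataFrame
    top_module: int
    de_results: pd.DataFrame
    up_genes: list[str]
    intersection: list[str]
    centrality: pd.DataFrame
    hubs: list[str]
    prognosis: pd.DataFrame | None
    connectivity: cmap.ConnectivityReport
    reversers: list[str]
    funnel_records: pd.DataFrame
    funnel_counts: dict[str, int]
    report: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _hash_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes())
    return h.hexdigest()[:16]


def run_pipeline(inputs: PipelineInputs, config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()

    # 1. GMT score + stratification
    gmt = enrichment.gmt_score(inputs.expr, inputs.mes_set, inputs.pn_set, alpha=config.alpha)
    groups = enrichment.stratify_by_median(gmt)

    # 2. annotation GSEA between strata
    gsea_table = None
    if inputs.annotation_sets is not None:
        res = enrichment.gsea_two_group(
            inputs.expr, groups, inputs.annotation_sets,
            n_perm=config.n_perm, seed=config.seed, weight_p=config.gsea_weight_p,
        )
        gsea_table = pd.DataFrame(
            [{"set": r.set_name, "es": r.es, "nes": r.nes, "p": r.p,
              "fdr_q": r.fdr_q, "direction": r.direction} for r in res]
        ).set_index("set")

    # 3. co-expression modules, GMT-associated module
    tom = coexpression.compute_tom(inputs.expr, config.soft_power)
    modules = coexpression.detect_modules(
        1.0 - tom, min_module_size=config.min_module_size, cut_height=config.cut_height
    )
    if not modules.module_ids:
        raise RuntimeError("coexpression stage found no modules")
    modules, eigengenes = coexpression.merge_modules(
        inputs.expr, modules, merge_height=config.merge_height
    )
    traits = pd.DataFrame({"gmt_score": gmt.scores})
    module_trait = coexpression.module_trait_correlation(eigengenes, traits)
    top_module = coexpression.top_module_for_trait(module_trait, "gmt_score")
    module_genes = modules.genes_in(top_module)

    # 4. differential expression
    de = diffexpr.de_test(inputs.counts)
    up_genes = diffexpr.select_upregulated(
        de, padj_threshold=config.padj_threshold, log2fc_threshold=config.log2fc_threshold
    )

    # 5. intersection
    intersection = sorted(set(module_genes) & set(up_genes))
    if not intersection:
        raise RuntimeError("empty intersection of GMT module and up-regulated genes")

    # 6. hub ranking
    centrality = netrank.compute_centralities(
        inputs.network, epc_trials=config.epc_trials,
        epc_retain=config.epc_retain, seed=config.seed,
    )
    hubs = netrank.select_hubs(centrality, intersection, config.k_hubs)
    if not hubs:
        raise RuntimeError("no intersection gene present in the interaction network")

    # 7. prognosis screen (annotation)
    prognosis = None
    try:
        prognosis = survival.prognosis_screen(inputs.expr, inputs.surv, hubs)
    except ValueError as exc:
        logger.warning("prognosis screen skipped: %s", exc)

    # 8. connectivity map
    connectivity = cmap.query_library(inputs.library, up_set=hubs)
    reversers = cmap.select_reversers(connectivity, threshold=config.tau_threshold)

    # 9. funnel
    funnel_cfg = chemfilter.FunnelConfig(
        tau_threshold=config.tau_threshold,
        bbb_mode=config.bbb_mode,
        bbb_reference=config.bbb_reference,
        bbb_top_k=config.bbb_top_k,
    )
    records, counts = chemfilter.run_funnel(
        connectivity.per_compound, inputs.bbb, inputs.pgp, inputs.cooc,
        inputs.fingerprints, inputs.reference_fps, funnel_cfg,
    )

    # 10. report
    report = records.sort_values(
        ["summary_tau"], kind="mergesort"
    ).copy()
    report.index.name = "compound"

    provenance = {
        "config": asdict(config),
        "inputs": {
            "expr": _hash_frame(inputs.expr.data),
            "counts": _hash_frame(inputs.counts.data),
            "library": _hash_frame(inputs.library.zscores),
            "n_network_nodes": inputs.network.graph.number_of_nodes(),
        },
        "survivors": {
            "module_genes": len(module_genes),
            "up_genes": len(up_genes),
            "intersection": len(intersection),
            "hubs": len(hubs),
            "reversers": len(reversers),
            **{f"funnel_{k}": v for k, v in counts.items()},
        },
    }
    return PipelineResult(
        gmt_scores=gmt.scores, groups=groups, gsea=gsea_table, modules=modules,
        eigengenes=eigengenes, module_trait=module_trait, top_module=top_module,
        de_results=de, up_genes=up_genes, intersection=intersection,
        centrality=centrality, hubs=hubs, prognosis=prognosis,
        connectivity=connectivity, reversers=reversers, funnel_records=records,
        funnel_counts=counts, report=report, provenance=provenance,
    )


def write_artifacts(result: PipelineResult, outdir) -> None:
    """Write every stage artifact plus the provenance record as text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.gmt_scores.rename("gmt_score").to_frame().assign(group=result.groups).to_csv(
        out / "gmt_scores.tsv", sep="\t", index_label="sample", lineterminator="\n")
    if result.gsea is not None:
        result.gsea.to_csv(out / "gsea.tsv", sep="\t", lineterminator="\n")
    result.modules.labels.rename("module").to_frame().to_csv(
        out / "modules.tsv", sep="\t", index_label="gene", lineterminator="\n")
    result.module_trait.to_csv(out / "module_trait.tsv", sep="\t", index=False,
                               lineterminator="\n")
    result.de_results.to_csv(out / "de.tsv", sep="\t", lineterminator="\n")
    result.centrality.to_csv(out / "centrality.tsv", sep="\t", lineterminator="\n")
    pd.Series(result.hubs, name="gene").to_csv(out / "hubs.tsv", sep="\t", index=False,
                                               lineterminator="\n")
    if result.prognosis is not None:
        result.prognosis.to_csv(out / "prognosis.tsv", sep="\t", lineterminator="\n")
    result.connectivity.per_compound.to_csv(out / "connectivity.tsv", sep="\t",
                                            lineterminator="\n")
    result.report.to_csv(out / "report.tsv", sep="\t", lineterminator="\n")
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=1, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        fh.write(make_report(result))


def make_report(result: PipelineResult) -> str:
    """Human-readable run summary: survivor counts, hub list, top compounds."""
    lines = ["GMT drug-repurposing pipeline summary", "=" * 38]
    surv = result.provenance.get("survivors", {})
    for key, val in surv.items():
        lines.append(f"{key:>16}: {val}")
    lines.append("")
    lines.append(f"top GMT-associated module: {result.top_module} "
                 f"({len(result.modules.genes_in(result.top_module))} genes)")
    lines.append("hub signature: " + ", ".join(result.hubs))
    lines.append("")
    lines.append("top compounds by summary tau:")
    head = result.report.head(10)
    for compound, row in head.iterrows():
        lines.append(f"  {compound:>12}  tau={row['summary_tau']:+7.1f}  "
                     f"stage={row['stage_reached']}  final_pass={bool(row['final_pass'])}")
    if len(result.report) == 0:
        lines.append("  (empty funnel: zero survivors)")
    return "\n".join(lines) + "\n"
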