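"""Seeded generators emulating the cohorts the analysis assumes, with ground truth.

Each generator is a pure function of its parameters and seed and returns
its dataset together with a :class:`SyntheticTruth` record carrying the
planted structure (latent axis, gene programs, module membership, hubs,
differential genes, reverser compounds), so recovery metrics never need
to re-derive the truth.

The cohort generator plants a latent mesenchymal-proneural axis g_s ~
N(0,1) driving two antagonistic gene programs (loadings +lambda and
-lambda), one co-expressed module (axis loading plus a shared module
factor) and survival hazard increasing with the axis.  The count
generator is a two-condition negative-binomial experiment with planted
fold changes; the network generator a preferential-attachment graph
with planted, clique-connected hubs; the library generator a perturbagen
panel in which reverser compounds down-shift the signature genes by
``effect`` z-units in every cell line.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import (
    CountMatrix,
    ExpressionMatrix,
    FingerprintSet,
    InteractionGraph,
    PerturbagenLibrary,
    ScoreTable,
    SurvivalTable,
)

__all__ = [
    "SyntheticTruth",
    "gen_bulk_cohort",
    "gen_counts",
    "gen_network",
    "gen_signature_library",
    "gen_chem_tables",
    "simulate_all",
]


@dataclass
class SyntheticTruth:
    """Ground truth and full parameter record of one generated dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_default, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def gen_bulk_cohort(
    n_samples: int = 200,
    n_genes: int = 400,
    n_sig: int = 25,
    module_size: int = 60,
    loading: float = 1.0,
    noise: float = 0.5,
    surv_beta: float = 0.5,
    baseline_hazard: float = 0.001,
    censor_rate: float = 0.0005,
    mes_module_factor: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SurvivalTable, SyntheticTruth]:
    """Cohort with a latent GMT axis, antagonistic programs, one planted module.

    Mesenchymal genes load +``loading`` on the axis, proneural genes
    -``loading``; module genes add a shared per-sample module factor on
    top of the axis loading.  ``mes_module_factor`` optionally gives the
    mesenchymal genes a loading on the module factor too, co-expressing
    the mesenchymal program with the planted module (so that one module
    unambiguously carries the GMT program in end-to-end runs).  Survival
    is exponential with hazard ``baseline_hazard * exp(surv_beta * g_s)``
    under independent exponential censoring at ``censor_rate`` (both per
    day).
    """
    if module_size + 2 * n_sig > n_genes:
        raise ValueError("module_size + 2*n_sig exceeds n_genes")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n_samples)
    module_factor = rng.standard_normal(n_samples)

    mes = _gene_names("MES", n_sig)
    pn = _gene_names("PN", n_sig)
    mod = _gene_names("MOD", module_size)
    bg = _gene_names("BG", n_genes - 2 * n_sig - module_size)
    genes = mes + pn + mod + bg

    blocks = [
        loading * g + mes_module_factor * module_factor
        + noise * rng.standard_normal((n_sig, n_samples)),
        -loading * g + noise * rng.standard_normal((n_sig, n_samples)),
        loading * g + module_factor + noise * rng.standard_normal((module_size, n_samples)),
        rng.standard_normal((len(bg), n_samples)),
    ]
    X = np.vstack(blocks)
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples))

    hazard = baseline_hazard * np.exp(surv_beta * g)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / censor_rate, size=n_samples) if censor_rate > 0 else np.full(
        n_samples, np.inf
    )
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    surv = SurvivalTable(pd.DataFrame({"time": time, "event": event}, index=samples))

    truth = SyntheticTruth(
        kind="bulk_cohort",
        seed=seed,
        params=dict(
            n_samples=n_samples, n_genes=n_genes, n_sig=n_sig, module_size=module_size,
            loading=loading, noise=noise, surv_beta=surv_beta,
            baseline_hazard=baseline_hazard, censor_rate=censor_rate,
        ),
        data=dict(
            gmt_axis=dict(zip(samples, g.tolist())),
            mes_genes=mes, pn_genes=pn, module_genes=mod,
        ),
    )
    return expr, surv, truth


def gen_counts(
    n_genes: int = 2000,
    n_per_group: int = 5,
    frac_de: float = 0.05,
    log2fc: float = 2.0,
    mean_mu: float = 100.0,
    dispersion: float = 0.1,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    de_genes: list[str] | None = None,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Two-condition NB count experiment with planted fold changes.

    All genes share baseline mean ``mean_mu`` and dispersion
    ``dispersion``; planted genes are up-shifted by ``2**log2fc`` in
    condition A.  The planted set is either ``de_genes`` or the first
    ``frac_de`` fraction of the gene list.
    """
    rng = np.random.default_rng(seed)
    genes = list(gene_ids) if gene_ids is not None else _gene_names("G", n_genes)
    n_genes = len(genes)
    if de_genes is None:
        n_de = int(round(frac_de * n_genes))
        de_genes = genes[:n_de]
    de_set = set(de_genes)
    mu = np.full((n_genes, 2 * n_per_group), mean_mu)
    is_de = np.array([g in de_set for g in genes])
    mu[is_de, :n_per_group] *= 2.0 ** log2fc  # condition A columns first
    # NB(mean mu, dispersion a): n = 1/a successes, p = n/(n+mu)
    size = 1.0 / dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    samples = [f"A{i}" for i in range(1, n_per_group + 1)] + [
        f"B{i}" for i in range(1, n_per_group + 1)
    ]
    labels = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=samples)
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), labels)
    truth = SyntheticTruth(
        kind="counts",
        seed=seed,
        params=dict(
            n_genes=n_genes, n_per_group=n_per_group, frac_de=frac_de, log2fc=log2fc,
            mean_mu=mean_mu, dispersion=dispersion,
        ),
        data=dict(de_genes=sorted(de_set), condition_up="A"),
    )
    return cm, truth


def gen_network(
    n_nodes: int = 300,
    n_hubs: int = 20,
    hub_degree: int = 30,
    attachment_m: int = 2,
    seed: int = 0,
    node_names: list[str] | None = None,
    hub_names: list[str] | None = None,
) -> tuple[InteractionGraph, SyntheticTruth]:
    """Interaction graph: preferential-attachment background + planted hubs.

    Hubs are wired to ``hub_degree`` random background nodes each and to
    one another (an inter-hub clique).  Edge confidences are uniform in
    (0.71, 1.0) — already above the usual 0.7 threshold.
    """
    if hub_names is not None:
        n_hubs = len(hub_names)
    n_bg = n_nodes - n_hubs
    if n_bg < max(attachment_m + 1, hub_degree):
        raise ValueError("too few background nodes for the requested hubs")
    rng = np.random.default_rng(seed)
    bg_graph = nx.barabasi_albert_graph(n_bg, attachment_m, seed=int(rng.integers(2**31)))
    if node_names is not None:
        if len(node_names) != n_bg:
            raise ValueError(f"need {n_bg} background node names, got {len(node_names)}")
        bg_names = [str(x).upper() for x in node_names]
    else:
        bg_names = _gene_names("NODE", n_bg)
    g = nx.relabel_nodes(bg_graph, dict(enumerate(bg_names)))
    hubs = [str(h).upper() for h in hub_names] if hub_names is not None else _gene_names("HUB", n_hubs)
    for h in hubs:
        targets = rng.choice(n_bg, size=hub_degree, replace=False)
        for t in targets:
            g.add_edge(h, bg_names[t])
    for i, a in enumerate(hubs):
        for b in hubs[i + 1:]:
            g.add_edge(a, b)
    for u, v in g.edges:
        g.edges[u, v]["confidence"] = float(rng.uniform(0.71, 1.0))
    nx.set_node_attributes(g, "gene", "kind")
    truth = SyntheticTruth(
        kind="network",
        seed=seed,
        params=dict(n_nodes=n_nodes, n_hubs=n_hubs, hub_degree=hub_degree,
                    attachment_m=attachment_m),
        data=dict(hub_nodes=hubs),
    )
    return InteractionGraph(g), truth


def gen_signature_library(
    n_compounds: int = 100,
    n_reversers: int = 5,
    n_genes: int = 500,
    signature_genes: list[str] | None = None,
    effect: float = 3.0,
    noise: float = 1.0,
    n_cell_lines: int = 9,
    n_mimics: int = 0,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[PerturbagenLibrary, SyntheticTruth]:
    """Perturbagen z-score library with planted signature reversers.

    Inert compounds are N(0, noise) everywhere; reversers are shifted by
    ``-effect`` on the signature genes in every cell line (mimics, when
    requested, by ``+effect``).
    """
    rng = np.random.default_rng(seed)
    genes = [str(x).upper() for x in gene_ids] if gene_ids is not None else _gene_names("G", n_genes)
    n_genes = len(genes)
    if signature_genes is None:
        signature_genes = genes[: max(10, n_genes // 20)]
    signature_genes = [str(x).upper() for x in signature_genes]
    sig_idx = [genes.index(s) for s in signature_genes if s in genes]
    if not sig_idx:
        raise ValueError("no signature genes present in the library gene space")
    compounds = [f"CMP{i:03d}" for i in range(1, n_compounds + 1)]
    reversers = compounds[:n_reversers]
    mimics = compounds[n_reversers:n_reversers + n_mimics]
    cell_lines = [f"CELL{i}" for i in range(1, n_cell_lines + 1)]

    pert_ids, meta_rows, z_rows = [], [], []
    for compound in compounds:
        for cell in cell_lines:
            z = noise * rng.standard_normal(n_genes)
            if compound in reversers:
                z[sig_idx] -= effect
            elif compound in mimics:
                z[sig_idx] += effect
            pid = f"{compound}:{cell}"
            pert_ids.append(pid)
            meta_rows.append({"compound": compound, "cell_line": cell, "pert_type": "compound"})
            z_rows.append(z)
    meta = pd.DataFrame(meta_rows, index=pert_ids)
    zscores = pd.DataFrame(np.array(z_rows), index=pert_ids, columns=genes)
    lib = PerturbagenLibrary(meta=meta, zscores=zscores)
    truth = SyntheticTruth(
        kind="signature_library",
        seed=seed,
        params=dict(n_compounds=n_compounds, n_reversers=n_reversers, n_genes=n_genes,
                    effect=effect, noise=noise, n_cell_lines=n_cell_lines, n_mimics=n_mimics),
        data=dict(reversers=reversers, mimics=mimics, signature_genes=signature_genes),
    )
    return lib, truth


def _as_set(selection, compounds, rng) -> set[str]:
    if isinstance(selection, (set, frozenset, list, tuple)):
        return {str(c) for c in selection}
    n = int(round(float(selection) * len(compounds)))
    return set(rng.choice(compounds, size=n, replace=False))


def gen_chem_tables(
    compounds: list[str],
    seed: int = 0,
    bbb_pass=0.6,
    pgp_pass=0.5,
    text_related=0.7,
    similar=0.3,
    n_bits: int = 64,
    n_reference_drugs: int = 3,
    reference_compound: str = "TEMOZOLOMIDE",
) -> tuple[ScoreTable, ScoreTable, ScoreTable, FingerprintSet, FingerprintSet, SyntheticTruth]:
    """Predictor score tables and fingerprints with a configured pass pattern.

    ``bbb_pass``/``pgp_pass``/``text_related``/``similar`` are either
    fractions or explicit compound collections.  Returns (bbb, pgp,
    cooccurrence, fingerprints, reference_fps, truth); the BBB table
    includes a temozolomide-like reference row scoring 50 on both
    platforms.
    """
    rng = np.random.default_rng(seed)
    compounds = [str(c) for c in compounds]
    bbb_set = _as_set(bbb_pass, compounds, rng)
    pgp_set = _as_set(pgp_pass, compounds, rng)
    text_set = _as_set(text_related, compounds, rng)
    sim_set = _as_set(similar, compounds, rng)

    ref_score = 50.0
    rows = {}
    for c in compounds:
        if c in bbb_set:
            rows[c] = (rng.uniform(ref_score, 100.0), rng.uniform(ref_score, 100.0))
        else:
            rows[c] = (rng.uniform(0.0, ref_score - 1.0), rng.uniform(0.0, ref_score - 1.0))
    rows[reference_compound] = (ref_score, ref_score)
    bbb = ScoreTable(pd.DataFrame.from_dict(
        rows, orient="index", columns=["bbb_score_a", "bbb_score_b"]))

    pgp_rows = {}
    for c in compounds:
        if c in pgp_set:
            calls = ["non-substrate"] * 3
        else:
            calls = ["non-substrate"] * 3
            for i in rng.choice(3, size=int(rng.integers(1, 4)), replace=False):
                calls[i] = "substrate"
        pgp_rows[c] = calls
    pgp = ScoreTable(pd.DataFrame.from_dict(
        pgp_rows, orient="index", columns=["pgp_call_1", "pgp_call_2", "pgp_call_3"]))

    terms = ["emt", "glioblastoma", "metastasis", "invasion"]
    cooc_rows = {}
    for c in compounds:
        if c in text_set:
            counts = rng.integers(0, 6, size=len(terms))
            counts[rng.integers(len(terms))] = rng.integers(6, 51)
        else:
            counts = rng.integers(0, 6, size=len(terms))
        cooc_rows[c] = counts.tolist()
    cooc = ScoreTable(pd.DataFrame.from_dict(cooc_rows, orient="index", columns=terms))

    ref_names = [f"GBMDRUG{i}" for i in range(1, n_reference_drugs + 1)]
    ref_bits = rng.integers(0, 2, size=(n_reference_drugs, n_bits))
    ref_fps = FingerprintSet(pd.DataFrame(ref_bits, index=ref_names))
    fp_rows = {}
    for c in compounds:
        if c in sim_set:
            base = ref_bits[rng.integers(n_reference_drugs)].copy()
            flips = rng.choice(n_bits, size=max(1, n_bits // 16), replace=False)
            base[flips] = 1 - base[flips]
            fp_rows[c] = base
        else:
            fp_rows[c] = rng.integers(0, 2, size=n_bits)
    fps = FingerprintSet(pd.DataFrame.from_dict(fp_rows, orient="index"))

    truth = SyntheticTruth(
        kind="chem_tables",
        seed=seed,
        params=dict(n_bits=n_bits, n_reference_drugs=n_reference_drugs,
                    reference_compound=reference_compound),
        data=dict(
            bbb_pass=sorted(bbb_set), pgp_pass=sorted(pgp_set),
            text_related=sorted(text_set), similar=sorted(sim_set),
        ),
    )
    return bbb, pgp, cooc, fps, ref_fps, truth


def simulate_all(seed: int = 0, n_hubs: int = 20) -> dict:
    """One coherent synthetic study: cohort, counts, network, library, chem tables.

    The planted structures are linked the way the analysis expects to
    find them: the planted module genes are also planted up-regulated
    genes, the planted hubs sit inside the module, and the library's
    reverser compounds down-shift exactly the planted hub signature.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))  # noqa: E731 - derived stream seeds

    expr, surv, cohort_truth = gen_bulk_cohort(mes_module_factor=0.6, seed=sub())
    mes = cohort_truth.data["mes_genes"]
    mod = cohort_truth.data["module_genes"]
    genes = expr.gene_ids

    de_planted = sorted(set(mod) | set(mes))
    counts, counts_truth = gen_counts(
        gene_ids=genes, de_genes=de_planted, log2fc=2.0, seed=sub()
    )

    hub_genes = mod[:n_hubs]
    block = mes + mod  # the co-expressed GMT program
    non_hub_block = [g for g in block if g not in set(hub_genes)]
    background = [g for g in genes if g not in set(block)][: 300 - len(block)]
    net, net_truth = gen_network(
        n_nodes=len(non_hub_block) + len(background) + n_hubs,
        hub_names=hub_genes,
        node_names=non_hub_block + background,
        seed=sub(),
    )

    lib, lib_truth = gen_signature_library(
        gene_ids=genes, signature_genes=hub_genes, effect=3.0, seed=sub()
    )
    reversers = lib_truth.data["reversers"]
    compounds = sorted(lib.meta["compound"].unique())
    inert = [c for c in compounds if c not in set(reversers)]
    chem = gen_chem_tables(
        compounds,
        seed=sub(),
        bbb_pass=set(reversers) | set(inert[: len(inert) // 2]),
        pgp_pass=set(reversers[: max(1, len(reversers) - 1)]) | set(inert[: len(inert) // 3]),
        text_related=set(reversers) | set(inert[: len(inert) // 2]),
        similar=set(reversers[:2]),
    )
    bbb, pgp, cooc, fps, ref_fps, chem_truth = chem
    return {
        "expr": expr, "surv": surv, "cohort_truth": cohort_truth,
        "counts": counts, "counts_truth": counts_truth,
        "network": net, "network_truth": net_truth,
        "library": lib, "library_truth": lib_truth,
        "bbb": bbb, "pgp": pgp, "cooc": cooc,
        "fingerprints": fps, "reference_fps": ref_fps, "chem_truth": chem_truth,
        "seed": seed,
    }
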