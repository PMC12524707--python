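# gmtrepurpose

Glioblastoma (GBM) cells shift from a proneural toward a mesenchymal
transcriptional state — the glial-mesenchymal transition (GMT) — and that
shift tracks with invasion, therapy resistance and worse survival.
`gmtrepurpose` is a pipeline for deriving a GMT gene signature from bulk
expression cohorts and for ranking small molecules that *reverse* that
signature in a connectivity-map sense.  It is aimed at computational
biologists who want each stage — single-sample enrichment, co-expression
modules, differential expression, network hub ranking, connectivity
scoring, drug filtering — as a tested, reusable library rather than a
one-off script collection.

## What it computes

**GMT score.** For each sample, genes are ranked by expression and a
rank-weighted running-sum enrichment score ES(S) is computed per gene set
(ssGSEA statistic with position weights `(N - i + 1)^alpha`, alpha = 0.25).
The GMT score is

```
GMT_s = ES_s(mesenchymal) - ES_s(proneural)
```

Cohorts are stratified at the median GMT score ("GMT-high" vs "GMT-low")
and compared by permutation GSEA (signal-to-noise ranking, weighted
Kolmogorov–Smirnov statistic, same-sign NES/p/FDR conventions).

**GMT-associated module.** An unsigned weighted co-expression network
(adjacency `|cor|^beta`, default beta = 12) is summarized by the
topological overlap measure

```
omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   l_ij = sum_u a_iu a_uj
```

and clustered (average linkage, static cut, modules merged at eigengene
dissimilarity 0.25).  The module whose eigengene (first PC of the
standardized member genes) correlates most positively with the GMT score
is the GMT-associated module.

**Signature genes.** A negative-binomial Wald test on a two-condition
count experiment yields up-regulated genes (Bonferroni p < 0.05,
log2FC ≥ 1).  Their intersection with the GMT module is ranked in a
protein-interaction network (confidence > 0.7) by the mean rank of six
centralities — Degree, Maximal Clique Centrality, Maximum Neighborhood
Component, Edge Percolation Component, harmonic Closeness, Radiality —
and the top-k genes form the GMT hub signature.

**Drug ranking.** The hub signature is scored against a perturbagen
z-score library with the weighted-KS connectivity statistic; scores are
group-normalized (NCS) and converted to signed percentiles (tau) against
the library's NCS distribution, summarized across cell lines.  Compounds
with summary tau ≤ −90 are candidate GMT reversers and pass through a
fixed funnel: blood-brain-barrier permeability (two predictor platforms),
literature co-occurrence, P-glycoprotein non-substrate consensus (three
predictors) and Tanimoto similarity to known GBM drugs.

A seeded synthetic-data module (`gmtrepurpose.synthdata`) generates
cohorts with a planted mesenchymal–proneural axis, planted co-expression
module, planted fold changes, planted network hubs and planted reverser
compounds, so every stage is testable without any external download.

## Worked example

Generate a synthetic study and run the full pipeline:

```
$ gmtrepurpose simulate-all --seed 3 --out study
$ gmtrepurpose run --config study/config.yaml
```

which prints (abridged):

```
    module_genes: 110
        up_genes: 83
    intersection: 83
            hubs: 20
       reversers: 5
     funnel_cmap: 5
      funnel_bbb: 5
     funnel_text: 5
      funnel_pgp: 4

top GMT-associated module: 1 (110 genes)
hub signature: MOD0018, MOD0004, MOD0015, ... MES0007

top compounds by summary tau:
        CMP005  tau=  -98.8  stage=text        final_pass=False
        CMP002  tau=  -98.6  stage=similarity  final_pass=True
        CMP001  tau=  -98.4  stage=similarity  final_pass=True
        CMP003  tau=  -98.1  stage=similarity  final_pass=True
        CMP004  tau=  -97.3  stage=similarity  final_pass=True
        CMP074  tau=  -65.7  stage=none        final_pass=False
```

The five compounds with tau below −97 are exactly the five planted
reversers (their z-scores were shifted by −3 on the planted hub genes in
every cell line); the best inert compound sits near −66.  Four of the
five also survive the chemoinformatic funnel — CMP005 fails only the
P-gp consensus, by construction of the synthetic predictor tables.
`stage` names the deepest funnel stage a compound passed; every stage
artifact (GMT scores, module assignment, DE table, centrality table,
connectivity scores, funnel records, provenance) is written under
`study/artifacts/`.

The same stages are available as library calls
(`enrichment.gmt_score`, `coexpression.compute_tom`, `diffexpr.de_test`,
`netrank.compute_centralities`, `cmap.query_library`,
`chemfilter.run_funnel`, `pipeline.run_pipeline`) and as per-stage
subcommands (`score-gmt`, `wgcna`, `de`, `hubs`, `cmap-query`,
`prognosis`, `funnel`).

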