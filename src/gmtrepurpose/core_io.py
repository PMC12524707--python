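"""Domain containers and file-format I/O for the repurposing pipeline.

Every external format the pipeline touches is parsed and serialized here:
expression matrices (TSV and GCT v1.2), gene-set collections (GMT text
format), STRING/STITCH-style edge lists, perturbagen signature libraries
(GCT-like matrix plus a metadata sidecar), survival tables and compound
score tables.  Readers validate the container invariants on load; writers
are exact inverses of the readers on valid data.

Gene symbols are upper-cased on load so that matrices, gene sets and
interaction graphs join on a canonical namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "CountMatrix",
    "GeneSetCollection",
    "InteractionGraph",
    "PerturbagenLibrary",
    "SurvivalTable",
    "ScoreTable",
    "FingerprintSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_edge_list",
    "write_edge_list",
    "read_signature_library",
    "write_signature_library",
    "read_survival_table",
    "write_survival_table",
    "read_score_table",
    "write_score_table",
    "read_fingerprints",
    "write_fingerprints",
    "lognorm_counts",
]


class FormatError(ValueError):
    """Raised when a file violates its declared dialect or a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of continuous, normalized expression.

    ``data`` is indexed by unique upper-cased gene symbols with unique
    sample columns.  Genes containing any missing value are dropped (and
    logged) at construction; at least 2 genes and 2 samples must remain.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        df.index = df.index.astype(str).str.upper()
        df.columns = df.columns.astype(str)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            logger.warning("collapsing %d duplicate gene rows by mean: %s", len(dups), dups[:5])
            df = df.groupby(level=0, sort=False).mean()
        if df.columns.duplicated().any():
            raise FormatError("duplicate sample identifiers")
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)].tolist()
            logger.warning("dropping %d genes with missing values: %s", len(bad), bad[:5])
            df = df.dropna(axis=0)
        df = df.astype(float)
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise FormatError(
                f"expression matrix needs >=2 genes and >=2 samples, got {df.shape}"
            )
        self.data = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with one condition label per sample."""

    data: pd.DataFrame
    condition_labels: pd.Series

    def __post_init__(self) -> None:
        df = self.data
        df.index = df.index.astype(str).str.upper()
        arr = df.to_numpy()
        if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
            raise FormatError("counts must be non-negative integers")
        self.data = df.astype(np.int64)
        labels = pd.Series(self.condition_labels)
        labels.index = labels.index.astype(str)
        labels = labels.reindex(df.columns)
        if labels.isna().any():
            missing = df.columns[labels.isna()].tolist()
            raise FormatError(f"samples without condition label: {missing}")
        counts = labels.value_counts()
        if (counts < 2).any():
            raise FormatError("every condition needs >=2 samples")
        self.condition_labels = labels

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets; genes stored upper-cased, ordered, de-duplicated."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(str(g).upper())
            if not seen:
                raise FormatError(f"gene set {name!r} is empty")
            canon[name] = list(seen)
        self.sets = canon
        self.descriptions = {k: self.descriptions.get(k, "") for k in canon}

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class InteractionGraph:
    """Undirected association graph with per-edge confidence in [0, 1].

    Node kind tags (``gene`` | ``compound`` | ``protein``) live in the node
    attribute ``kind``; confidences in the edge attribute ``confidence``.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            logger.warning("dropping %d self-loops", len(loops))
            g.remove_edges_from(loops)
        for u, v, conf in g.edges(data="confidence"):
            if conf is None or not (0.0 <= conf <= 1.0):
                raise FormatError(f"edge ({u},{v}) confidence {conf!r} outside [0,1]")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class PerturbagenLibrary:
    """Perturbagen x gene z-score matrix with perturbagen metadata.

    ``meta`` is indexed by perturbagen id with columns ``compound``,
    ``cell_line`` and ``pert_type`` (``compound`` | ``knockdown``);
    ``zscores`` shares the same index and has one column per gene.
    """

    meta: pd.DataFrame
    zscores: pd.DataFrame

    def __post_init__(self) -> None:
        self.zscores.columns = self.zscores.columns.astype(str).str.upper()
        if not self.meta.index.equals(self.zscores.index):
            raise FormatError("metadata rows do not match z-score matrix rows")
        if self.meta.index.duplicated().any():
            raise FormatError("duplicate perturbagen ids")
        missing = {"compound", "cell_line", "pert_type"} - set(self.meta.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.meta["pert_type"]) - {"compound", "knockdown"}
        if bad:
            raise FormatError(f"unknown perturbagen types: {sorted(bad)}")
        if self.zscores.isna().any().any():
            raise FormatError("missing z-scores in signature library")
        self.zscores = self.zscores.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.zscores.columns)

    @property
    def perturbagen_ids(self) -> list[str]:
        return list(self.meta.index)


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (days), event indicator and optional covariates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids in survival table")
        for col in ("time", "event"):
            if col not in df.columns:
                raise FormatError(f"survival table missing column {col!r}")
        df["time"] = df["time"].astype(float)
        if (df["time"] <= 0).any():
            bad = df.index[df["time"] <= 0].tolist()
            raise FormatError(f"non-positive survival times for samples {bad[:5]}")
        if not df["event"].isin([0, 1]).all():
            raise FormatError("event indicator must be 0 or 1")
        df["event"] = df["event"].astype(int)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def subset(self, samples) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(samples)].copy())


PGP_CATEGORIES = {"substrate", "non-substrate"}


@dataclass
class ScoreTable:
    """Per-compound predictor outputs (BBB scores, P-gp calls, co-occurrence counts)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate compound ids: {dups}")
        for col in df.columns:
            if df[col].dtype == object:
                vals = set(df[col].dropna().astype(str))
                if vals and vals <= PGP_CATEGORIES:
                    continue
                try:
                    df[col] = df[col].astype(float)
                except (TypeError, ValueError) as exc:
                    raise FormatError(
                        f"column {col!r} is neither numeric nor P-gp categorical: {exc}"
                    ) from None
        self.data = df

    @property
    def compounds(self) -> list[str]:
        return list(self.data.index)


@dataclass
class FingerprintSet:
    """Fixed-length binary fingerprints keyed by compound id."""

    data: pd.DataFrame  # compounds x bit positions, values in {0,1}

    def __post_init__(self) -> None:
        df = self.data
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise FormatError("duplicate compound ids in fingerprints")
        arr = df.to_numpy()
        if not np.isin(arr, [0, 1]).all():
            raise FormatError("fingerprint bits must be 0/1")
        self.data = df.astype(np.int8)

    @property
    def n_bits(self) -> int:
        return self.data.shape[1]

    def bits(self, compound: str) -> np.ndarray:
        return self.data.loc[compound].to_numpy()


# ---------------------------------------------------------------------------
# expression matrices: TSV and GCT v1.2
# ---------------------------------------------------------------------------


def _read_matrix_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from None
    return df


def _read_matrix_gct(path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    if body.columns[0] != "Name" or body.columns[1] != "Description":
        raise FormatError(f"{path}: GCT body must start with Name and Description columns")
    if body.shape[0] != n_genes or body.shape[1] - 2 != n_samples:
        raise FormatError(
            f"{path}: GCT header declares {n_genes}x{n_samples} but body is "
            f"{body.shape[0]}x{body.shape[1] - 2}"
        )
    df = body.set_index("Name").drop(columns="Description")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from None
    return df


def read_expression_matrix(path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT v1.2.

    ``format`` is ``"tsv"`` or ``"gct"``; when None it is inferred from the
    file extension (``.gct`` => GCT, anything else => TSV).
    """
    fmt = format or ("gct" if str(path).lower().endswith(".gct") else "tsv")
    if fmt == "gct":
        df = _read_matrix_gct(path)
    elif fmt == "tsv":
        df = _read_matrix_tsv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return ExpressionMatrix(df)


def write_expression_matrix(expr: ExpressionMatrix, path, format: str | None = None) -> None:
    fmt = format or ("gct" if str(path).lower().endswith(".gct") else "tsv")
    if fmt == "gct":
        n_genes, n_samples = expr.shape
        body = expr.data.copy()
        body.insert(0, "Description", "na")
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_genes}\t{n_samples}\n")
            body.to_csv(fh, sep="\t", index_label="Name", lineterminator="\n")
    else:
        expr.data.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


# ---------------------------------------------------------------------------
# gene sets (GMT text format: name <tab> description <tab> genes...)
# ---------------------------------------------------------------------------


def read_gene_sets(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: gene-set line needs name, description and >=1 gene"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
            desc[name] = fields[1]
    return GeneSetCollection(sets, desc)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# edge lists (STRING/STITCH-style)
# ---------------------------------------------------------------------------


def read_edge_list(
    path,
    min_confidence: float = 0.7,
    kind: str = "gene",
) -> InteractionGraph:
    """Read a tab-separated nodeA/nodeB/combined_score edge list.

    Scores on the STRING 0-1000 scale are auto-detected (any score > 1)
    and divided by 1000.  Edges with confidence strictly greater than
    ``min_confidence`` are retained; self-loops are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: edge list needs nodeA, nodeB, combined_score columns")
    a, b, score = df.columns[:3]
    scores = df[score].astype(float)
    if (scores < 0).any():
        raise FormatError(f"{path}: negative combined_score")
    if (scores > 1).any():
        scores = scores / 1000.0
        if (scores > 1).any():
            raise FormatError(f"{path}: scores exceed the STRING 0-1000 scale")
    g = nx.Graph()
    for u, v, conf in zip(df[a].astype(str).str.upper(), df[b].astype(str).str.upper(), scores):
        if u == v:
            logger.warning("dropping self-loop %s-%s", u, v)
            continue
        if conf > min_confidence:
            g.add_edge(u, v, confidence=float(conf))
    nx.set_node_attributes(g, kind, "kind")
    return InteractionGraph(g)


def write_edge_list(ig: InteractionGraph, path, string_scale: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write("nodeA\tnodeB\tcombined_score\n")
        for u, v, conf in sorted(ig.graph.edges(data="confidence")):
            out = int(round(conf * 1000)) if string_scale else conf
            fh.write(f"{u}\t{v}\t{out}\n")


# ---------------------------------------------------------------------------
# signature library (GCT-like z-score matrix + metadata sidecar)
# ---------------------------------------------------------------------------


def read_signature_library(matrix_path, meta_path) -> PerturbagenLibrary:
    """Read a perturbagen library: GCT matrix (perturbagen rows) + metadata TSV."""
    mat = _read_matrix_gct(matrix_path) if str(matrix_path).endswith(".gct") else _read_matrix_tsv(matrix_path)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    mat.index = mat.index.astype(str)
    if len(meta) != len(mat):
        raise FormatError(
            f"metadata has {len(meta)} rows but matrix has {len(mat)} perturbagens"
        )
    if set(meta.index) != set(mat.index):
        raise FormatError("metadata perturbagen ids do not match matrix rows")
    mat = mat.loc[meta.index]
    return PerturbagenLibrary(meta=meta, zscores=mat)


def write_signature_library(lib: PerturbagenLibrary, matrix_path, meta_path) -> None:
    lib.zscores.to_csv(matrix_path, sep="\t", index_label="perturbagen", lineterminator="\n")
    lib.meta.to_csv(meta_path, sep="\t", index_label="perturbagen", lineterminator="\n")


# ---------------------------------------------------------------------------
# survival, score tables, fingerprints
# ---------------------------------------------------------------------------


def read_survival_table(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SurvivalTable(df)


def write_survival_table(table: SurvivalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample", lineterminator="\n")


def read_score_table(path) -> ScoreTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreTable(df)


def write_score_table(table: ScoreTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="compound", lineterminator="\n")


def read_fingerprints(path) -> FingerprintSet:
    """Read compound fingerprints as TSV: compound <tab> bitstring (e.g. '01101...')."""
    rows: dict[str, list[int]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("compound"):
            raise FormatError(f"{path}: expected header starting with 'compound'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                cid, bitstring = line.split("\t")
            except ValueError:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated fields") from None
            if set(bitstring) - {"0", "1"}:
                raise FormatError(f"{path}:{lineno}: bitstring has non-binary characters")
            rows[cid] = [int(c) for c in bitstring]
    lengths = {len(v) for v in rows.values()}
    if len(lengths) > 1:
        raise FormatError(f"{path}: fingerprints of unequal length {sorted(lengths)}")
    return FingerprintSet(pd.DataFrame.from_dict(rows, orient="index"))


def write_fingerprints(fps: FingerprintSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("compound\tbits\n")
        for cid, row in fps.data.iterrows():
            fh.write(f"{cid}\t{''.join(str(int(b)) for b in row)}\n")


# ---------------------------------------------------------------------------
# count normalization
# ---------------------------------------------------------------------------


def lognorm_counts(counts: CountMatrix) -> ExpressionMatrix:
    """log-CPM transform: log2(1e6 * c_gs / library_size_s + 1).

    A monotone, variance-damping stand-in for count normalization; the
    rank/correlation-based downstream stages are insensitive to the exact
    transform.
    """
    libsize = counts.data.sum(axis=0)
    zero = libsize.index[libsize == 0].tolist()
    if zero:
        raise FormatError(f"samples with zero total counts: {zero}")
    cpm = counts.data * 1e6 / libsize
    return ExpressionMatrix(np.log2(cpm + 1.0))
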