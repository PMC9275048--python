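"""Readers and writers for every external format the pipeline touches.

Formats
-------
* expression matrix: TSV, genes in rows, one header row of sample ids,
  log-scale numeric values (the package expects already-normalized input,
  e.g. log2(TPM+1) or variance-stabilized values)
* sample annotation: CSV or TSV with columns ``sample_id``, ``subgroup``,
  optional ``response`` and arbitrary covariate columns
* curated interactions: SIF-like 3-column TSV (gene_a, relation, gene_b)
* gene sets: GMT (term, description, tab-separated member genes)
* network export: GraphML or a documented JSON schema
  (``{"nodes": [{"id": ...}], "edges": [{"source", "target", "provenance"}]}``)

Gene identity throughout is the uppercase symbol string; mismatches are
reported, never guessed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, ValidationError
from .network_core import InteractionNetwork, canonical_edge

logger = logging.getLogger(__name__)

RESPONSE_LEVELS = ("Good", "Moderate", "None")
_MISSING_MARKERS = {"", "NA", "N/A", "NaN", "nan", "missing"}


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Log-scale gene x sample expression values.

    Thin wrapper over a pandas DataFrame (genes in rows, samples in
    columns) enforcing unique uppercase gene symbols, unique sample ids and
    finite values.
    """

    def __init__(self, values: pd.DataFrame):
        df = values.copy()
        df.index = [str(g).upper() for g in df.index]
        df.columns = [str(s) for s in df.columns]
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = sorted(set(df.columns[df.columns.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self._df = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy(dtype=float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def gene(self, symbol: str) -> pd.Series:
        symbol = symbol.upper()
        if symbol not in self._df.index:
            raise KeyError(f"gene {symbol!r} not measured")
        return self._df.loc[symbol]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._df.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self._df.loc[:, list(sample_ids)])


class SampleAnnotation:
    """Per-sample subgroup and response labels plus arbitrary covariates.

    ``subgroup`` is a categorical label over a finite set; ``response``,
    when present, takes values Good / Moderate / None (EULAR-style response
    categories) or is missing.
    """

    def __init__(self, table: pd.DataFrame):
        if table.index.duplicated().any():
            dups = sorted(set(table.index[table.index.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if "subgroup" not in table.columns:
            raise ValidationError("annotation must contain a 'subgroup' column")
        if "response" in table.columns:
            bad = set(table["response"].dropna()) - set(RESPONSE_LEVELS)
            if bad:
                raise ValidationError(
                    f"unknown response label(s) {sorted(bad)}; expected {RESPONSE_LEVELS}"
                )
        else:
            table = table.copy()
            table["response"] = pd.Series([np.nan] * len(table), index=table.index, dtype=object)
        self._df = table

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def subgroup(self) -> pd.Series:
        return self._df["subgroup"]

    @property
    def subgroup_levels(self) -> list[str]:
        return sorted(self._df["subgroup"].unique())

    @property
    def response(self) -> pd.Series:
        return self._df["response"]

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self._df.columns if c not in ("subgroup", "response")]

    def covariate(self, name: str) -> pd.Series:
        if name not in self.covariate_names:
            raise KeyError(f"covariate {name!r} not in annotation")
        return self._df[name]

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    def samples_in_subgroup(self, label: str) -> list[str]:
        return list(self._df.index[self._df["subgroup"] == label])

    def subset(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        return SampleAnnotation(self._df.loc[list(sample_ids)])

    @property
    def outcome(self) -> pd.Series:
        """Binary response coding Good=1, None=0 (NaN elsewhere)."""
        return self._df["response"].map({"Good": 1.0, "None": 0.0})

    def __len__(self) -> int:
        return len(self._df)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT semantics)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def add(self, term: str, description: str, genes: Iterable[str]) -> None:
        genes = [g.upper() for g in genes]
        if not genes:
            raise ValidationError(f"gene set {term!r} is empty")
        if term in self.sets:
            raise ValidationError(f"duplicate gene-set term {term!r}")
        self.sets[term] = (description, genes)

    def genes(self, term: str) -> list[str]:
        return list(self.sets[term][1])

    def terms(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes-in-rows numeric matrix.

    Gene symbols are uppercased.  Duplicate gene rows are collapsed keeping
    the row with the highest mean (logged).  A non-numeric cell raises
    :class:`ParseError` naming the offending row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, keep_default_na=False, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: expression file has no data rows or sample columns")
    coarse = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(coarse.to_numpy(dtype=float))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    # numpy's string conversion is correctly rounded (full round-trip)
    numeric = pd.DataFrame(
        df.to_numpy().astype(float), index=df.index, columns=df.columns
    )
    numeric.index = [str(g).upper() for g in numeric.index]
    if numeric.index.duplicated().any():
        dup_symbols = sorted(set(numeric.index[numeric.index.duplicated()]))
        logger.warning(
            "collapsing %d duplicated gene symbol(s) by max-mean rule: %s",
            len(dup_symbols),
            dup_symbols[:5],
        )
        means = numeric.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        numeric = numeric.iloc[order]
        numeric = numeric[~numeric.index.duplicated(keep="first")]
        numeric = numeric.sort_index()
    return ExpressionMatrix(numeric)


def write_expression(expr: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a matrix read back by :func:`read_expression` at full float precision."""
    df = expr.frame.copy()
    df.index.name = "gene"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path, delimiter: str | None = None) -> SampleAnnotation:
    """Read a sample annotation table (CSV or TSV; delimiter inferred).

    Requires ``sample_id`` and ``subgroup`` columns; ``response`` is optional
    (missing values allowed, unknown labels rejected).  Remaining columns are
    covariates, converted to numeric where possible.
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = "\t" if "\t" in first else ","
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty annotation file") from exc
    if "sample_id" not in raw.columns:
        raise ValidationError(f"{path}: annotation must contain a 'sample_id' column")
    if "subgroup" not in raw.columns:
        raise ValidationError(f"{path}: annotation must contain a 'subgroup' column")
    if raw["sample_id"].duplicated().any():
        dups = sorted(set(raw["sample_id"][raw["sample_id"].duplicated()]))
        raise ValidationError(f"{path}: duplicated sample_id(s): {dups[:5]}")
    raw = raw.set_index("sample_id")

    table = pd.DataFrame(index=raw.index)
    table["subgroup"] = raw["subgroup"].astype(str)
    if "response" in raw.columns:
        resp = raw["response"].where(~raw["response"].isin(_MISSING_MARKERS), np.nan)
        table["response"] = resp
    for col in raw.columns:
        if col in ("subgroup", "response"):
            continue
        vals = raw[col].where(~raw[col].isin(_MISSING_MARKERS), np.nan)
        try:
            table[col] = pd.to_numeric(vals)
        except (ValueError, TypeError):
            table[col] = vals  # categorical covariate
    return SampleAnnotation(table)


# ---------------------------------------------------------------------------
# curated interactions (SIF-like)
# ---------------------------------------------------------------------------


def read_interactions(path: str | Path) -> InteractionNetwork:
    """Read a 3-column SIF-like interaction table into an undirected graph.

    Self-loops are dropped (logged); parallel/reversed duplicates merge their
    provenance tags.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            a, rel, b = (f.strip() for f in fields)
            records.append((a, rel, b))
    return InteractionNetwork.from_records(records)


def write_interactions(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(network.edges):
            for tag in sorted(network.provenance((a, b))):
                fh.write(f"{a}\t{tag}\t{b}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term, description, then tab-separated member genes."""
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT requires term, description and >=1 gene"
                )
            term, desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set {term!r} has no genes")
            coll.add(term, desc, genes)
    return coll


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in sets.sets.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

_PROVENANCE_SEP = "|"


def export_network(network: InteractionNetwork, path: str | Path, format: str | None = None) -> None:
    """Write a network as GraphML or JSON (lossless round-trip).

    Provenance sets serialize as sorted ``|``-joined strings in GraphML and
    as JSON arrays in the JSON schema.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(sorted(network.nodes))
        for a, b in sorted(network.edges):
            g.add_edge(a, b, provenance=_PROVENANCE_SEP.join(sorted(network.provenance((a, b)))))
        nx.write_graphml(g, path)
    elif fmt == "json":
        doc = {
            "nodes": [{"id": n} for n in sorted(network.nodes)],
            "edges": [
                {"source": a, "target": b, "provenance": sorted(network.provenance((a, b)))}
                for a, b in sorted(network.edges)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise FormatError(f"unsupported network format {fmt!r} (use graphml or json)")


def read_network(path: str | Path, format: str | None = None) -> InteractionNetwork:
    """Read a network previously written by :func:`export_network`."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    net = InteractionNetwork()
    if fmt == "graphml":
        g = nx.read_graphml(path)
        for n in g.nodes:
            net.add_node(str(n))
        for u, v, data in g.edges(data=True):
            tags = set(str(data.get("provenance", "")).split(_PROVENANCE_SEP)) - {""}
            net.add_edge(str(u), str(v), tags or {"unknown"})
    elif fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        for node in doc.get("nodes", []):
            net.add_node(node["id"])
        for edge in doc.get("edges", []):
            net.add_edge(edge["source"], edge["target"], set(edge.get("provenance", ["unknown"])))
    else:
        raise FormatError(f"unsupported network format {fmt!r} (use graphml or json)")
    return net


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

EDGE_TABLE_BASE_COLUMNS = [
    "gene_a",
    "gene_b",
    "response_gene",
    "predictor_gene",
    "wald",
    "df",
    "p_raw",
    "p_adj",
]


def write_edge_table(results: Sequence, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write differential-edge results as TSV.

    Columns: gene_a, gene_b, response_gene, predictor_gene, n_<group>...,
    slope_<group>..., wald, df, p_raw, p_adj.  An empty result list writes
    the base header only.
    """
    rows = [r.as_record() for r in results]
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=EDGE_TABLE_BASE_COLUMNS)
    _write_table(df, path, header_lines)


def _write_table(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by this package, skipping ``#`` header comments."""
    return pd.read_csv(path, sep="\t", comment="#")
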