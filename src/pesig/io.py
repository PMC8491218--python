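"""Readers and writers for the pipeline's on-disk artifacts.

Every identifier (gene symbol, alias, network node) is uppercased on
ingest: expression platforms, interaction files and alias tables mix
cases freely, and symbol joins across them must be exact.

File dialects are deliberately plain: tab-delimited matrices with a
feature-id first column, three-column SIF interaction files, two-column
alias tables, and a versioned JSON signature format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SENSITIVE = -1
RESISTANT = 1

SIGNATURE_FORMAT = "pesig-signature/1"


class FormatError(ValueError):
    """Structural problem in an input file (duplicate ids, bad shape)."""


class ParseError(ValueError):
    """Unparseable cell or line, reported with its location."""


class AliasConflictError(ValueError):
    """An alias maps to more than one approved symbol."""


class UnsupportedVersionError(ValueError):
    """Signature file written by an unknown format version."""


class IntegrityError(ValueError):
    """Signature file is truncated or internally inconsistent."""


def _upper(items: Iterable[str]) -> list[str]:
    return [str(s).strip().upper() for s in items]


@dataclass
class ExpressionMatrix:
    """Features x samples numeric matrix (log-scale expression or copy number).

    ``data`` is indexed by feature id (gene symbol or probe; duplicates
    allowed until probe collapsing) with one column per sample.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise FormatError(f"duplicate sample ids: {dupes}")
        self.data.index = pd.Index(_upper(self.data.index), name=self.data.index.name)
        self.data.columns = [str(c) for c in self.data.columns]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def has_feature(self, symbol: str) -> bool:
        return symbol.upper() in self.data.index

    def subset_features(self, symbols: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[[s.upper() for s in symbols]].copy())

    def feature_vector(self, symbol: str) -> np.ndarray:
        """Per-sample values for one feature; errors if the id is duplicated."""
        rows = self.data.loc[symbol.upper()]
        if isinstance(rows, pd.DataFrame):
            raise FormatError(
                f"feature {symbol!r} has {len(rows)} rows; collapse probes first"
            )
        return rows.to_numpy(dtype=float)

    def drop_incomplete(self) -> "ExpressionMatrix":
        """Drop features with any missing value, logging what was removed."""
        keep = self.data.notna().all(axis=1)
        dropped = sorted(set(self.data.index[~keep]))
        if dropped:
            logger.warning(
                "dropping %d feature(s) with missing values: %s",
                len(dropped),
                ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
            )
        return ExpressionMatrix(self.data.loc[keep].copy())


@dataclass
class ResponseTable:
    """Per-sample outcome: continuous GI50 (training) or binary label (validation).

    GI50 is on the -log10 molar scale. Binary labels are stored as
    +1 (resistant) / -1 (sensitive); see :data:`RESISTANT`/:data:`SENSITIVE`.
    Exactly one of ``gi50``/``label`` is populated.
    """

    gi50: pd.Series | None = None
    label: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.gi50 is None) == (self.label is None):
            raise FormatError("exactly one of gi50/label must be populated")
        series = self.gi50 if self.gi50 is not None else self.label
        ids = list(series.index)
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample ids in response table")
        if self.label is not None:
            bad = set(self.label.unique()) - {SENSITIVE, RESISTANT}
            if bad:
                raise FormatError(f"labels must be +-1 (resistant/sensitive), got {bad}")

    @property
    def sample_ids(self) -> list[str]:
        series = self.gi50 if self.gi50 is not None else self.label
        return list(series.index)


def encode_labels(labels: Sequence) -> pd.Series:
    """Coerce 'sensitive'/'resistant' strings or +-1 ints to the +-1 encoding."""
    mapping = {
        "sensitive": SENSITIVE,
        "resistant": RESISTANT,
        SENSITIVE: SENSITIVE,
        RESISTANT: RESISTANT,
    }
    if isinstance(labels, pd.Series):
        index = labels.index
        vals = labels.tolist()
    else:
        index = pd.RangeIndex(len(labels))
        vals = list(labels)
    out = []
    for v in vals:
        key = v.strip().lower() if isinstance(v, str) else int(v)
        if key not in mapping:
            raise FormatError(f"unrecognized response label {v!r}")
        out.append(mapping[key])
    return pd.Series(out, index=index, dtype=int)


def decode_labels(labels: Sequence[int]) -> list[str]:
    return ["resistant" if v == RESISTANT else "sensitive" for v in labels]


@dataclass
class InteractionNetwork:
    """Undirected gene-symbol graph with interaction-type tags on edges."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str]]) -> "InteractionNetwork":
        g = nx.Graph()
        for a, kind, b in edges:
            a, b = a.upper(), b.upper()
            if a == b:
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["types"].add(kind)
            else:
                g.add_edge(a, b, types={kind})
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a.upper(), b.upper())

    def neighbors(self, symbol: str) -> set[str]:
        symbol = symbol.upper()
        if symbol not in self.graph:
            return set()
        return set(self.graph.neighbors(symbol))

    def edge_types(self, a: str, b: str) -> set[str]:
        return set(self.graph.edges[a.upper(), b.upper()]["types"])

    def relabel(self, aliases: "AliasMap") -> "InteractionNetwork":
        """Map every node through the alias table (deprecated symbol cleanup)."""
        edges = []
        for a, b, data in self.graph.edges(data=True):
            aa, _ = aliases.resolve(a)
            bb, _ = aliases.resolve(b)
            for kind in data["types"]:
                edges.append((aa, kind, bb))
        return InteractionNetwork.from_edges(edges)


@dataclass
class AliasMap:
    """Functional alias -> approved-symbol mapping (both uppercase)."""

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AliasMap":
        mapping: dict[str, str] = {}
        for alias, approved in pairs:
            alias, approved = alias.upper(), approved.upper()
            if alias in mapping and mapping[alias] != approved:
                raise AliasConflictError(
                    f"alias {alias!r} maps to both {mapping[alias]!r} and {approved!r}"
                )
            mapping[alias] = approved
        # approved symbols always resolve to themselves
        for approved in list(mapping.values()):
            existing = mapping.get(approved)
            if existing is not None and existing != approved:
                raise AliasConflictError(
                    f"approved symbol {approved!r} is also an alias of {existing!r}"
                )
            mapping[approved] = approved
        return cls(mapping)

    def resolve(self, symbol: str) -> tuple[str, bool]:
        """Return (approved symbol, known?); unknown symbols pass through."""
        symbol = symbol.upper()
        if symbol in self.mapping:
            return self.mapping[symbol], True
        return symbol, False


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path, missing_token: str = "NA", dialect: str = "tsv"
) -> ExpressionMatrix:
    """Read a tab-delimited features x samples matrix.

    First column holds feature ids (retained verbatim apart from
    uppercasing; duplicate ids are kept for later probe collapsing),
    the header row holds sample ids. Cells must be numeric or equal to
    ``missing_token``.
    """
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"duplicate sample id(s) in header: {dupes}")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, skiprows=1,
        header=None, names=["__feature__"] + sample_ids,
    )
    numeric = pd.DataFrame(index=raw.index, columns=sample_ids, dtype=float)
    for col in sample_ids:
        cell = raw[col].str.strip()
        is_missing = cell == missing_token
        converted = pd.to_numeric(cell.where(~is_missing), errors="coerce")
        bad = converted.isna() & ~is_missing
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric value {cell[bad].iloc[0]!r} at feature {row!r}, "
                f"sample {col!r}"
            )
        numeric[col] = converted
    numeric.index = raw.index
    numeric.index.name = "feature"
    return ExpressionMatrix(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path, missing_token="NA") -> None:
    out = matrix.data.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t", na_rep=missing_token)


def read_gi50_table(path) -> ResponseTable:
    """Two-column (sample, gi50) tab-delimited table."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise FormatError(f"expected 2 columns (sample, gi50), got {df.shape[1]}")
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if values.isna().any():
        row = df.iloc[values.isna().to_numpy().nonzero()[0][0], 0]
        raise ParseError(f"non-numeric GI50 for sample {row!r}")
    series = pd.Series(values.to_numpy(), index=df.iloc[:, 0].astype(str).tolist())
    return ResponseTable(gi50=series)


def read_label_table(path) -> ResponseTable:
    """Two-column (sample, sensitive|resistant) tab-delimited table."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise FormatError(f"expected 2 columns (sample, label), got {df.shape[1]}")
    series = encode_labels(
        pd.Series(df.iloc[:, 1].tolist(), index=df.iloc[:, 0].astype(str).tolist())
    )
    return ResponseTable(label=series)


def write_response_table(responses: ResponseTable, path) -> None:
    if responses.gi50 is not None:
        df = pd.DataFrame({"sample": responses.gi50.index, "gi50": responses.gi50.values})
    else:
        df = pd.DataFrame(
            {"sample": responses.label.index, "label": decode_labels(responses.label)}
        )
    df.to_csv(path, sep="\t", index=False)


def read_sif(path, include_types: set[str] | None = None) -> InteractionNetwork:
    """Parse a 3-column SIF interaction file into an undirected network.

    Self-loops are dropped, duplicate edges merged (interaction types
    accumulate as tags). ``include_types`` optionally restricts to a
    subset of interaction types.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            a, kind, b = parts
            if include_types is not None and kind not in include_types:
                continue
            edges.append((a, kind, b))
    return InteractionNetwork.from_edges(edges)


def write_sif(network: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(network.graph.edges(data=True)):
            for kind in sorted(data["types"]):
                fh.write(f"{a}\t{kind}\t{b}\n")


def read_alias_map(path) -> AliasMap:
    """Two-column (alias, approved symbol) tab-delimited table."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            pairs.append((parts[0], parts[1]))
    return AliasMap.from_pairs(pairs)


def write_alias_map(aliases: AliasMap, path) -> None:
    with open(path, "w") as fh:
        for alias, approved in sorted(aliases.mapping.items()):
            fh.write(f"{alias}\t{approved}\n")


def read_gene_list(path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.upper())
    return genes


# ---------------------------------------------------------------------------
# signature serialization
# ---------------------------------------------------------------------------

def write_signature(model, path) -> None:
    """Serialize a trained SignatureModel losslessly as versioned JSON."""
    payload = {
        "format": SIGNATURE_FORMAT,
        "features": list(model.features),
        "C": float(model.C),
        "sigma": float(model.sigma),
        "criterion": model.criterion,
        "criterion_value": float(model.criterion_value),
        "condition_id": model.condition_id,
        "seed": int(model.seed),
        "decision": {
            "support_vectors": np.asarray(model.support_vectors).tolist(),
            "dual_coef": np.asarray(model.dual_coef).tolist(),
            "intercept": float(model.intercept),
            "gamma": float(model.gamma),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_signature(path):
    from .signature import SignatureModel  # local import to avoid a cycle

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise IntegrityError(f"{path}: truncated or corrupt signature file: {exc}")
    fmt = payload.get("format")
    if fmt != SIGNATURE_FORMAT:
        raise UnsupportedVersionError(
            f"{path}: format {fmt!r} not supported (expected {SIGNATURE_FORMAT!r})"
        )
    required = {"features", "C", "sigma", "criterion", "criterion_value", "decision"}
    missing = required - payload.keys()
    if missing:
        raise IntegrityError(f"{path}: missing fields {sorted(missing)}")
    dec = payload["decision"]
    sv = np.asarray(dec["support_vectors"], dtype=float)
    if sv.ndim != 2 or sv.shape[1] != len(payload["features"]):
        raise IntegrityError(f"{path}: support-vector block inconsistent with features")
    return SignatureModel(
        features=list(payload["features"]),
        C=float(payload["C"]),
        sigma=float(payload["sigma"]),
        criterion=payload["criterion"],
        criterion_value=float(payload["criterion_value"]),
        condition_id=payload.get("condition_id"),
        seed=int(payload.get("seed", 0)),
        support_vectors=sv,
        dual_coef=np.asarray(dec["dual_coef"], dtype=float),
        intercept=float(dec["intercept"]),
        gamma=float(dec["gamma"]),
    )
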