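"""Readers and writers for the package's plain-text formats.

Edge lists, node-role tables and property tables are tab-separated with a
header row; layer assignments are written as a deterministic TSV; all
statistical results serialize to JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .hierarchy import LayerPartition, LevelSpan
from .network import ROLES, DirectedNetwork, Edge

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("source", "target", "itype")
NODE_COLUMNS = ("id", "role")
_LAYER_ORDER = {"top": 0, "core": 1, "bottom": 2, "peripheral": 3, "substrate": 4}


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_network(edge_path: str | Path, node_path: str | Path) -> DirectedNetwork:
    """Load a signed directed network from an edge TSV and a node-role TSV.

    Duplicate (source, target, itype) triples are dropped with a warning;
    nodes appearing only in edges get role ``"other"``; an edge whose source
    is not an enzyme raises :class:`ValidationError`.
    """
    edges_df = _read_tsv(edge_path, EDGE_COLUMNS)
    nodes_df = _read_tsv(node_path, NODE_COLUMNS)
    if nodes_df["id"].duplicated().any():
        dups = nodes_df.loc[nodes_df["id"].duplicated(), "id"].tolist()
        raise FormatError(f"{node_path}: duplicated node id(s) {dups}")
    bad_roles = set(nodes_df["role"]) - set(ROLES)
    if bad_roles:
        raise FormatError(f"{node_path}: unknown role(s) {sorted(bad_roles)}")
    roles = dict(zip(nodes_df["id"], nodes_df["role"]))
    edges = [
        Edge(row.source, row.target, row.itype)
        for row in edges_df.itertuples(index=False)
    ]
    return DirectedNetwork.build(edges, roles=roles)


def write_network(
    network: DirectedNetwork, edge_path: str | Path, node_path: str | Path
) -> None:
    """Write sorted edge and node tables (round-trips with read_network)."""
    with open(edge_path, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in network.sorted_edges():
            fh.write(f"{e.source}\t{e.target}\t{e.itype}\n")
    with open(node_path, "w") as fh:
        fh.write("\t".join(NODE_COLUMNS) + "\n")
        for node in sorted(network.roles):
            fh.write(f"{node}\t{network.roles[node]}\n")


class PropertyTable:
    """Node -> numeric property values with per-column missing masks.

    Backed by a float DataFrame indexed by node id; empty cells become NaN.
    Columns whose observed values are all 0/1 are flagged boolean.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def column(self, name: str) -> pd.Series:
        return self.frame[name]

    def is_boolean(self, name: str) -> bool:
        vals = self.frame[name].dropna().unique()
        return len(vals) > 0 and set(vals) <= {0.0, 1.0}

    def missing_mask(self, name: str) -> pd.Series:
        return self.frame[name].isna()

    def values_for(self, name: str, ids) -> np.ndarray:
        """Non-missing values of *name* over the given ids."""
        sub = self.frame[name].reindex(sorted(ids))
        return sub.dropna().to_numpy()


def read_property_table(path: str | Path) -> PropertyTable:
    """Load a property TSV: first column ``id``, remaining columns numeric."""
    df = _read_tsv(path, ("id",))
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise FormatError(f"{path}: duplicated id row(s) {dups}")
    df = df.set_index("id")
    out = {}
    for col in df.columns:
        raw = df[col].replace("", np.nan)
        try:
            out[col] = raw.astype(float)
        except ValueError:
            bad = raw[pd.to_numeric(raw, errors="coerce").isna() & raw.notna()]
            row = int(df.index.get_loc(bad.index[0])) if len(bad) else -1
            raise FormatError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r} "
                f"(row index {row})"
            ) from None
    return PropertyTable(pd.DataFrame(out, index=df.index))


def write_property_table(table: PropertyTable, path: str | Path) -> None:
    df = table.frame.sort_index()
    df.to_csv(path, sep="\t", index_label="id", na_rep="")


def write_layers(
    partition: LayerPartition, spans: LevelSpan, path: str | Path
) -> None:
    """Write id / layer / level_min / level_max rows, ordered layer then id.

    Substrate-layer nodes have no span and get empty level cells; a node
    with a span but no layer is an internal consistency error.
    """
    layer_of = partition.layer_of()
    missing = sorted(spans.nodes() - set(layer_of))
    if missing:
        raise ValidationError(f"node(s) with a span but no layer: {missing}")
    rows = sorted(layer_of, key=lambda n: (_LAYER_ORDER[layer_of[n]], n))
    with open(path, "w") as fh:
        fh.write("id\tlayer\tlevel_min\tlevel_max\n")
        for n in rows:
            lo = spans.level_min.get(n, "")
            hi = spans.level_max.get(n, "")
            fh.write(f"{n}\t{layer_of[n]}\t{lo}\t{hi}\n")


def read_layers(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ("id", "layer", "level_min", "level_max"))


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_result_json(result: Any, path: str | Path) -> None:
    """Serialize a result object (dataclass / mapping) to pretty JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(result), fh, indent=2, sort_keys=False)
        fh.write("\n")
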