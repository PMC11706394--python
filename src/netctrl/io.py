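"""Reading and writing networks, node metadata and result tables.

Adjacency input is either a dense numeric CSV/TSV (optional header row of
node labels) or a three-column edge list (source, target, weight) with each
undirected edge stored once.  Results are written as tidy CSV with a JSON
provenance sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .brain_systems import NodePartition
from .graph_spectral import NetworkValidationError, WeightedNetwork

__all__ = [
    "read_network",
    "write_network",
    "read_partition",
    "write_results",
]


def _read_edge_list(df: pd.DataFrame) -> WeightedNetwork:
    df = df.iloc[:, :3].copy()
    df.columns = ["source", "target", "weight"]
    labels = sorted(set(df["source"].astype(str)) | set(df["target"].astype(str)))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    adj = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for src, dst, w in df.itertuples(index=False):
        i, j = index[str(src)], index[str(dst)]
        if i == j:
            raise NetworkValidationError(f"self-loop on node {src!r} not allowed")
        key = (min(i, j), max(i, j))
        w = float(w)
        if key in seen and seen[key] != w:
            raise NetworkValidationError(
                f"conflicting duplicate edge {src}-{dst}: weights {seen[key]} and {w}"
            )
        seen[key] = w
        adj[i, j] = adj[j, i] = w
    return WeightedNetwork(adjacency=adj, node_labels=tuple(labels))


def read_network(path: str | Path) -> WeightedNetwork:
    """Load a network from dense CSV/TSV or a 3-column edge list.

    A file whose rows form a square numeric matrix is treated as dense
    (with an optional label header row); a 3-column file is an edge list.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, header=None, comment="#", float_precision="round_trip")
    nrow, ncol = raw.shape
    first_row_numeric = pd.to_numeric(raw.iloc[0], errors="coerce").notna().all()
    if nrow == ncol and first_row_numeric:
        values = raw.apply(pd.to_numeric).to_numpy(dtype=float)
        looks_dense = ncol != 3 or (
            np.allclose(values, values.T) and np.all(np.diagonal(values) == 0)
        )
        if looks_dense:  # an ambiguous 3x3 is dense only if it is adjacency-shaped
            return WeightedNetwork(adjacency=values)
    if nrow == ncol + 1:
        labels = tuple(str(v) for v in raw.iloc[0])
        values = raw.iloc[1:].apply(pd.to_numeric).to_numpy(dtype=float)
        return WeightedNetwork(adjacency=values, node_labels=labels)
    if ncol == 3:
        # a non-numeric weight in the first row marks a header line
        if pd.to_numeric(raw.iloc[0, 2:3], errors="coerce").isna().any():
            raw = raw.iloc[1:].reset_index(drop=True)
        return _read_edge_list(raw)
    raise NetworkValidationError(
        f"cannot interpret {path}: shape {raw.shape} is neither square nor 3-column"
    )


def write_network(network: WeightedNetwork, path: str | Path, fmt: str = "edgelist") -> None:
    """Write a network as an edge-list TSV (default) or dense CSV."""
    path = Path(path)
    if fmt == "edgelist":
        ii, jj = np.nonzero(np.triu(network.adjacency))
        df = pd.DataFrame(
            {
                "source": [network.node_labels[i] for i in ii],
                "target": [network.node_labels[j] for j in jj],
                "weight": network.adjacency[ii, jj],
            }
        )
        # %.17g keeps the write/read round trip bit-exact
        df.to_csv(path, sep="\t", index=False, header=False, float_format="%.17g")
    elif fmt == "dense":
        df = pd.DataFrame(network.adjacency, columns=network.node_labels)
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_partition(path: str | Path) -> tuple[list[str], NodePartition]:
    """Read node metadata TSV: node_label, system, hemisphere[, x, y, z]."""
    df = pd.read_csv(path, sep="\t")
    required = {"node_label", "system", "hemisphere"}
    if not required <= set(df.columns):
        raise ValueError(f"partition file must have columns {sorted(required)}")
    coords = None
    if {"x", "y", "z"} <= set(df.columns) and df[["x", "y", "z"]].notna().all().all():
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    partition = NodePartition(
        system_label=tuple(df["system"].astype(str)),
        hemisphere=tuple(df["hemisphere"].astype(str)),
        coordinates=coords,
    )
    return list(df["node_label"].astype(str)), partition


def write_results(table: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Write a tidy results CSV plus a JSON provenance sidecar.

    The sidecar (``<stem>.provenance.json``) records the configuration,
    seeds and package version so any table can be regenerated.
    """
    from . import __version__

    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = path.with_suffix(".provenance.json")
    payload = {"package_version": __version__, **(provenance or {})}
    sidecar.write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
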