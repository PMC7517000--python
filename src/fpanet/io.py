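"""Reading and writing networks and analysis products.

Formats
-------
* Edge list: TSV, two columns of 0-based integer node ids, one
  undirected edge per line.  Lines starting with ``#`` are comments;
  ``# key=value`` comments carry generation metadata (n, m, f, seed).
* Node table: TSV with header ``node  parent  depth  degree`` (the
  root's parent is written as -1).
* GraphML: via networkx, with ``degree``, ``depth`` and ``parent``
  node attributes when the source is a :class:`NetworkState`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import networkx as nx
import numpy as np

from .generator import NetworkState

__all__ = [
    "write_edgelist",
    "read_edgelist",
    "write_node_table",
    "write_graphml",
    "read_graphml",
    "load_network",
]


def _metadata_of(network, extra: Optional[dict]) -> dict:
    meta = {}
    if isinstance(network, NetworkState):
        meta.update(network.meta)
    if extra:
        meta.update(extra)
    return meta


def write_edgelist(network, path, metadata: Optional[dict] = None) -> None:
    """Write a TSV edge list with ``# key=value`` metadata comments."""
    from .topology import as_arrays

    n, edges = as_arrays(network)
    meta = _metadata_of(network, metadata)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# fpanet edge list (undirected, 0-based node ids)\n")
        fh.write(f"# nodes={n}\n")
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_edgelist(path) -> Tuple[nx.Graph, dict]:
    """Read an edge-list TSV; returns the graph and its metadata."""
    meta: dict = {}
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body and " " not in body.split("=")[0]:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            u, v = line.split()[:2]
            g.add_edge(int(u), int(v))
    if "nodes" in meta:
        g.add_nodes_from(range(int(meta["nodes"])))
    g.graph.update(meta)
    return g, meta


def write_node_table(state: NetworkState, path) -> None:
    """Per-node table: id, parent (-1 for the root), depth, degree."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("node\tparent\tdepth\tdegree\n")
        for v in range(state.num_nodes):
            fh.write(f"{v}\t{state.parent[v]}\t{state.depth[v]}"
                     f"\t{state.degree[v]}\n")


def write_graphml(network, path) -> None:
    if isinstance(network, NetworkState):
        g = network.to_networkx()
        g.graph.update({k: str(v) for k, v in network.meta.items()})
    elif isinstance(network, nx.Graph):
        g = network
    else:
        from .topology import as_arrays
        n, edges = as_arrays(network)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(map(tuple, edges))
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    # GraphML stringifies ids; restore integers where possible
    try:
        return nx.relabel_nodes(g, {u: int(u) for u in g.nodes()})
    except ValueError:
        return g


def load_network(path, fmt: Optional[str] = None) -> nx.Graph:
    """Load a network by format name or file suffix."""
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix == ".graphml" else "edgelist"
    if fmt == "edgelist":
        g, _ = read_edgelist(path)
        return g
    if fmt == "graphml":
        return read_graphml(path)
    raise ValueError(f"unknown format {fmt!r} (use 'edgelist' or 'graphml')")
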