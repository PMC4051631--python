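"""Readers and writers: edge lists, GraphML, GEXF in; CSV, GEXF out.

Edge lists are parsed here (the dialect is two or three whitespace- or
comma-delimited columns, ``#`` comments). GraphML and GEXF go through
networkx, which implements the published schemas including the GEXF
``viz:position`` visualization namespace.
"""

from __future__ import annotations

import os

import numpy as np

from .graph import Graph

__all__ = ["load_graph", "write_layout"]

_EXT_FORMAT = {
    ".graphml": "graphml",
    ".gexf": "gexf",
    ".csv": "edgelist",
    ".tsv": "edgelist",
    ".txt": "edgelist",
    ".edges": "edgelist",
    ".edgelist": "edgelist",
}


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in _EXT_FORMAT:
        return _EXT_FORMAT[ext]
    raise ValueError(f"cannot infer graph format from extension {ext!r}")


def _parse_edge_list(path: str) -> Graph:
    pairs: list[tuple] = []
    weights: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            if len(fields) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))
            if len(fields) == 3:
                try:
                    weights.append(float(fields[2]))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                    ) from exc
            else:
                weights.append(1.0)
    return Graph.from_edge_pairs(pairs, weights=weights)


def load_graph(path: str, format: str | None = None) -> Graph:
    """Read a graph from ``path``.

    ``format`` is one of ``edgelist``, ``graphml``, ``gexf``; inferred from
    the extension when omitted. Missing weights and sizes default to 1;
    degrees are available on the returned :class:`Graph`.
    """
    fmt = _infer_format(path, format)
    if fmt == "edgelist":
        return _parse_edge_list(path)
    import networkx as nx

    if fmt not in ("graphml", "gexf"):
        raise ValueError(f"unknown graph format {fmt!r}")
    try:
        g = nx.read_graphml(path) if fmt == "graphml" else nx.read_gexf(path)
    except Exception as exc:  # parser error types vary (lxml, xml, networkx)
        raise ValueError(f"could not parse {path} as {fmt}: {exc}") from exc
    return Graph.from_networkx(g)


def write_layout(graph: Graph, path: str, format: str | None = None) -> None:
    """Write node positions (``csv``) or the full graph with positions
    (``gexf``). Positions must be finite; values keep ≥ 6 significant
    digits."""
    if graph.positions is None:
        raise ValueError("graph has no positions to write")
    if not np.all(np.isfinite(graph.positions)):
        bad = int(np.flatnonzero(~np.isfinite(graph.positions).all(axis=1))[0])
        raise ValueError(f"non-finite position for node {graph.ids[bad]!r}")
    fmt = format
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {"csv": "csv", "gexf": "gexf"}.get(ext.lstrip("."), None)
        if fmt is None:
            raise ValueError(f"cannot infer layout format from extension {ext!r}")
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write("id,x,y\n")
            for nid, (x, y) in zip(graph.ids, graph.positions):
                fh.write(f"{nid},{x:.8g},{y:.8g}\n")
    elif fmt == "gexf":
        import networkx as nx

        nx.write_gexf(graph.to_networkx(), path)
    else:
        raise ValueError(f"unknown layout format {fmt!r}")
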