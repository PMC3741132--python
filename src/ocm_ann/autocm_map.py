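"""Auto-contractive map training and the MST connectivity graph.

The network has one mono-dedicated first layer (weight ``v_i`` per variable)
and a full second-layer matrix ``w``; both contract toward the parameter
``C`` as records are presented.  For each record x (values in [0, 1]):

    h_i   = x_i (1 - v_i / C)
    dv_i  = (x_i - h_i)(1 - v_i / C)
    net_i = sum_j h_j (1 - w_ij / C)
    out_i = h_i (1 - net_i / C)
    dw_ij = (h_i - out_i)(1 - w_ij / C) h_j

As the first layer saturates (v -> C for active variables) the hidden signal
vanishes and w freezes; the converged w is monotone in pairwise variable
association.  Symmetrized weights convert to distances d = C - (w + w.T)/2,
a deterministic Kruskal MST filters the distance matrix, and edge link
strengths are the symmetrized weights scaled by their global maximum.

Note: the exact-zero weight initialization is a fixed point of the update
rule (dv = 0 when v = 0), so weights start at a small fraction of C instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "AutoCMModel",
    "ConnectivityMap",
    "train_autocm",
    "weights_to_distances",
    "minimum_spanning_tree",
    "build_map",
    "export_map",
    "import_graphml",
]


@dataclass
class AutoCMModel:
    C: float
    v: np.ndarray
    w: np.ndarray
    epochs: int
    delta_trace: list[float]
    converged: bool
    trained: bool = True

    @property
    def n_variables(self) -> int:
        return len(self.v)


def train_autocm(
    matrix: np.ndarray,
    C: float | None = None,
    max_epochs: int = 2000,
    tolerance: float = 1e-5,
    init_scale: float = 0.01,
) -> AutoCMModel:
    """Train on a records x variables matrix with entries in [0, 1].

    ``C`` defaults to the number of variables.  Records are presented in
    dataset order every epoch; training stops when the epoch's mean per-update
    |dv| drops below ``tolerance`` or at ``max_epochs``.
    """
    x = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 2:
        raise ValueError("matrix must be 2-D with >= 1 record and >= 2 variables")
    if np.min(x) < 0.0 or np.max(x) > 1.0:
        raise ValueError("matrix entries must lie in [0, 1]")
    n, p = x.shape
    if C is None:
        C = float(p)
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    v = np.full(p, init_scale * C)
    w = np.full((p, p), init_scale * C)
    trace: list[float] = []
    converged = False
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        total_dv = 0.0
        for record in x:
            hv = 1.0 - v / C
            h = record * hv
            dv = (record - h) * hv
            v += dv
            total_dv += float(np.abs(dv).sum())
            hw = 1.0 - w / C
            net = hw @ h
            out = h * (1.0 - net / C)
            w += ((h - out)[:, None] * hw) * h[None, :]
        mean_dv = total_dv / (n * p)
        trace.append(mean_dv)
        if mean_dv < tolerance:
            converged = True
            break
    return AutoCMModel(C=C, v=v, w=w, epochs=epoch, delta_trace=trace, converged=converged)


def weights_to_distances(model: AutoCMModel) -> np.ndarray:
    """d_ij = C - (w_ij + w_ji)/2 — stronger association, smaller distance.

    Symmetric, non-negative, zero diagonal.
    """
    if not getattr(model, "trained", False):
        raise ValueError("model is not trained")
    sym = (model.w + model.w.T) / 2.0
    d = np.clip(model.C - sym, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


def minimum_spanning_tree(distances: np.ndarray) -> list[tuple[int, int, float]]:
    """Kruskal MST with deterministic lexicographic tie-breaks.

    Returns (i, j, distance) with i < j, sorted by (distance, i, j).
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix must be finite")
    n = d.shape[0]
    edges = sorted(
        ((float(d[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: e,
    )
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree: list[tuple[int, int, float]] = []
    for weight, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j, weight))
            if len(tree) == n - 1:
                break
    if len(tree) != n - 1:
        raise ValueError("graph is not connected")
    return tree


@dataclass
class ConnectivityMap:
    nodes: list[str]
    distances: np.ndarray
    mst_edges: list[tuple[str, str, float]]  # (node, node, link strength)
    hubs: list[str]
    link_strengths: dict[tuple[str, str], float] = field(default_factory=dict)

    def neighbors(self, node: str) -> list[str]:
        out = []
        for a, b, _ in self.mst_edges:
            if a == node:
                out.append(b)
            elif b == node:
                out.append(a)
        return out


def build_map(
    model: AutoCMModel,
    distances: np.ndarray,
    mst: list[tuple[int, int, float]],
    node_names: list[str],
) -> ConnectivityMap:
    """Attach [0, 1] link strengths to the MST and identify hubs.

    Link strength of an edge is its symmetrized weight divided by the global
    maximum symmetrized off-diagonal weight, so the strongest-associated pair
    in the dataset scores 1.
    """
    p = model.n_variables
    if len(node_names) != p or distances.shape != (p, p):
        raise ValueError("inconsistent dimensions")
    sym = (model.w + model.w.T) / 2.0
    off = sym[~np.eye(p, dtype=bool)]
    max_weight = float(off.max())
    degree = np.zeros(p, dtype=int)
    named_edges: list[tuple[str, str, float]] = []
    strengths: dict[tuple[str, str], float] = {}
    for i, j, _ in mst:
        ls = float(sym[i, j] / max_weight) if max_weight > 0 else 0.0
        named_edges.append((node_names[i], node_names[j], ls))
        strengths[(node_names[i], node_names[j])] = ls
        degree[i] += 1
        degree[j] += 1
    top = degree.max()
    hubs = [node_names[i] for i in range(p) if degree[i] == top]
    return ConnectivityMap(
        nodes=list(node_names),
        distances=distances,
        mst_edges=named_edges,
        hubs=hubs,
        link_strengths=strengths,
    )


def _to_networkx(cmap: ConnectivityMap) -> nx.Graph:
    g = nx.Graph()
    hubset = set(cmap.hubs)
    for node in cmap.nodes:
        g.add_node(node, hub=node in hubset)
    for a, b, ls in cmap.mst_edges:
        g.add_edge(a, b, ls=float(ls), label=f"{ls:.2f}")
    return g


def export_map(cmap: ConnectivityMap, fmt: str = "graphml") -> str:
    """Serialize the map; ``graphml`` round-trips, ``dot`` is for rendering.

    Edge labels carry the link strength formatted to two decimals.
    """
    if fmt == "graphml":
        g = _to_networkx(cmap)
        return "\n".join(nx.generate_graphml(g))
    if fmt == "dot":
        lines = ["graph connectivity_map {"]
        for node in cmap.nodes:
            shape = "box" if node in set(cmap.hubs) else "ellipse"
            lines.append(f'  "{node}" [shape={shape}];')
        for a, b, ls in cmap.mst_edges:
            lines.append(f'  "{a}" -- "{b}" [label="{ls:.2f}"];')
        lines.append("}")
        return "\n".join(lines)
    raise ValueError(f"unknown format {fmt!r} (use 'graphml' or 'dot')")


def import_graphml(text: str) -> ConnectivityMap:
    """Rebuild a map from :func:`export_map` GraphML output."""
    g = nx.read_graphml(StringIO(text))
    nodes = list(g.nodes)
    edges = [(a, b, float(data["ls"])) for a, b, data in g.edges(data=True)]
    hubs = [n for n, data in g.nodes(data=True) if data.get("hub") in (True, "true", "True")]
    return ConnectivityMap(
        nodes=nodes,
        distances=np.zeros((len(nodes), len(nodes))),
        mst_edges=edges,
        hubs=hubs,
        link_strengths={(a, b): ls for a, b, ls in edges},
    )


def write_map(cmap: ConnectivityMap, outdir: str | Path, node_names: list[str] | None = None) -> list[Path]:
    """Write distances CSV, MST edge list CSV, GraphML and DOT files."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = node_names or cmap.nodes
    paths = []
    dist_path = outdir / "distances.csv"
    pd.DataFrame(cmap.distances, index=names, columns=names).to_csv(
        dist_path, float_format="%.10g"
    )
    paths.append(dist_path)
    edge_path = outdir / "mst_edges.csv"
    pd.DataFrame(
        [{"node_a": a, "node_b": b, "link_strength": round(ls, 6)} for a, b, ls in cmap.mst_edges]
    ).to_csv(edge_path, index=False)
    paths.append(edge_path)
    for fmt, suffix in (("graphml", "map.graphml"), ("dot", "map.dot")):
        path = outdir / suffix
        path.write_text(export_map(cmap, fmt))
        paths.append(path)
    return paths
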