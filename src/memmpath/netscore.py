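"""Dynamic-network analysis and critical-residue scoring.

Per macrostate, residues (nodes) are connected by an edge when they stay in
contact for a sufficient fraction of frames; edges are weighted by
-ln|c_ij| where c_ij is the Pearson correlation of displacement vectors
after superposing every frame onto the mean structure.  Optimal and
suboptimal paths between two anchor nodes are enumerated on these graphs;
a node's usage across suboptimal paths, its evolutionary conservation, and
its contact persistence combine into a single ranked score from which the
top candidates are drawn.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import floyd_warshall as _csgraph_fw

__all__ = [
    "PathSet",
    "node_correlation",
    "build_network",
    "floyd_warshall",
    "suboptimal_paths",
    "node_usage",
    "contact_persistence",
    "combined_score",
]

#: |c| floor before taking -ln|c| so that uncorrelated contacts get a large
#: but finite weight
CORRELATION_FLOOR = 1e-12


def _kabsch(P, Q):
    """Rotation matrix aligning P onto Q (both centered, (n, 3))."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(frames):
    """Least-squares superposition of all frames onto their mean structure.

    Two passes: align to the first frame, take the mean, re-align to the
    mean.  Returns the aligned frames.
    """
    frames = np.asarray(frames, dtype=float)
    ref = frames[0] - frames[0].mean(axis=0)
    for _ in range(2):
        aligned = np.empty_like(frames)
        for t, fr in enumerate(frames):
            x = fr - fr.mean(axis=0)
            aligned[t] = x @ _kabsch(x, ref).T
        ref = aligned.mean(axis=0)
    return aligned


def node_correlation(frames, superpose_frames: bool = True):
    """Pearson correlation of node displacement vectors.

    c_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr the deviation
    from the mean position after optimal superposition.  Zero-variance nodes
    yield NaN rows/columns and a warning.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (T, n_nodes, 3)")
    if len(frames) < 30:
        raise ValueError("need >= 30 frames for correlations")
    if superpose_frames:
        frames = superpose(frames)
    d = frames - frames.mean(axis=0, keepdims=True)
    dots = np.einsum("tif,tjf->ij", d, d) / len(frames)
    var = np.diag(dots).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"zero-variance nodes: {np.where(zero)[0].tolist()}")
        var[zero] = np.nan
    c = dots / np.sqrt(np.outer(var, var))
    return np.clip(c, -1.0, 1.0, out=c)


def contact_persistence_matrix(frames, cutoff: float):
    """Fraction of frames with inter-node distance below ``cutoff``."""
    frames = np.asarray(frames, dtype=float)
    T = len(frames)
    n = frames.shape[1]
    pers = np.zeros((n, n))
    for fr in frames:
        diff = fr[:, None, :] - fr[None, :, :]
        pers += np.linalg.norm(diff, axis=2) < cutoff
    return pers / T


def build_network(frames, contact_cutoff: float,
                  persistence_threshold: float = 0.75,
                  correlations=None, macrostate=None,
                  source=None, sink=None) -> nx.Graph:
    """Correlation-weighted contact graph of one macrostate ensemble.

    Edge (i, j) exists when the nodes are within ``contact_cutoff`` in at
    least ``persistence_threshold`` of frames; its weight is -ln|c_ij| with
    |c| floored at 1e-12 (and capped at 1, so weight >= 0).
    """
    if contact_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not 0 < persistence_threshold <= 1:
        raise ValueError("persistence threshold must be in (0, 1]")
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    if correlations is None:
        correlations = node_correlation(frames)
    pers = contact_persistence_matrix(frames, contact_cutoff)
    g = nx.Graph(macrostate=macrostate)
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if pers[i, j] >= persistence_threshold:
                c = abs(correlations[i, j])
                w = -np.log(min(max(c, CORRELATION_FLOOR), 1.0))
                g.add_edge(i, j, weight=float(w),
                           correlation=float(correlations[i, j]),
                           persistence=float(pers[i, j]))
    if source is not None and sink is not None and \
            not nx.has_path(g, source, sink):
        warnings.warn("source and sink are disconnected in this graph")
    return g


def floyd_warshall(graph: nx.Graph):
    """All-pairs shortest path lengths and predecessors (Floyd–Warshall).

    Returns (nodes, dist, pred): ``dist[i, j]`` is the shortest weighted
    distance (inf when disconnected), ``pred`` the predecessor matrix for
    path reconstruction.
    """
    nodes = list(graph.nodes)
    A = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight")
    dist, pred = _csgraph_fw(A, directed=False, return_predecessors=True)
    return nodes, dist, pred


def reconstruct_path(pred, nodes, source_idx, sink_idx):
    """Node sequence of one optimal path from the predecessor matrix."""
    path = [sink_idx]
    while path[-1] != source_idx:
        p = pred[source_idx, path[-1]]
        if p < 0:
            raise ValueError("no path between source and sink")
        path.append(int(p))
    return [nodes[i] for i in reversed(path)]


@dataclass
class PathSet:
    source: int
    sink: int
    optimal_length: float
    paths: list                 # node sequences, by (length, lexicographic)
    lengths: np.ndarray
    dilation: float
    max_paths: int
    truncated: bool


def suboptimal_paths(graph: nx.Graph, source, sink, dilation: float,
                     max_paths: int = 150_000) -> PathSet:
    """All simple paths within ``dilation`` of the optimal path length.

    Best-first enumeration ordered by a shortest-distance-to-sink lower
    bound, so paths are produced shortest first and truncation at
    ``max_paths`` keeps the near-optimal ones.  Deterministic order:
    (length, lexicographic node sequence).
    """
    if dilation < 0:
        raise ValueError("dilation must be >= 0")
    if source == sink:
        raise ValueError("source and sink must differ")
    nodes = list(graph.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    A = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight")
    from scipy.sparse.csgraph import dijkstra

    h = dijkstra(A, directed=False, indices=pos[sink])
    if np.isinf(h[pos[source]]):
        raise ValueError("source and sink are disconnected")
    opt = float(h[pos[source]])
    bound = opt + dilation + 1e-9
    # best-first over partial simple paths; key (g + h, path) gives
    # shortest-first with lexicographic tie-break
    heap = [(opt, (source,), 0.0)]
    out, lengths = [], []
    while heap and len(out) < max_paths:
        fval, path, g = heapq.heappop(heap)
        last = path[-1]
        if last == sink:
            out.append(list(path))
            lengths.append(g)
            continue
        for nb in sorted(graph.neighbors(last)):
            if nb in path:
                continue
            g2 = g + graph[last][nb]["weight"]
            f2 = g2 + h[pos[nb]]
            if f2 <= bound:
                heapq.heappush(heap, (f2, path + (nb,), g2))
    truncated = bool(heap) and len(out) >= max_paths
    order = sorted(range(len(out)),
                   key=lambda i: (round(lengths[i], 12), tuple(out[i])))
    out = [out[i] for i in order]
    lengths = np.array([lengths[i] for i in order])
    return PathSet(source=source, sink=sink, optimal_length=opt,
                   paths=out, lengths=lengths, dilation=dilation,
                   max_paths=max_paths, truncated=truncated)


def node_usage(pathsets, nodes=None) -> pd.Series:
    """Fraction of suboptimal paths traversing each node, averaged over
    macrostates, then min–max normalized to [0, 1]."""
    if not pathsets:
        raise ValueError("need at least one path set")
    if nodes is None:
        nodes = sorted({v for ps in pathsets for p in ps.paths for v in p})
    fracs = pd.DataFrame(0.0, index=list(nodes),
                         columns=range(len(pathsets)))
    for col, ps in enumerate(pathsets):
        if not ps.paths:
            raise ValueError("empty path set")
        for p in ps.paths:
            for v in set(p):
                if v in fracs.index:
                    fracs.loc[v, col] += 1.0
        fracs[col] /= len(ps.paths)
    raw = fracs.mean(axis=1)
    rng = raw.max() - raw.min()
    return (raw - raw.min()) / rng if rng > 0 else raw * 0.0


def contact_persistence(frames_per_macrostate, group_a, group_b,
                        cutoff: float) -> pd.Series:
    """Per-node contact persistence to a partner group, summed over
    macrostates and min–max normalized.

    For every macrostate ensemble and node in ``group_a``: the fraction of
    frames in which the node lies within ``cutoff`` of any node of
    ``group_b``; these fractions are summed across macrostates before
    normalization.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    total = pd.Series(0.0, index=group_a)
    for frames in frames_per_macrostate:
        frames = np.asarray(frames, dtype=float)
        if len(frames) == 0:
            raise ValueError("empty trajectory for a macrostate")
        da = frames[:, group_a, :]
        db = frames[:, group_b, :]
        dist = np.linalg.norm(da[:, :, None, :] - db[:, None, :, :], axis=3)
        total += pd.Series(np.mean(dist.min(axis=2) < cutoff, axis=0),
                           index=group_a)
    rng = total.max() - total.min()
    return (total - total.min()) / rng if rng > 0 else total * 0.0


def combined_score(usage: pd.Series, conservation, persistence: pd.Series,
                   top_k: int = 16, weights=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Ranked residue table combining the three normalized component scores.

    combined = w_u * usage + w_c * conservation + w_p * persistence, each
    component already in [0, 1].  Nodes missing a conservation entry score 0
    there and are flagged; ranks are unique (ties broken by usage, then node
    id) and the ``top_k`` highest combined scores are flagged candidates.
    """
    nodes = sorted(set(usage.index))
    cons = pd.Series(conservation, dtype=float)
    missing = [n for n in nodes if n not in cons.index]
    if missing:
        warnings.warn(f"no conservation score for nodes {missing}; using 0")
    rows = []
    for n in nodes:
        u = float(usage.get(n, 0.0))
        c = float(cons.get(n, 0.0))
        p = float(persistence.get(n, 0.0))
        rows.append((n, u, c, p,
                     weights[0] * u + weights[1] * c + weights[2] * p))
    df = pd.DataFrame(rows, columns=[
        "node", "usage", "conservation", "persistence", "combined",
    ])
    df = df.sort_values(["combined", "usage", "node"],
                        ascending=[False, False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    df["candidate"] = df["rank"] <= top_k
    return df.reset_index(drop=True)
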