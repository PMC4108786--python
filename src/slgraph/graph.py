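"""Fixed-degree binary graphs and per-node clustering / path-length metrics.

A connectivity matrix is thresholded by retaining the ``floor(n K / 2)``
strongest off-diagonal values as edges, fixing the mean degree at (almost)
K per node.  Per-node metrics follow the classic local definitions: the
clustering coefficient C is the fraction of a node's neighbour pairs that
are themselves connected, and the path length L is the arithmetic mean of
shortest-path hop distances to every other node, with unreachable nodes
contributing infinity.  Aggregation across epochs and sessions uses the
harmonic mean, which maps infinite path lengths to vanishing reciprocal
contributions and so stays finite whenever any epoch is finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sl import SLMatrix

__all__ = [
    "BinaryGraph",
    "threshold_to_degree",
    "node_clustering",
    "node_path_length",
    "node_metrics",
    "harmonic_aggregate",
    "metrics_table",
    "aggregate_design",
    "C_FLOOR_DEFAULT",
]

C_FLOOR_DEFAULT = 1e-6


@dataclass
class BinaryGraph:
    """Symmetric, irreflexive boolean adjacency with a target mean degree K."""

    adjacency: np.ndarray
    K: int
    band: str | None = None
    key: tuple | None = None

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj)):
            raise ValueError("no self-loops allowed")
        self.adjacency = adj

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def threshold_to_degree(sl: SLMatrix | np.ndarray, K: int) -> BinaryGraph:
    """Binary graph keeping the ``floor(n K / 2)`` strongest connections.

    Ties at the threshold are broken deterministically by ascending
    (row, column) index after sorting by descending connectivity, so the
    edge count is exact and reproducible.
    """
    if isinstance(sl, SLMatrix):
        values, band, key = sl.values, sl.band, sl.key
    else:
        values, band, key = np.asarray(sl, dtype=float), None, None
    n = values.shape[0]
    if not 1 <= K < n:
        raise ValueError(f"K must satisfy 1 <= K < n_channels={n}, got {K}")
    n_edges = (n * K) // 2
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    # stable sort on (-w, i, j): lexsort keys are applied last-key-primary
    order = np.lexsort((ju, iu, -w))
    keep = order[:n_edges]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return BinaryGraph(adjacency=adj, K=K, band=band, key=key)


def node_clustering(g: BinaryGraph, node: int) -> float:
    """Fraction of the node's neighbour pairs that are themselves connected.

    Nodes of degree < 2 have no neighbour pair and get C = 0.
    """
    adj = g.adjacency
    nbrs = np.flatnonzero(adj[node])
    k = nbrs.size
    if k < 2:
        return 0.0
    sub = adj[np.ix_(nbrs, nbrs)]
    return float(sub.sum() / (k * (k - 1)))


def _bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    """Hop distances from source to every node; unreachable -> inf."""
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    frontier = np.zeros(n, dtype=bool)
    frontier[source] = True
    d = 0
    while frontier.any():
        d += 1
        nxt = adj[frontier].any(axis=0) & np.isinf(dist)
        dist[nxt] = d
        frontier = nxt
    return dist


def node_path_length(g: BinaryGraph, node: int) -> float:
    """Arithmetic mean hop distance from the node to all other nodes.

    Any unreachable node contributes infinity, so L is infinite whenever the
    graph is disconnected as seen from ``node``.
    """
    dist = _bfs_distances(g.adjacency, node)
    others = np.delete(dist, node)
    if others.size == 0:
        return 0.0
    return float(np.mean(others))  # inf propagates


def node_metrics(g: BinaryGraph) -> tuple[np.ndarray, np.ndarray]:
    """Per-node (C, L) arrays for all nodes of a graph."""
    n = g.n_nodes
    C = np.array([node_clustering(g, v) for v in range(n)])
    L = np.array([node_path_length(g, v) for v in range(n)])
    return C, L


def harmonic_aggregate(values) -> float:
    """Harmonic mean ``n / sum(1/v)`` with ``1/inf := 0``.

    Finite whenever at least one value is finite; infinite only if all
    values are infinite.  Zero or negative finite values are rejected.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot aggregate an empty sequence")
    finite = np.isfinite(v)
    if np.any(v[finite] <= 0):
        raise ValueError("harmonic aggregation requires strictly positive values")
    recip_sum = np.sum(1.0 / v[finite])
    if recip_sum == 0.0:
        return float("inf")
    return float(v.size / recip_sum)


def metrics_table(
    graphs: dict[tuple, BinaryGraph], band: str, K: int
) -> pd.DataFrame:
    """Per-epoch, per-node metric table from a keyed collection of graphs.

    Keys are (subject, condition, session, epoch); columns are
    band, K, subject, condition, session, epoch, node, C, L.
    """
    rows = []
    for (subj, cond, sess, ep), g in sorted(graphs.items()):
        C, L = node_metrics(g)
        for node in range(g.n_nodes):
            rows.append(
                {
                    "band": band,
                    "K": K,
                    "subject": subj,
                    "condition": cond,
                    "session": sess,
                    "epoch": ep,
                    "node": node,
                    "C": C[node],
                    "L": L[node],
                }
            )
    return pd.DataFrame(rows)


def _two_stage_harmonic(df: pd.DataFrame, value: str) -> pd.DataFrame:
    by_session = (
        df.groupby(["band", "K", "subject", "condition", "session", "node"])[value]
        .apply(harmonic_aggregate)
        .reset_index()
    )
    out = (
        by_session.groupby(["band", "K", "subject", "condition", "node"])[value]
        .apply(harmonic_aggregate)
        .reset_index()
    )
    return out


def aggregate_design(
    metrics: pd.DataFrame, c_floor: float = C_FLOOR_DEFAULT
) -> pd.DataFrame:
    """Harmonic-mean aggregation over epochs within session, then sessions.

    Produces one C and one L per (band, K, subject, condition, node).
    Clustering coefficients of exactly 0 are floored at ``c_floor`` before
    harmonic aggregation (the harmonic mean is undefined at 0); the number
    of floored cells is reported via a warning.
    """
    required = {"band", "K", "subject", "condition", "session", "epoch", "node", "C", "L"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    full_index = ["band", "K", "subject", "condition", "session", "node"]
    counts = metrics.groupby(full_index)["epoch"].count()
    if counts.nunique() > 1:
        bad = counts[counts != counts.max()]
        raise ValueError(f"missing epochs for cells: {bad.index.tolist()[:5]}")
    df = metrics.copy()
    n_floored = int((df["C"] <= 0).sum())
    if n_floored:
        warnings.warn(
            f"floored {n_floored} zero clustering coefficients at {c_floor} "
            "before harmonic aggregation",
            stacklevel=2,
        )
        df.loc[df["C"] <= 0, "C"] = c_floor
    agg_c = _two_stage_harmonic(df, "C")
    agg_l = _two_stage_harmonic(df, "L")
    return agg_c.merge(agg_l, on=["band", "K", "subject", "condition", "node"])


def write_metrics_tsv(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, sep="\t", index=False, na_rep="nan")
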