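"""Node-wise paired tests and spatial cluster-based permutation inference.

The multiple-comparison problem over electrodes is handled with the
cluster-based permutation approach: node-wise paired t-tests between the
two conditions, spatial clusters formed from significant nodes that have at
least two significant neighbours, and a Monte-Carlo null distribution of the
maximal summed cluster t-value obtained by randomly swapping the condition
labels within each subject.  Positive and negative clusters are evaluated
against the corresponding tail's maximum-statistic null, each at the
configured per-tail alpha (default 0.025, i.e. a two-sided test).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_layout import ChannelLayout, RunConfig

__all__ = [
    "PairedSample",
    "Cluster",
    "ClusterResult",
    "nodewise_paired_t",
    "form_clusters",
    "permutation_test",
    "paired_sample_from_table",
]


@dataclass
class PairedSample:
    """Per-subject, per-node values for the two conditions.

    ``ns`` and ``tsd`` are (n_subjects, n_nodes) arrays with matching subject
    rows; node columns follow the channel-layout order.
    """

    ns: np.ndarray
    tsd: np.ndarray
    subjects: list[str]
    node_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.ns = np.asarray(self.ns, dtype=float)
        self.tsd = np.asarray(self.tsd, dtype=float)
        if self.ns.shape != self.tsd.shape:
            raise ValueError("NS and TSD arrays must have identical shape")
        if self.ns.shape[0] != len(self.subjects):
            raise ValueError("subject labels do not match array rows")
        if self.ns.shape[0] < 2:
            raise ValueError("need at least 2 subjects for a paired test")

    @property
    def differences(self) -> np.ndarray:
        """Per-subject TSD - NS differences, shape (n_subjects, n_nodes)."""
        return self.tsd - self.ns

    @property
    def n_nodes(self) -> int:
        return self.ns.shape[1]


def paired_sample_from_table(
    aggregated: pd.DataFrame, value: str, layout: ChannelLayout | None = None
) -> PairedSample:
    """Build a PairedSample from an aggregate_design table for metric ``value``.

    A cell is infinite only when a node was disconnected in every single
    epoch of a condition; such cells are capped at 1.5x the largest finite
    value in the table so the t statistics stay finite while the node still
    registers as extreme (a warning reports the number of capped cells).
    """
    piv = aggregated.pivot_table(
        index="subject", columns=["condition", "node"], values=value, sort=True
    )
    subjects = list(piv.index)
    nodes = sorted(aggregated["node"].unique())
    ns = piv["NS"][nodes].to_numpy()
    tsd = piv["TSD"][nodes].to_numpy()
    n_inf = int(np.isinf(ns).sum() + np.isinf(tsd).sum())
    if n_inf:
        finite = np.concatenate([ns[np.isfinite(ns)], tsd[np.isfinite(tsd)]])
        cap = 1.5 * finite.max() if finite.size else 1.0
        ns = np.where(np.isinf(ns), cap, ns)
        tsd = np.where(np.isinf(tsd), cap, tsd)
        warnings.warn(
            f"capped {n_inf} infinite aggregated {value} values at {cap:.3g}",
            stacklevel=2,
        )
    names = list(layout.names) if layout is not None else [str(n) for n in nodes]
    return PairedSample(ns=ns, tsd=tsd, subjects=subjects, node_names=names)


def _paired_t_from_diffs(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """t and two-sided p per column of a (n_subjects, n_nodes) difference array."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros(d.shape[1])
    p = np.ones(d.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        nz = sd > 0
        t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
        p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), df=n - 1)
        # zero-variance, non-zero mean: infinite t, p -> 0
        degen = (~nz) & (mean != 0)
        t[degen] = np.sign(mean[degen]) * np.inf
        p[degen] = 0.0
    return t, p


def nodewise_paired_t(sample: PairedSample) -> tuple[np.ndarray, np.ndarray]:
    """Paired t-test (TSD vs NS) for every node; returns (t, p) arrays.

    Zero-variance nodes with a non-zero mean difference yield t = +/-inf and
    p = 0 (with a warning); identically zero differences yield t = 0, p = 1.
    """
    t, p = _paired_t_from_diffs(sample.differences)
    if np.any(np.isinf(t)):
        warnings.warn(
            f"{int(np.isinf(t).sum())} node(s) with zero-variance differences; "
            "t reported as +/-inf with p = 0",
            stacklevel=2,
        )
    return t, p


def form_clusters(
    sig_mask: np.ndarray, adjacency: np.ndarray, t_values: np.ndarray | None = None
) -> list[np.ndarray]:
    """Spatial clusters of significant nodes.

    A node enters a cluster only if it is significant and has at least two
    significant neighbours; clusters are the connected components of the
    adjacency restricted to those candidate nodes, split by t-value sign
    when ``t_values`` is given.
    """
    sig = np.asarray(sig_mask, dtype=bool)
    adjacency = np.asarray(adjacency, dtype=bool)
    n_sig_nbrs = (adjacency & sig[None, :]).sum(axis=1)
    candidates = sig & (n_sig_nbrs >= 2)
    if not candidates.any():
        return []
    if t_values is None:
        sign_groups = [candidates]
    else:
        sign = np.sign(np.asarray(t_values))
        sign_groups = [candidates & (sign > 0), candidates & (sign < 0)]
    clusters: list[np.ndarray] = []
    for group in sign_groups:
        todo = set(np.flatnonzero(group))
        while todo:
            seed = todo.pop()
            comp = {seed}
            frontier = {seed}
            while frontier:
                nxt = set()
                for v in frontier:
                    for u in np.flatnonzero(adjacency[v]):
                        if u in todo:
                            nxt.add(u)
                            todo.discard(u)
                comp |= nxt
                frontier = nxt
            clusters.append(np.array(sorted(comp), dtype=int))
    clusters.sort(key=lambda c: (c[0], len(c)))
    return clusters


@dataclass
class Cluster:
    nodes: np.ndarray
    node_names: list[str]
    summed_t: float
    p_value: float
    significant: bool


@dataclass
class ClusterResult:
    """Observed clusters with Monte-Carlo p-values and per-node statistics."""

    clusters: list[Cluster]
    t_values: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    seed: int
    mc_alpha: float
    cluster_alpha: float
    node_names: list[str] = field(default_factory=list)

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.clusters)

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "mc_alpha": self.mc_alpha,
            "cluster_alpha": self.cluster_alpha,
            "clusters": [
                {
                    "nodes": [self.node_names[i] if self.node_names else int(i) for i in c.nodes],
                    "node_indices": [int(i) for i in c.nodes],
                    "summed_t": round(float(c.summed_t), 10),
                    "p_value": float(c.p_value),
                    "significant": bool(c.significant),
                }
                for c in self.clusters
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True)


def _max_tail_sums(
    t: np.ndarray, sig: np.ndarray, adjacency: np.ndarray
) -> tuple[float, float]:
    """(max positive summed t, max |negative summed t|) over clusters of one sample."""
    clusters = form_clusters(sig, adjacency, t_values=t)
    max_pos = 0.0
    max_neg = 0.0
    for c in clusters:
        s = float(np.sum(t[c]))
        if s > max_pos:
            max_pos = s
        if -s > max_neg:
            max_neg = -s
    return max_pos, max_neg


def _sign_flip_t(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-values for a batch of subject-level sign flips of the differences.

    Sign flips leave the per-node sum of squares unchanged, so the whole
    batch reduces to one matrix product plus elementwise algebra.
    """
    n = d.shape[0]
    means = signs @ d / n
    ss = np.sum(d * d, axis=0)
    var = (ss[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    t = np.zeros_like(means)
    with np.errstate(divide="ignore", invalid="ignore"):
        nz = var > 0
        t[nz] = (means / np.sqrt(var / n))[nz]
        degen = (~nz) & (means != 0)
        t[degen] = np.sign(means[degen]) * np.inf
    return t


def permutation_test(
    sample: PairedSample,
    adjacency: np.ndarray,
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Cluster-based Monte-Carlo permutation test on a paired sample.

    The null distribution swaps NS/TSD labels within each subject with an
    independent fair coin (equivalently, flips the sign of that subject's
    difference), recomputing node-wise t-tests and clusters each time.  Each
    observed cluster is compared against the maximum summed-t distribution of
    its own sign tail; the Monte-Carlo p-value uses the (+1)/(+1) correction.
    """
    if cfg.n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape[0] != sample.n_nodes:
        raise ValueError("adjacency size does not match sample nodes")
    d = sample.differences
    n_subj = d.shape[0]

    t_obs, p_obs = _paired_t_from_diffs(d)
    observed = form_clusters(p_obs < cfg.cluster_alpha, adjacency, t_values=t_obs)

    B = cfg.n_permutations
    signs = rng.choice([-1.0, 1.0], size=(B, n_subj))
    t_null = _sign_flip_t(d, signs)
    t_crit = stats.t.ppf(1.0 - cfg.cluster_alpha / 2.0, df=n_subj - 1)
    sig_null = np.abs(t_null) > t_crit
    # only permutations with >= 3 significant nodes can form a cluster
    null_pos = np.zeros(B)
    null_neg = np.zeros(B)
    nbr_counts = sig_null.astype(int) @ adjacency.astype(int)
    has_candidate = (sig_null & (nbr_counts >= 2)).any(axis=1)
    for b in np.flatnonzero(has_candidate):
        null_pos[b], null_neg[b] = _max_tail_sums(t_null[b], sig_null[b], adjacency)

    clusters = []
    names = sample.node_names or [str(i) for i in range(sample.n_nodes)]
    for c in observed:
        s = float(np.sum(t_obs[c]))
        if not np.isfinite(s):
            s = float(np.sign(s) * np.inf) if s != 0 else 0.0
        null = null_pos if s >= 0 else null_neg
        p_mc = (np.sum(null >= abs(s)) + 1.0) / (cfg.n_permutations + 1.0)
        clusters.append(
            Cluster(
                nodes=c,
                node_names=[names[i] for i in c],
                summed_t=s,
                p_value=float(p_mc),
                significant=bool(p_mc < cfg.mc_alpha),
            )
        )
    return ClusterResult(
        clusters=clusters,
        t_values=t_obs,
        p_values=p_obs,
        n_permutations=cfg.n_permutations,
        seed=cfg.seed,
        mc_alpha=cfg.mc_alpha,
        cluster_alpha=cfg.cluster_alpha,
        node_names=names,
    )
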