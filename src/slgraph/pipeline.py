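"""End-to-end orchestration: filter -> SL -> graphs -> metrics -> cluster
statistics -> mediation, with on-disk artifacts at every stage.

Every stage is callable on its own (the CLI exposes one subcommand per
stage) and ``run_all`` composes them; per-(band, K, metric) permutation
seeds are derived deterministically from the run seed so that a stage re-run
from saved intermediates reproduces the composed run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .clusterstats import ClusterResult, paired_sample_from_table, permutation_test
from .graph import aggregate_design, harmonic_aggregate, metrics_table, threshold_to_degree
from .io_layout import ChannelLayout, EpochSet, RunConfig
from .mediation import band_power_table, fit_mediation_models
from .preprocess import BandDefinition, bandpass
from .sl import SLMatrix, derive_params, sl_epochset

log = logging.getLogger("slgraph")

__all__ = [
    "stage_seed",
    "config_hash",
    "compute_band_sl",
    "band_metrics",
    "cluster_stats",
    "mediation_for_cluster",
    "run_all",
    "write_sl_matrices",
    "read_sl_matrices",
]


def stage_seed(seed: int, *labels) -> int:
    """Deterministic sub-seed for a labelled pipeline stage (< 2**31)."""
    tag = "|".join(str(x) for x in labels)
    return (seed ^ zlib.crc32(tag.encode())) % (2**31 - 1)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sl_matrices(mats: dict[tuple, SLMatrix], path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for (subj, cond, sess, ep), m in sorted(mats.items()):
            grp = f.require_group(f"{subj}/{cond}/{sess:03d}")
            ds = grp.create_dataset(f"{ep:03d}", data=m.values)
            ds.attrs["band"] = m.band or ""
    return path


def read_sl_matrices(path) -> dict[tuple, SLMatrix]:
    out = {}
    with h5py.File(path, "r") as f:
        for subj in f:
            for cond in f[subj]:
                for sess in f[subj][cond]:
                    for ep in f[subj][cond][sess]:
                        ds = f[subj][cond][sess][ep]
                        key = (subj, cond, int(sess), int(ep))
                        out[key] = SLMatrix(
                            values=ds[()], band=str(ds.attrs.get("band", "")) or None,
                            key=key,
                        )
    return out


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("stage=%s elapsed=%.2fs", stage, time.perf_counter() - self.t0)

    return _T()


def compute_band_sl(
    epochs: EpochSet, band: BandDefinition, cfg: RunConfig
) -> dict[tuple, SLMatrix]:
    """Band-pass filter an EpochSet and compute per-epoch SL matrices."""
    with _timed(f"filter[{band.name}]"):
        filtered = bandpass(epochs, band)
    params = derive_params(band, epochs.fs, cfg.p_ref, epochs.n_samples)
    with _timed(f"sl[{band.name}]"):
        return sl_epochset(filtered, params)


def band_metrics(
    sl_mats: dict[tuple, SLMatrix], band_name: str, K: int
) -> pd.DataFrame:
    """Threshold SL matrices at mean degree K and tabulate per-node C and L."""
    graphs = {key: threshold_to_degree(m, K) for key, m in sorted(sl_mats.items())}
    return metrics_table(graphs, band=band_name, K=K)


def cluster_stats(
    metrics: pd.DataFrame,
    layout: ChannelLayout,
    cfg: RunConfig,
    band_name: str,
    K: int,
) -> dict[str, ClusterResult]:
    """Aggregate a per-epoch metric table and run the cluster permutation
    test for both node metrics (C and L)."""
    if layout.adjacency is None:
        raise ValueError("layout adjacency not built")
    agg = aggregate_design(metrics, c_floor=cfg.c_floor)
    out = {}
    for metric in ("C", "L"):
        sample = paired_sample_from_table(agg, metric, layout)
        rng = np.random.default_rng(stage_seed(cfg.seed, band_name, K, metric))
        out[metric] = permutation_test(sample, layout.adjacency, cfg, rng=rng)
    return out


def node_stats_frame(results: dict[str, ClusterResult], band_name: str, K: int) -> pd.DataFrame:
    """Per-node t and p values of both metric tests as a flat table."""
    rows = []
    for metric, res in results.items():
        for node, (t, p) in enumerate(zip(res.t_values, res.p_values)):
            rows.append(
                {
                    "band": band_name,
                    "K": K,
                    "metric": metric,
                    "node": res.node_names[node] if res.node_names else node,
                    "t": t,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def _session_level(metrics: pd.DataFrame, metric: str, c_floor: float) -> pd.DataFrame:
    df = metrics.copy()
    if metric == "C":
        df.loc[df["C"] <= 0, "C"] = c_floor
    out = (
        df.groupby(["subject", "condition", "session", "node"])[metric]
        .apply(harmonic_aggregate)
        .reset_index()
        .rename(columns={metric: "metric"})
    )
    return out


def mediation_for_cluster(
    epochs: EpochSet,
    metrics: pd.DataFrame,
    cluster_nodes: list[int],
    band: BandDefinition,
    metric: str,
    cfg: RunConfig,
    layout: ChannelLayout,
):
    """Test whether band power mediates the condition effect on ``metric``
    within a cluster.  Outcomes are session-level harmonic aggregates; the
    mediator is the session-mean Welch band power at the same electrodes."""
    power = band_power_table(
        epochs, band, window_seconds=cfg.welch_window_seconds, overlap=cfg.welch_overlap
    )
    power = power[power["node"].isin(cluster_nodes)]
    med = (
        power.groupby(["subject", "condition", "session", "node"])["power"]
        .mean()
        .reset_index()
    )
    outcome = _session_level(
        metrics[metrics["node"].isin(cluster_nodes)], metric, cfg.c_floor
    )
    table = med.merge(outcome, on=["subject", "condition", "session", "node"])
    table["electrode"] = table["node"].map(lambda i: layout.names[i])
    table["day"] = table["condition"]
    return fit_mediation_models(table, outcome="metric", mediator="power")


def run_all(
    epochs: EpochSet,
    layout: ChannelLayout,
    cfg: RunConfig,
    out_dir: str | Path | None = None,
    run_mediation: bool = True,
) -> dict:
    """Execute the full analysis and return (and optionally write) the report.

    The report has one entry per (band, K) with the cluster test for both C
    and L, a mediation result for every significant cluster, and a per-band
    robustness flag stating whether a significant cluster was found for all
    configured K.
    """
    if layout.adjacency is None:
        raise ValueError("layout adjacency not built; call build_adjacency")
    if len(layout.names) != epochs.n_channels:
        raise ValueError(
            f"layout has {len(layout.names)} channels, epochs have {epochs.n_channels}"
        )
    for K in cfg.K_values:
        if K >= epochs.n_channels:
            raise ValueError(f"K={K} must be < n_channels={epochs.n_channels}")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "bands": {},
    }
    for band_name in sorted(cfg.bands):
        low, high = cfg.bands[band_name]
        band = BandDefinition(band_name, low, high)
        try:
            sl_mats = compute_band_sl(epochs, band, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage connectivity failed for band {band_name!r}") from exc
        band_entry: dict = {"K": {}}
        for K in cfg.K_values:
            with _timed(f"graphs[{band_name},K={K}]"):
                metrics = band_metrics(sl_mats, band_name, K)
            if out is not None:
                metrics.to_csv(
                    out / f"metrics_{band_name}_K{K}.tsv", sep="\t", index=False
                )
            with _timed(f"stats[{band_name},K={K}]"):
                results = cluster_stats(metrics, layout, cfg, band_name, K)
            if out is not None:
                node_stats_frame(results, band_name, K).to_csv(
                    out / f"nodestats_{band_name}_K{K}.tsv", sep="\t", index=False
                )
            k_entry: dict = {}
            for metric, res in results.items():
                k_entry[metric] = res.to_dict()
                if run_mediation:
                    med_entries = []
                    for ci, cl in enumerate(res.clusters):
                        if not cl.significant:
                            continue
                        mres = mediation_for_cluster(
                            epochs, metrics, [int(i) for i in cl.nodes],
                            band, metric, cfg, layout,
                        )
                        med_entries.append(
                            {"cluster_index": ci, **mres.to_dict()}
                        )
                    if med_entries:
                        k_entry[f"mediation_{metric}"] = med_entries
            band_entry["K"][str(K)] = k_entry
        for metric in ("C", "L"):
            band_entry[f"{metric}_significant_all_K"] = all(
                any(c["significant"] for c in band_entry["K"][str(K)][metric]["clusters"])
                for K in cfg.K_values
            )
        report["bands"][band_name] = band_entry
    if out is not None:
        with open(out / "report.json", "w") as f:
            json.dump(report, f, indent=2, sort_keys=True)
    return report
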