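"""Frozen reduced-scale study scenarios for validation experiments.

Full-scale studies (61 channels, 512 Hz, 8-s epochs, five bands, hundreds of
epochs) are expensive; these scenarios scale the design down to sizes where
repeated end-to-end runs are practical while keeping the statistical
structure intact:

* the *null* scenario — no planted effect — drives empirical type-I-error
  checks of the cluster permutation machinery (one band, one K, the
  clustering-coefficient test, so a run constitutes exactly one two-sided
  test family);
* the *effect* scenario plants the headline topography (frontal alpha
  decoupling read out through C, frontal theta decoupling read out through
  L) at 12 subjects — enough sign-flip patterns (2^12) that the Monte-Carlo
  p-value floor sits well below the 0.025 decision threshold.
"""

from __future__ import annotations

import numpy as np

from .clusterstats import paired_sample_from_table, permutation_test
from .graph import aggregate_design
from .io_layout import RunConfig
from .pipeline import band_metrics, compute_band_sl, stage_seed
from .preprocess import BandDefinition
from .synthdata import SynthConfig, generate_study

__all__ = [
    "null_scenario",
    "effect_scenario",
    "run_null_trial",
    "run_topography_trial",
]


def null_scenario(seed: int) -> tuple[SynthConfig, RunConfig]:
    """No-effect study: 8 subjects, 16 channels, 1 session, 4 epochs of 4 s
    at 128 Hz; analysis of the alpha band at K = 4."""
    synth = SynthConfig(
        n_subjects=8,
        n_sessions=1,
        n_epochs=4,
        epoch_seconds=4.0,
        fs=128.0,
        n_channels=16,
        bands={"alpha": (8.0, 13.0)},
        coupling_delta={},
        power_delta={},
        seed=seed,
    )
    run = RunConfig(
        bands={"alpha": (8.0, 13.0)},
        K_values=[4],
        n_permutations=1000,
        seed=seed,
    )
    return synth, run


def effect_scenario(seed: int) -> tuple[SynthConfig, RunConfig]:
    """Planted-topography study: frontal alpha decoupling (delta -0.8) and a
    partial frontal theta decoupling (delta -0.6, keeping the region weakly
    attached so paths lengthen without global disconnection), 12 subjects,
    25 channels, 2 sessions x 4 epochs of 4 s at 128 Hz; K in {7, 8}."""
    synth = SynthConfig(
        n_subjects=12,
        n_sessions=2,
        n_epochs=4,
        epoch_seconds=4.0,
        fs=128.0,
        n_channels=25,
        bands={"alpha": (8.0, 13.0), "theta": (4.0, 8.0)},
        coupling_delta={"alpha": -0.8, "theta": -0.6},
        power_delta={},
        seed=seed,
    )
    run = RunConfig(
        bands={"alpha": (8.0, 13.0), "theta": (4.0, 8.0)},
        K_values=[7, 8],
        n_permutations=1000,
        seed=seed,
    )
    return synth, run


def run_null_trial(seed: int) -> bool:
    """One null-study pipeline run; True iff any cluster (C or L test)
    reaches significance."""
    synth, run = null_scenario(seed)
    epochs, layout, _ = generate_study(synth)
    band = BandDefinition("alpha", *run.bands["alpha"])
    sl_mats = compute_band_sl(epochs, band, run)
    metrics = band_metrics(sl_mats, "alpha", run.K_values[0])
    agg = aggregate_design(metrics, c_floor=run.c_floor)
    for metric in ("C", "L"):
        sample = paired_sample_from_table(agg, metric, layout)
        rng = np.random.default_rng(stage_seed(run.seed, "alpha", run.K_values[0], metric))
        result = permutation_test(sample, layout.adjacency, run, rng=rng)
        if result.any_significant:
            return True
    return False


def run_topography_trial(seed: int) -> dict[str, bool]:
    """One planted-effect pipeline run.

    Returns flags for the two planted read-outs, each requiring, for every
    configured K, a significant majority-frontal cluster of the expected
    sign: ``alpha_C`` (negative summed t) and ``theta_L`` (positive).
    """
    synth, run = effect_scenario(seed)
    epochs, layout, truth = generate_study(synth)
    frontal = {layout.index(n) for n in truth.frontal_nodes}

    def frontal_cluster(result, sign: float) -> bool:
        for c in result.clusters:
            if c.significant and sign * c.summed_t > 0:
                if len(set(int(i) for i in c.nodes) & frontal) / len(c.nodes) >= 0.5:
                    return True
        return False

    flags = {"alpha_C": True, "theta_L": True}
    for band_name, metric, sign, flag in (
        ("alpha", "C", -1.0, "alpha_C"),
        ("theta", "L", +1.0, "theta_L"),
    ):
        band = BandDefinition(band_name, *run.bands[band_name])
        sl_mats = compute_band_sl(epochs, band, run)
        for K in run.K_values:
            metrics = band_metrics(sl_mats, band_name, K)
            agg = aggregate_design(metrics, c_floor=run.c_floor)
            sample = paired_sample_from_table(agg, metric, layout)
            rng = np.random.default_rng(stage_seed(run.seed, band_name, K, metric))
            result = permutation_test(sample, layout.adjacency, run, rng=rng)
            if not frontal_cluster(result, sign):
                flags[flag] = False
    return flags
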