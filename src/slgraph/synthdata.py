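"""Synthetic multichannel EEG studies with planted sleep-deprivation effects.

The generator emulates a within-subject sleep-deprivation design: each
subject is recorded under a normal-sleep (NS) and a total-sleep-deprivation
(TSD) condition, in several sessions of several fixed-length epochs, on a
quasi-equidistant planar electrode grid with a designated frontal subset.

Every channel is a sum over the analysis bands of band-limited Gaussian
sources plus broadband 1/f noise.  Within a band, each channel mixes a field
of latent sources (one per electrode site) with Gaussian spatial weights, so
inter-channel correlation decays smoothly with scalp distance — the smooth,
volume-conduction-like topography that makes fixed-degree graphs connect
into a local lattice.  The fraction of channel variance carried by the
shared field (the coupling strength) is set per band; under TSD the frontal
channels' coupling is shifted by a per-band delta and frontal band power is
scaled by a per-band factor.  Coupling and power effects are independently
switchable so connectivity changes with and without accompanying power
changes can both be planted.  Couplings receive a per-subject perturbation
to create between-subject variability; all draws descend from one seed.

The defaults mirror the reference study design (8 subjects x 2 conditions x
5 sessions x 8 epochs of 8 s at 512 Hz over 61 channels) and plant its
headline effect: a frontal alpha and theta decoupling under TSD, with an
alpha power decrease and a theta power increase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_layout import ChannelLayout, EpochSet, DEFAULT_BANDS, build_adjacency

__all__ = ["SynthConfig", "GroundTruth", "generate_layout", "generate_epoch",
           "generate_study", "simulate_mediation_dataset"]

# relative band source amplitudes (resting eyes-closed-like spectrum)
BAND_AMPLITUDES = {"delta": 2.0, "theta": 1.5, "alpha": 2.0, "beta": 0.8, "gamma": 0.4}


@dataclass
class SynthConfig:
    """Study design, signal structure, and planted TSD effects."""

    n_subjects: int = 8
    n_sessions: int = 5
    n_epochs: int = 8
    epoch_seconds: float = 8.0
    fs: float = 512.0
    n_channels: int = 61
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    band_amplitudes: dict = field(default_factory=lambda: dict(BAND_AMPLITUDES))
    base_coupling: dict = field(
        default_factory=lambda: {b: 0.9 for b in DEFAULT_BANDS}
    )  # per band: fraction of channel variance carried by the shared field
    spatial_scale: float = 1.2  # Gaussian source-weight length scale (grid units)
    coupling_delta: dict = field(
        default_factory=lambda: {"alpha": -0.8, "theta": -0.6}
    )  # additive change of the frontal channels' coupling under TSD; the
    # alpha drop is near-total (local cliques dissolve -> C falls), the theta
    # drop partial so the region stays weakly attached and its path lengths
    # grow without disconnecting the whole graph
    power_delta: dict = field(
        default_factory=lambda: {"alpha": -0.3, "theta": 0.3}
    )  # relative frontal band-power change under TSD
    noise_level: float = 1.0  # 1/f broadband noise amplitude
    subject_sd: float = 0.05  # sd of per-subject coupling perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in {
            "n_subjects": self.n_subjects,
            "n_sessions": self.n_sessions,
            "n_epochs": self.n_epochs,
            "n_channels": self.n_channels,
        }.items():
            if val < 1:
                raise ValueError(f"{name} must be >= 1, got {val}")
        for b, c in self.base_coupling.items():
            if not 0 <= c <= 1:
                raise ValueError(f"base coupling for {b!r} must be in [0, 1]")
        if self.spatial_scale <= 0:
            raise ValueError("spatial_scale must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """What was actually planted: effect nodes and per-subject couplings."""

    frontal_nodes: list[str]
    coupling_delta: dict
    power_delta: dict
    subject_couplings: dict  # subject -> {band: NS coupling}

    def to_json(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, sort_keys=True)
        return path


def generate_layout(
    n_channels: int, geometry: str = "grid", seed: int = 0
) -> tuple[ChannelLayout, list[str]]:
    """Quasi-equidistant planar grid layout and its frontal (top-third) subset.

    Positions get a small seeded jitter so the Delaunay triangulation is
    non-degenerate; the frontal subset contains the channels whose y
    coordinate lies in the top third of the layout's vertical extent.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    if geometry != "grid":
        raise ValueError(f"unknown geometry {geometry!r}")
    n_cols = int(np.ceil(np.sqrt(n_channels)))
    rng = np.random.default_rng(seed)
    names, pos = [], []
    for i in range(n_channels):
        r, c = divmod(i, n_cols)
        names.append(f"E{i + 1:02d}")
        # row 0 at the top (front of the head): largest y
        pos.append([c + 0.05 * rng.uniform(-1, 1), -r + 0.05 * rng.uniform(-1, 1)])
    pos = np.asarray(pos)
    layout = ChannelLayout(names=names, positions=pos)
    y = pos[:, 1]
    # top third of the vertical extent, with a margin exceeding the jitter so
    # the frontal set is a stable union of grid rows
    cut = y.min() + (2.0 / 3.0) * (y.max() - y.min()) + 0.1
    frontal = [names[i] for i in np.flatnonzero(y >= cut)]
    return layout, frontal


def _band_limited_noise(
    rng: np.random.Generator, shape, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance Gaussian noise with spectral support in [low, high] Hz.

    ``shape`` is (n_series, n_samples) or an int (one series).
    """
    if np.isscalar(shape):
        shape = (1, int(shape))
    n_series, n = shape
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    band = (freqs >= low) & (freqs <= high)
    k = int(band.sum())
    if k == 0:
        raise ValueError(f"no FFT bins in band ({low}, {high}) Hz for {n} samples")
    spec = np.zeros((n_series, len(freqs)), dtype=complex)
    spec[:, band] = rng.standard_normal((n_series, k)) + 1j * rng.standard_normal(
        (n_series, k)
    )
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pink_noise(rng: np.random.Generator, shape, fs: float) -> np.ndarray:
    """Unit-variance 1/f (amplitude ~ f^-0.5) broadband noise."""
    if np.isscalar(shape):
        shape = (1, int(shape))
    n_series, n = shape
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    nz = freqs > 0
    spec = np.zeros((n_series, len(freqs)), dtype=complex)
    amp = 1.0 / np.sqrt(freqs[nz])
    spec[:, nz] = amp * (
        rng.standard_normal((n_series, nz.sum()))
        + 1j * rng.standard_normal((n_series, nz.sum()))
    )
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _mixing_matrix(
    positions: np.ndarray, couplings: np.ndarray, spatial_scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Source mixing matrix and private weights for one band.

    One latent source sits at each electrode position; channel ``i`` weights
    source ``s`` by a Gaussian in their distance, with the row scaled so the
    shared field carries ``couplings[i]`` of the channel variance.  Returns
    (M, w_priv) with ``M @ sources + w_priv * private`` having unit variance.
    """
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    m0 = np.exp(-d2 / (2.0 * spatial_scale**2))
    norms = np.linalg.norm(m0, axis=1, keepdims=True)
    m = m0 / norms * np.sqrt(couplings)[:, None]
    w_priv = np.sqrt(np.clip(1.0 - couplings, 0.0, 1.0))
    return m, w_priv


def _subject_couplings(cfg: SynthConfig, rng: np.random.Generator) -> dict:
    """Per-subject NS coupling per band, jittered once per subject."""
    out = {}
    for s in range(cfg.n_subjects):
        subj = f"S{s + 1:02d}"
        out[subj] = {
            band: float(np.clip(base + cfg.subject_sd * rng.standard_normal(), 0.0, 0.98))
            for band, base in sorted(cfg.base_coupling.items())
        }
    return out


def generate_epoch(
    cfg: SynthConfig,
    rng: np.random.Generator,
    layout: ChannelLayout,
    frontal_mask: np.ndarray,
    condition: str,
    subject_coupling: dict | None = None,
) -> np.ndarray:
    """One (channels x samples) epoch for a given condition."""
    n = int(round(cfg.fs * cfg.epoch_seconds))
    n_ch = cfg.n_channels
    is_tsd = condition == "TSD"
    couplings = subject_coupling if subject_coupling is not None else cfg.base_coupling
    x = np.zeros((n_ch, n))
    for band_name in sorted(cfg.bands):
        low, high = cfg.bands[band_name]
        amp = cfg.band_amplitudes.get(band_name, 1.0)
        c_band = couplings.get(band_name, 0.0)
        c_vec = np.full(n_ch, c_band)
        if is_tsd:
            delta = cfg.coupling_delta.get(band_name, 0.0)
            c_vec[frontal_mask] = np.clip(c_band + delta, 0.0, 0.98)
        mix, w_priv = _mixing_matrix(layout.positions, c_vec, cfg.spatial_scale)
        sources = _band_limited_noise(rng, (n_ch, n), cfg.fs, low, high)
        private = _band_limited_noise(rng, (n_ch, n), cfg.fs, low, high)
        band_sig = mix @ sources + w_priv[:, None] * private
        scale = np.ones(n_ch)
        if is_tsd:
            p_scale = max(0.0, 1.0 + cfg.power_delta.get(band_name, 0.0))
            scale[frontal_mask] = np.sqrt(p_scale)
        x += amp * scale[:, None] * band_sig
    x += cfg.noise_level * _pink_noise(rng, (n_ch, n), cfg.fs)
    return x


def generate_study(cfg: SynthConfig) -> tuple[EpochSet, ChannelLayout, GroundTruth]:
    """Full factorial synthetic study: subjects x {NS, TSD} x sessions x epochs."""
    rng = np.random.default_rng(cfg.seed)
    layout, frontal = generate_layout(cfg.n_channels, seed=cfg.seed)
    layout = build_adjacency(layout, method="delaunay")
    frontal_mask = np.array([name in frontal for name in layout.names])
    subj_coup = _subject_couplings(cfg, rng)
    data = {}
    for s in range(cfg.n_subjects):
        subj = f"S{s + 1:02d}"
        for cond in ("NS", "TSD"):
            for sess in range(cfg.n_sessions):
                for ep in range(cfg.n_epochs):
                    data[(subj, cond, sess, ep)] = generate_epoch(
                        cfg, rng, layout, frontal_mask, cond, subj_coup[subj]
                    )
    epochs = EpochSet(data=data, fs=cfg.fs, channel_names=list(layout.names))
    truth = GroundTruth(
        frontal_nodes=frontal,
        coupling_delta=dict(cfg.coupling_delta),
        power_delta=dict(cfg.power_delta),
        subject_couplings=subj_coup,
    )
    return epochs, layout, truth


def simulate_mediation_dataset(
    scenario: str,
    n_subjects: int = 8,
    n_sessions: int = 5,
    n_electrodes: int = 5,
    a: float = 1.0,
    b: float = 0.8,
    direct: float = 0.8,
    seed: int = 0,
):
    """Long-format mediation test bed with known causal structure.

    Scenarios: ``"full"`` (condition -> mediator -> outcome, no direct path),
    ``"direct"`` (condition -> outcome only, mediator pure noise), and
    ``"null_a"`` (mediator unaffected by condition but predictive of the
    outcome).  Random intercepts for subject (sd 0.3), subject x day (sd 0.2)
    and subject x electrode (sd 0.2); residual sd 0.5.
    """
    import pandas as pd

    if scenario == "full":
        a_eff, b_eff, c_eff = a, b, 0.0
    elif scenario == "direct":
        a_eff, b_eff, c_eff = 0.0, 0.0, direct
    elif scenario == "null_a":
        a_eff, b_eff, c_eff = 0.0, b, direct
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subj = f"S{s + 1:02d}"
        u_subj_m, u_subj_y = 0.3 * rng.standard_normal(2)
        u_elec_m = 0.2 * rng.standard_normal(n_electrodes)
        u_elec_y = 0.2 * rng.standard_normal(n_electrodes)
        for cond, xval in (("NS", 0.0), ("TSD", 1.0)):
            u_day_m, u_day_y = 0.2 * rng.standard_normal(2)
            for sess in range(n_sessions):
                for e in range(n_electrodes):
                    med = (
                        a_eff * xval + u_subj_m + u_day_m + u_elec_m[e]
                        + 0.5 * rng.standard_normal()
                    )
                    out = (
                        b_eff * med + c_eff * xval + u_subj_y + u_day_y + u_elec_y[e]
                        + 0.5 * rng.standard_normal()
                    )
                    rows.append(
                        {
                            "subject": subj,
                            "condition": cond,
                            "day": cond,
                            "session": sess,
                            "electrode": f"e{e}",
                            "power": med,
                            "metric": out,
                        }
                    )
    return pd.DataFrame(rows)
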