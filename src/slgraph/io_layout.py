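"""Channel layouts, epoch containers, and run configuration.

The on-disk artifacts are deliberately plain: a tab-separated layout table
(``name``, ``x``, ``y``) with flattened 2-D scalp coordinates, an HDF5 epoch
container keyed by subject/condition/session/epoch, and a YAML run
configuration.  The layout also carries the electrode spatial-adjacency
relation used for cluster forming; since sensor caps rarely publish a
canonical neighbour definition, two constructions are provided (Delaunay
triangulation, the parameter-free default, and a Euclidean distance cutoff).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path


import h5py
import numpy as np
import pandas as pd
import yaml
from scipy.spatial import Delaunay

__all__ = [
    "ChannelLayout",
    "EpochSet",
    "RunConfig",
    "load_layout",
    "save_layout",
    "build_adjacency",
    "read_epochs",
    "write_epochs",
]

CONDITIONS = ("NS", "TSD")


@dataclass
class ChannelLayout:
    """Electrode names, planar positions, and the neighbour relation.

    Parameters
    ----------
    names : list of str
        Unique channel identifiers, in matrix row order.
    positions : ndarray, shape (n_channels, 2)
        Flattened scalp coordinates (arbitrary planar units).
    adjacency : ndarray of bool, shape (n_channels, n_channels), optional
        Symmetric, irreflexive neighbour relation; ``None`` until built.
    """

    names: list[str]
    positions: np.ndarray
    adjacency: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate channel names: {dupes}")
        if self.positions.shape != (len(self.names), 2):
            raise ValueError(
                f"positions must be ({len(self.names)}, 2), got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite channel coordinates")
        if self.adjacency is not None:
            self._check_adjacency(np.asarray(self.adjacency, dtype=bool))

    @staticmethod
    def _check_adjacency(adj: np.ndarray) -> None:
        if adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj)):
            raise ValueError("adjacency must have a false diagonal")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def neighbors(self, name: str) -> list[str]:
        if self.adjacency is None:
            raise ValueError("adjacency not built; call build_adjacency first")
        i = self.index(name)
        return [self.names[j] for j in np.flatnonzero(self.adjacency[i])]


def load_layout(path: str | Path) -> ChannelLayout:
    """Read a tab-separated layout table with columns ``name``, ``x``, ``y``."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"name", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"layout file {path} missing columns: {sorted(missing)}")
    names = df["name"].astype(str).tolist()
    try:
        xy = df[["x", "y"]].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric coordinates in layout file {path}") from exc
    return ChannelLayout(names=names, positions=xy)


def save_layout(layout: ChannelLayout, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"name": layout.names, "x": layout.positions[:, 0], "y": layout.positions[:, 1]}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def build_adjacency(
    layout: ChannelLayout, method: str = "delaunay", param: float | None = None
) -> ChannelLayout:
    """Populate the spatial neighbour relation of a layout.

    ``method="delaunay"`` links channels sharing a Delaunay-triangulation
    edge (parameter-free); ``method="distance"`` links channels whose
    Euclidean distance is at most ``param``.  Returns a new layout; the
    input is not modified.
    """
    pos = layout.positions
    n = layout.n_channels
    adj = np.zeros((n, n), dtype=bool)
    if method == "distance":
        if param is None or param <= 0:
            raise ValueError("distance method requires a positive cutoff param")
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        adj = d <= param
        np.fill_diagonal(adj, False)
    elif method == "delaunay":
        if n < 3:
            # degenerate: everything is a neighbour
            adj[:] = True
            np.fill_diagonal(adj, False)
        else:
            tri = Delaunay(pos)
            for simplex in tri.simplices:
                for a in simplex:
                    for b in simplex:
                        if a != b:
                            adj[a, b] = True
    else:
        raise ValueError(f"unknown adjacency method {method!r}")
    if n >= 2 and not adj.any(axis=1).all():
        isolated = [layout.names[i] for i in np.flatnonzero(~adj.any(axis=1))]
        warnings.warn(f"isolated channels (no neighbours): {isolated}", stacklevel=2)
    return ChannelLayout(names=list(layout.names), positions=pos.copy(), adjacency=adj)


@dataclass
class EpochSet:
    """Labelled collection of channels x samples epochs with a sampling rate.

    ``data`` maps ``(subject, condition, session, epoch)`` to a real matrix of
    shape (n_channels, n_samples); all matrices share shape and channel order.
    """

    data: dict[tuple[str, str, int, int], np.ndarray]
    fs: float
    channel_names: list[str]
    band: str | None = None

    def __post_init__(self) -> None:
        if not self.data:
            raise ValueError("EpochSet must contain at least one epoch")
        shapes = {m.shape for m in self.data.values()}
        if len(shapes) != 1:
            raise ValueError(f"epochs have inconsistent shapes: {sorted(shapes)}")
        shape = next(iter(shapes))
        if shape[0] != len(self.channel_names):
            raise ValueError(
                f"epoch channel count {shape[0]} != layout channels {len(self.channel_names)}"
            )
        for key in self.data:
            if key[1] not in CONDITIONS:
                raise ValueError(f"condition must be one of {CONDITIONS}, got {key[1]!r}")

    @property
    def n_channels(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return next(iter(self.data.values())).shape[1]

    @property
    def keys_df(self) -> pd.DataFrame:
        rows = [
            {"subject": s, "condition": c, "session": se, "epoch": e}
            for (s, c, se, e) in sorted(self.data)
        ]
        return pd.DataFrame(rows)

    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.data})

    def map_epochs(self, fn, band: str | None = None) -> "EpochSet":
        """Apply ``fn`` to every epoch matrix, keeping labels."""
        return EpochSet(
            data={k: fn(v) for k, v in sorted(self.data.items())},
            fs=self.fs,
            channel_names=list(self.channel_names),
            band=band if band is not None else self.band,
        )


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an EpochSet to an HDF5 container (bit-exact round trip)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["band"] = epochs.band if epochs.band is not None else ""
        f.attrs["channel_names"] = json.dumps(epochs.channel_names)
        for (subj, cond, sess, ep), mat in sorted(epochs.data.items()):
            grp = f.require_group(f"{subj}/{cond}/{sess:03d}")
            grp.create_dataset(f"{ep:03d}", data=np.asarray(mat, dtype=np.float64))
    return path


def read_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs`."""
    data: dict[tuple[str, str, int, int], np.ndarray] = {}
    with h5py.File(path, "r") as f:
        if "fs" not in f.attrs:
            raise ValueError(f"epoch container {path} missing 'fs' attribute")
        fs = float(f.attrs["fs"])
        band = str(f.attrs.get("band", "")) or None
        channel_names = json.loads(f.attrs["channel_names"])
        for subj in f:
            for cond in f[subj]:
                for sess in f[subj][cond]:
                    for ep in f[subj][cond][sess]:
                        data[(subj, cond, int(sess), int(ep))] = f[subj][cond][sess][
                            ep
                        ][()]
    return EpochSet(data=data, fs=fs, channel_names=channel_names, band=band)


DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass
class RunConfig:
    """Analysis configuration for the full pipeline.

    Defaults mirror the reference study design: five canonical EEG bands,
    mean degrees K of 5-8, recurrence probability 0.01, 1000 permutations,
    node-level alpha 0.05 and Monte-Carlo alpha 0.025 per tail.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    K_values: list[int] = field(default_factory=lambda: [5, 6, 7, 8])
    p_ref: float = 0.01
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    mc_alpha: float = 0.025
    seed: int = 0
    adjacency_method: str = "delaunay"
    adjacency_param: float | None = None
    c_floor: float = 1e-6
    welch_window_seconds: float = 2.0
    welch_overlap: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.p_ref < 1:
            raise ValueError(f"p_ref must be in (0, 1), got {self.p_ref}")
        for name, (low, high) in self.bands.items():
            if not (0 < low < high):
                raise ValueError(f"band {name!r}: need 0 < low < high, got ({low}, {high})")
        for k in self.K_values:
            if k < 1:
                raise ValueError(f"K must be >= 1, got {k}")
        self.bands = {k: (float(v[0]), float(v[1])) for k, v in self.bands.items()}

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(**raw)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=True)
        return path

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d
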