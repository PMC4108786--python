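"""Band-pass filtering and epoch segmentation.

Filtering is zero-phase FIR (forward-backward application of a Hamming-window
design), with the transition width set to 25% of the low band edge.  Applying
the filter to the continuous recording before segmentation keeps epoch
boundaries free of filter edge artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_layout import EpochSet

__all__ = ["BandDefinition", "design_fir", "bandpass", "bandpass_array", "segment"]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def validate(self, fs: float) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name!r}: need 0 < low < high")
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name!r}: high edge {self.high} Hz >= Nyquist {fs / 2} Hz"
            )


def design_fir(band: BandDefinition, fs: float, n_samples: int | None = None) -> np.ndarray:
    """Hamming-window band-pass FIR taps; transition width = 25% of the low edge.

    The order is capped so that forward-backward filtering remains applicable
    to a record of ``n_samples`` (a cap triggers a warning).
    """
    band.validate(fs)
    trans = 0.25 * band.low
    # Hamming window: ~3.3 / (normalized transition width) taps
    numtaps = int(np.ceil(3.3 * fs / trans))
    if numtaps % 2 == 0:
        numtaps += 1
    if n_samples is not None:
        cap = max(3, (n_samples - 2) // 3)
        if cap % 2 == 0:
            cap -= 1
        if numtaps > cap:
            warnings.warn(
                f"FIR order capped from {numtaps} to {cap} taps for a "
                f"{n_samples}-sample record; the {band.name} transition band widens",
                stacklevel=2,
            )
            numtaps = cap
    return signal.firwin(
        numtaps, [band.low, band.high], pass_zero=False, fs=fs, window="hamming"
    )


def bandpass_array(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase band-pass filter along the last axis."""
    taps = design_fir(band, fs, n_samples=x.shape[-1])
    return signal.filtfilt(taps, [1.0], x, axis=-1)


def bandpass(epochs: EpochSet, band: BandDefinition) -> EpochSet:
    """Filter every epoch into ``band``; the result is labelled with the band name."""
    band.validate(epochs.fs)
    taps = design_fir(band, epochs.fs, n_samples=epochs.n_samples)
    return epochs.map_epochs(
        lambda m: signal.filtfilt(taps, [1.0], m, axis=-1), band=band.name
    )


def segment(
    continuous: np.ndarray, fs: float, n_epochs: int, epoch_seconds: float
) -> list[np.ndarray]:
    """Cut a continuous (channels x samples) record into consecutive epochs.

    Epochs are non-overlapping prefixes: epoch ``e`` covers samples
    ``[e * L, (e + 1) * L)`` with ``L = fs * epoch_seconds``.
    """
    continuous = np.atleast_2d(np.asarray(continuous))
    samples_per_epoch = int(round(fs * epoch_seconds))
    needed = n_epochs * samples_per_epoch
    if continuous.shape[-1] < needed:
        raise ValueError(
            f"continuous record too short: need {needed} samples "
            f"({n_epochs} x {epoch_seconds} s at {fs} Hz), have {continuous.shape[-1]}"
        )
    return [
        continuous[:, e * samples_per_epoch : (e + 1) * samples_per_epoch].copy()
        for e in range(n_epochs)
    ]
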