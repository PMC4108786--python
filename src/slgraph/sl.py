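"""Synchronization likelihood (SL) between multichannel time series.

SL measures generalized (linear and nonlinear) synchronization between two
signals.  Each signal is time-delay embedded; for every reference time ``i``
a per-signal critical distance is chosen so that a fixed fraction ``p_ref``
of candidate times within a search annulus counts as *recurrent* (state
closer than the critical distance).  SL is then the conditional likelihood
that one signal is recurrent given that the other is, averaged over reference
times and symmetrized.  It equals ``p_ref`` in expectation for independent
stationary signals and 1 for identical signals.

Embedding parameters follow a frequency-prior recipe driven by the analysis
band (low edge LF, high edge HF) and sampling rate fs:

* ``lag   = round(fs / (3 HF))`` — about a third of the shortest period,
* ``m     = floor(3 HF / LF) + 1`` — spans the longest period,
* ``w1    = 2 lag (m - 1)`` — Theiler window excluding autocorrelated states,
* ``w2    = w1 + floor(n_rec / p_ref)`` with ``n_rec = 10`` expected
  recurrences per reference, capped at the available embedding length.

The inner loops (per-reference critical distances and recurrence bitmaps)
are JIT-compiled; pairwise coincidence counts use packed-bit popcounts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .io_layout import EpochSet
from .preprocess import BandDefinition

__all__ = [
    "SLParams",
    "SLMatrix",
    "derive_params",
    "embed",
    "critical_distance",
    "sl_pair",
    "sl_matrix",
    "sl_epochset",
]

N_RECURRENCES = 10  # target expected recurrences per reference time


@dataclass(frozen=True)
class SLParams:
    """Embedding and recurrence parameters for the SL computation."""

    lag: int
    m: int
    w1: int
    w2: int
    p_ref: float

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if not 0 < self.w1 < self.w2:
            raise ValueError(f"need 0 < w1 < w2, got w1={self.w1}, w2={self.w2}")
        if not 0 < self.p_ref < 1:
            raise ValueError("p_ref must be in (0, 1)")

    @property
    def window(self) -> int:
        """Samples consumed by the embedding: (m - 1) * lag."""
        return (self.m - 1) * self.lag


@dataclass
class SLMatrix:
    """Symmetric channels x channels SL matrix for one epoch and band."""

    values: np.ndarray
    band: str | None = None
    key: tuple | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("SL matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("SL matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("SL matrix must be finite")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _annulus_count(i: int, n: int, w1: int, w2: int) -> int:
    left = max(0, min(w2, i) - w1)
    right = max(0, min(w2, n - 1 - i) - w1)
    return left + right


def derive_params(
    band: BandDefinition,
    fs: float,
    p_ref: float,
    n_samples: int,
    n_recurrences: int = N_RECURRENCES,
) -> SLParams:
    """Derive SL embedding parameters from the band limits and sampling rate."""
    band.validate(fs)
    if not 0 < p_ref < 1:
        raise ValueError("p_ref must be in (0, 1)")
    lag = max(1, int(round(fs / (3.0 * band.high))))
    m = max(2, int(math.floor(3.0 * band.high / band.low)) + 1)
    w1 = 2 * lag * (m - 1)
    n_emb = n_samples - (m - 1) * lag
    if n_emb < 2:
        raise ValueError(
            f"epoch of {n_samples} samples too short for embedding "
            f"(m={m}, lag={lag} needs > {(m - 1) * lag} samples)"
        )
    w2 = min(w1 + int(math.floor(n_recurrences / p_ref)), n_emb - 1)
    if w2 <= w1:
        raise ValueError(
            f"epoch too short: search window collapses (w1={w1} >= w2={w2}); "
            f"need more than {(m - 1) * lag + w1 + 1} samples"
        )
    # candidate budget at the best-placed reference time
    c_mid = _annulus_count(n_emb // 2, n_emb, w1, w2)
    c_min_required = max(n_recurrences, int(math.ceil(1.0 / p_ref)))
    if c_mid < c_min_required:
        min_len = (m - 1) * lag + 2 * w1 + c_min_required + 2
        raise ValueError(
            f"epoch too short for p_ref={p_ref}: the search annulus holds "
            f"{c_mid} candidate times, need >= {c_min_required} "
            f"(minimum ~{min_len} samples)"
        )
    if c_mid < n_recurrences / p_ref:
        warnings.warn(
            f"search annulus holds {c_mid} candidates, fewer than the "
            f"{n_recurrences / p_ref:.0f} targeted for p_ref={p_ref}; "
            "recurrence counts will be small",
            stacklevel=2,
        )
    return SLParams(lag=lag, m=m, w1=w1, w2=w2, p_ref=p_ref)


def embed(x: np.ndarray, m: int, lag: int) -> np.ndarray:
    """Time-delay embedding: row ``i`` is ``(x[i], x[i+lag], ..., x[i+(m-1)lag])``."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("embed expects a 1-D series")
    n_emb = len(x) - (m - 1) * lag
    if n_emb < 1:
        raise ValueError(
            f"series of length {len(x)} too short for m={m}, lag={lag} "
            f"(needs > {(m - 1) * lag})"
        )
    idx = np.arange(n_emb)[:, None] + lag * np.arange(m)[None, :]
    return x[idx]


@njit(cache=True)
def _popcount64_swar(v):  # pragma: no cover - exercised through JIT
    v = v - ((v >> np.uint64(1)) & np.uint64(0x5555555555555555))
    v = (v & np.uint64(0x3333333333333333)) + (
        (v >> np.uint64(2)) & np.uint64(0x3333333333333333)
    )
    v = (v + (v >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (v * np.uint64(0x0101010101010101)) >> np.uint64(56)


@njit(cache=True)
def _recurrence_bits(emb, w1, w2, p_ref):  # pragma: no cover - exercised through JIT
    """Per-reference recurrence bitmap and recurrence counts for one channel.

    Returns (bits, counts): bits is (n, ceil(n/64)) uint64 with bit j of row i
    set iff time j is recurrent for reference i; counts[i] is the number of
    recurrent candidates (>= ceil(p_ref * n_candidates), ties included).
    """
    n, m = emb.shape
    n_words = (n + 63) // 64
    bits = np.zeros((n, n_words), dtype=np.uint64)
    counts = np.zeros(n, dtype=np.int64)
    dbuf = np.empty(n, dtype=np.float64)
    jbuf = np.empty(n, dtype=np.int64)
    kbuf = np.empty(n, dtype=np.float64)  # running k smallest distances, sorted
    for i in range(n):
        c = 0
        lo = i - w2
        if lo < 0:
            lo = 0
        hi = i + w2
        if hi > n - 1:
            hi = n - 1
        for j in range(lo, hi + 1):
            dij = i - j
            if dij < 0:
                dij = -dij
            if dij <= w1:
                continue
            d2 = 0.0
            for k in range(m):
                diff = emb[i, k] - emb[j, k]
                d2 += diff * diff
            dbuf[c] = d2
            jbuf[c] = j
            c += 1
        if c == 0:
            counts[i] = 0
            continue
        k_near = int(np.ceil(p_ref * c))
        if k_near < 1:
            k_near = 1
        if k_near > c:
            k_near = c
        # k-th smallest by insertion into a small sorted buffer (k << c)
        for t in range(k_near):
            kbuf[t] = np.inf
        for t in range(c):
            d2 = dbuf[t]
            if d2 < kbuf[k_near - 1]:
                pos = k_near - 1
                while pos > 0 and kbuf[pos - 1] > d2:
                    kbuf[pos] = kbuf[pos - 1]
                    pos -= 1
                kbuf[pos] = d2
        radius2 = kbuf[k_near - 1]
        cnt = 0
        for t in range(c):
            if dbuf[t] <= radius2:
                j = jbuf[t]
                bits[i, j >> 6] |= np.uint64(1) << np.uint64(j & 63)
                cnt += 1
        counts[i] = cnt
    return bits, counts


@njit(cache=True)
def _pair_sl_from_bits(bx, cx, by, cy):  # pragma: no cover - exercised through JIT
    """Symmetrized SL from two recurrence bitmaps."""
    n, n_words = bx.shape
    total = 0.0
    used = 0
    for i in range(n):
        if cx[i] == 0 or cy[i] == 0:
            continue
        hits = 0
        for w in range(n_words):
            v = bx[i, w] & by[i, w]
            if v != np.uint64(0):
                hits += int(_popcount64_swar(v))
        total += 0.5 * (hits / cx[i] + hits / cy[i])
        used += 1
    if used == 0:
        return 0.0
    return total / used


def _channel_bits(x: np.ndarray, params: SLParams):
    emb = embed(x, params.m, params.lag)
    n = emb.shape[0]
    if _annulus_count(n // 2, n, params.w1, min(params.w2, n - 1)) < 1:
        raise ValueError("empty candidate annulus: series too short for params")
    return _recurrence_bits(emb, params.w1, min(params.w2, n - 1), params.p_ref)


def critical_distance(embedded: np.ndarray, i: int, params: SLParams) -> float:
    """Euclidean critical distance at reference ``i``: the ``ceil(p_ref * n_cand)``-th
    nearest candidate within the ``(w1, w2]`` annulus."""
    emb = np.asarray(embedded, dtype=float)
    n = emb.shape[0]
    offsets = np.arange(n)
    dist_idx = np.abs(offsets - i)
    cand = np.flatnonzero((dist_idx > params.w1) & (dist_idx <= params.w2))
    if cand.size == 0:
        raise ValueError(f"empty candidate set at reference {i}")
    d = np.linalg.norm(emb[cand] - emb[i], axis=1)
    k = max(1, int(math.ceil(params.p_ref * cand.size)))
    return float(np.sort(d)[k - 1])


def sl_pair(x: np.ndarray, y: np.ndarray, params: SLParams) -> float:
    """Synchronization likelihood between two equally long series."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    bx, cx = _channel_bits(x, params)
    by, cy = _channel_bits(y, params)
    return float(_pair_sl_from_bits(bx, cx, by, cy))


def sl_matrix(
    epoch: np.ndarray,
    params: SLParams,
    band: str | None = None,
    key: tuple | None = None,
) -> SLMatrix:
    """SL between all channel pairs of one (channels x samples) epoch."""
    epoch = np.asarray(epoch, dtype=np.float64)
    n_ch = epoch.shape[0]
    if n_ch < 2:
        raise ValueError("need >= 2 channels")
    bits = []
    counts = []
    for ch in range(n_ch):
        b, c = _channel_bits(epoch[ch], params)
        bits.append(b)
        counts.append(c)
    values = np.eye(n_ch)
    for a in range(n_ch):
        for b_idx in range(a + 1, n_ch):
            v = _pair_sl_from_bits(bits[a], counts[a], bits[b_idx], counts[b_idx])
            values[a, b_idx] = values[b_idx, a] = v
    return SLMatrix(values=values, band=band, key=key)


def sl_epochset(epochs: EpochSet, params: SLParams) -> dict[tuple, SLMatrix]:
    """SL matrices for every epoch of an EpochSet, keyed like the input."""
    return {
        key: sl_matrix(mat, params, band=epochs.band, key=key)
        for key, mat in sorted(epochs.data.items())
    }
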