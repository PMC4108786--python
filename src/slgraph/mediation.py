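"""Band-power mediation analysis of condition effects on network metrics.

Volume conduction can masquerade as connectivity: a regional power change
alters the signal-to-noise ratio at several electrodes at once and can move
synchronization estimates without any true coupling change.  The mediation
design addresses this by asking whether band power within a significant
cluster statistically mediates the condition effect on the cluster's graph
metric.  Power enters as the mediator M, the condition (NS=0, TSD=1) as the
exposure X, and the node metric (C or L) as the outcome Y:

* model M1: ``M ~ X``           -> coefficient a (s_a)
* model M2: ``Y ~ M + X``       -> coefficient b (s_b) and beta_with (X)
* model M3: ``Y ~ X``           -> beta_without

all as linear mixed models with random intercepts for subject, for subject
within experimental day, and for electrode within subject.  Mediation holds
when (1) X affects M, (2) X affects Y, (3) M affects Y given X, and (4) the
X effect shrinks when M is added; the indirect effect is then tested with
the Sobel statistic ``Z = a b / sqrt(b^2 s_a^2 + a^2 s_b^2)``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal, stats

from .preprocess import BandDefinition

__all__ = [
    "MediationResult",
    "welch_band_power",
    "band_power_table",
    "fit_mediation_models",
    "sobel_z",
]


def welch_band_power(
    epoch: np.ndarray,
    fs: float,
    band: BandDefinition,
    window_seconds: float = 2.0,
    overlap: float = 0.5,
    mode: str = "mean",
) -> np.ndarray:
    """Per-channel Welch band power of a (channels x samples) epoch.

    Welch's averaged periodogram with Hamming windows of ``window_seconds``
    (default 2 s) and fractional ``overlap`` (default 50%).  ``mode="mean"``
    returns the mean spectral density over in-band bins (comparable across
    bands of different width); ``mode="integral"`` integrates the density
    over the band.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    nperseg = int(round(window_seconds * fs))
    if epoch.shape[-1] < nperseg:
        raise ValueError(
            f"epoch of {epoch.shape[-1]} samples shorter than one "
            f"{window_seconds} s Welch window ({nperseg} samples)"
        )
    noverlap = int(round(nperseg * overlap))
    freqs, psd = signal.welch(
        epoch, fs=fs, window="hamming", nperseg=nperseg, noverlap=noverlap, axis=-1
    )
    in_band = (freqs >= band.low) & (freqs <= band.high)
    if not in_band.any():
        raise ValueError(f"no frequency bins inside band {band.name}")
    if mode == "mean":
        return psd[:, in_band].mean(axis=-1)
    if mode == "integral":
        return np.trapezoid(psd[:, in_band], freqs[in_band], axis=-1)
    raise ValueError(f"unknown band power mode {mode!r}")


def band_power_table(
    epochs, band: BandDefinition, window_seconds: float = 2.0, overlap: float = 0.5
) -> pd.DataFrame:
    """Welch band power for every epoch and node of an EpochSet."""
    rows = []
    for (subj, cond, sess, ep), mat in sorted(epochs.data.items()):
        power = welch_band_power(mat, epochs.fs, band, window_seconds, overlap)
        for node, val in enumerate(power):
            rows.append(
                {
                    "band": band.name,
                    "subject": subj,
                    "condition": cond,
                    "session": sess,
                    "epoch": ep,
                    "node": node,
                    "power": float(val),
                }
            )
    return pd.DataFrame(rows)


def sobel_z(a: float, b: float, s_a: float, s_b: float) -> float:
    """Sobel test statistic ``a b / sqrt(b^2 s_a^2 + a^2 s_b^2)``."""
    denom = math.sqrt(b * b * s_a * s_a + a * a * s_b * s_b)
    if denom == 0.0:
        raise ValueError("Sobel denominator is zero (a*s_b and b*s_a both zero)")
    return a * b / denom


@dataclass
class MediationResult:
    """Coefficients, Sobel statistic and criteria flags of one mediation test."""

    a: float
    s_a: float
    p_a: float
    b: float
    s_b: float
    p_b: float
    beta_without: float
    p_without: float
    beta_with: float
    p_with: float
    sobel: float
    sobel_p: float
    criteria_met: tuple[bool, bool, bool, bool]
    mediation: str  # "none", "partial", or "full"
    converged: bool
    n_obs: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["criteria_met"] = list(self.criteria_met)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True)


def _fit_mixed(df: pd.DataFrame, formula: str) -> tuple[dict, bool]:
    """Random-intercept mixed model grouped by subject with day- and
    electrode-within-subject variance components; falls back to OLS when the
    mixed fit is singular or fails outright."""
    import statsmodels.formula.api as smf

    vc = {}
    if df["day"].nunique() > 1:
        vc["day"] = "0 + C(day)"
    if df["electrode"].nunique() > 1:
        vc["electrode"] = "0 + C(electrode)"
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["subject"], vc_formula=vc or None)
            fit = model.fit(reml=True, method="lbfgs")
            converged = bool(fit.converged)
            params, bse, pvals = fit.params, fit.bse, fit.pvalues
        except Exception:
            fit = smf.ols(formula, df).fit()
            converged = False
            params, bse, pvals = fit.params, fit.bse, fit.pvalues
    out = {}
    for name in params.index:
        out[name] = (float(params[name]), float(bse[name]), float(pvals[name]))
    return out, converged


def fit_mediation_models(
    data: pd.DataFrame,
    outcome: str = "metric",
    mediator: str = "power",
    alpha: float = 0.05,
) -> MediationResult:
    """Run the three-model mediation analysis on a long-format table.

    ``data`` needs columns ``subject``, ``condition`` (NS/TSD), ``electrode``,
    the mediator and the outcome; optional ``day`` (defaults to the condition
    label, i.e. one experimental day per condition) and ``session``.
    """
    df = data.copy()
    required = {"subject", "condition", "electrode", mediator, outcome}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mediation table missing columns: {sorted(missing)}")
    if df["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    df["x"] = (df["condition"] == "TSD").astype(float)
    if "day" not in df.columns:
        df["day"] = df["condition"]
    df = df.rename(columns={mediator: "_med", outcome: "_out"})

    m1, conv1 = _fit_mixed(df, "_med ~ x")
    m2, conv2 = _fit_mixed(df, "_out ~ _med + x")
    m3, conv3 = _fit_mixed(df, "_out ~ x")

    a, s_a, p_a = m1["x"]
    b, s_b, p_b = m2["_med"]
    beta_with, _, p_with = m2["x"]
    beta_without, _, p_without = m3["x"]

    try:
        z = sobel_z(a, b, s_a, s_b)
        sobel_p = 2.0 * stats.norm.sf(abs(z))
    except ValueError:
        z, sobel_p = float("nan"), float("nan")

    criteria = (
        p_a < alpha,  # condition affects mediator
        p_without < alpha,  # condition affects outcome
        p_b < alpha,  # mediator affects outcome, given condition
        abs(beta_with) < abs(beta_without),  # condition effect diminished
    )
    if all(criteria) and sobel_p < alpha:
        mediation = "partial" if p_with < alpha else "full"
    else:
        mediation = "none"
    return MediationResult(
        a=a,
        s_a=s_a,
        p_a=p_a,
        b=b,
        s_b=s_b,
        p_b=p_b,
        beta_without=beta_without,
        p_without=p_without,
        beta_with=beta_with,
        p_with=p_with,
        sobel=z,
        sobel_p=float(sobel_p),
        criteria_met=criteria,
        mediation=mediation,
        converged=conv1 and conv2 and conv3,
        n_obs=len(df),
    )
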