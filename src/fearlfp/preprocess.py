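"""LFP conditioning: downsampling, detrend, 60 Hz notch, artifact rejection.

The conditioning chain is: anti-alias downsample to the target rate
(1000 Hz), per-session linear detrend, zero-phase 58–62 Hz band-stop to
remove line noise, then automated per-trial artifact screening.  The notch
is applied forward-backward so it adds no phase distortion that would bias
downstream coherence phase estimates.

Artifact screening replaces a manual plot-and-reject step with a robust-z
criterion: a trial is flagged when more than ``artifact_min_frac`` of its
samples exceed ``artifact_z_thresh`` in median/MAD units computed over the
whole session, which makes the decision invariant to channel gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .session import EpochSet, Timeseries


@dataclass
class PreprocessParams:
    target_fs: float = 1000.0
    notch_band: tuple[float, float] = (58.0, 62.0)
    notch_order: int = 4
    artifact_z_thresh: float = 6.0
    artifact_min_frac: float = 0.001

    def __post_init__(self) -> None:
        lo, hi = self.notch_band
        if not 0 < lo < hi < self.target_fs / 2:
            raise ValueError(f"notch band {self.notch_band} invalid for "
                             f"target_fs {self.target_fs}")


def downsample(signal: Timeseries, target_fs: float) -> Timeseries:
    """Anti-alias filter and decimate to ``target_fs`` (rational ratios OK)."""
    if target_fs > signal.fs:
        raise ValueError(f"target_fs {target_fs} exceeds signal fs {signal.fs}")
    if target_fs == signal.fs:
        return signal.copy_with(signal.samples.copy())
    frac = Fraction(target_fs / signal.fs).limit_denominator(10000)
    y = sps.resample_poly(signal.samples, frac.numerator, frac.denominator)
    return signal.copy_with(y, fs=target_fs)


def detrend_notch(signal: Timeseries, params: PreprocessParams | None = None) -> Timeseries:
    """Remove the linear trend, then zero-phase band-stop the line-noise band."""
    params = params or PreprocessParams()
    x = sps.detrend(signal.samples, type="linear")
    sos = sps.butter(params.notch_order, params.notch_band,
                     btype="bandstop", fs=signal.fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return signal.copy_with(y)


def preprocess_signal(signal: Timeseries, params: PreprocessParams | None = None) -> Timeseries:
    params = params or PreprocessParams()
    if signal.fs > params.target_fs:
        signal = downsample(signal, params.target_fs)
    return detrend_notch(signal, params)


def robust_z(x: np.ndarray, center: float | None = None,
             scale: float | None = None) -> np.ndarray:
    """(x − median) / (1.4826 · MAD); scale-free outlier score."""
    center = np.median(x) if center is None else center
    if scale is None:
        scale = 1.4826 * np.median(np.abs(x - center))
    if scale == 0:
        return np.zeros_like(x)
    return (x - center) / scale


def reject_artifact_trials(epochs: EpochSet, params: PreprocessParams | None = None,
                           session_reference: np.ndarray | None = None
                           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag epochs contaminated by large transients.

    Returns ``(kept_mask, report)``: ``kept_mask[i]`` is True when trial i is
    clean; the report has one row per trial with the outlier fraction and
    the max robust-z, so rejection decisions are auditable.

    The median/MAD reference is the whole session when given, else the
    pooled epoch samples.
    """
    params = params or PreprocessParams()
    if epochs.n_trials < 1:
        raise ValueError("need at least one epoch")
    ref = (session_reference if session_reference is not None
           else epochs.data.ravel())
    center = np.median(ref)
    scale = 1.4826 * np.median(np.abs(ref - center))
    rows = []
    kept = np.ones(epochs.n_trials, dtype=bool)
    for i in range(epochs.n_trials):
        z = np.abs(robust_z(epochs.data[i], center, scale))
        frac = float(np.mean(z > params.artifact_z_thresh))
        flagged = frac > params.artifact_min_frac
        kept[i] = not flagged
        rows.append({"trial": int(epochs.trial_index[i]) if epochs.trial_index.size else i,
                     "flagged": flagged, "frac_outlier": frac,
                     "max_robust_z": float(z.max())})
    report = pd.DataFrame(rows)
    return kept, report
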