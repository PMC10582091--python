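"""Freezing quantification from the load-cell motion trace.

Freezing is operationalized as immobility lasting at least one second: the
detrended load-cell signal is converted to a moving-RMS motion envelope,
samples below a motion threshold are candidate immobility, and maximal
immobile runs of >= ``min_bout`` seconds become freezing bouts (half-open
intervals).  The threshold can be given in absolute load-cell units or in
robust-z units of the envelope, which makes scoring invariant to the load
cell's gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .session import EventTable, Timeseries


@dataclass
class FreezingParams:
    """Freezing-detection parameters.

    ``threshold_mode``:

    * ``auto`` (default) — threshold at the geometric midpoint of the 5th
      and 95th percentiles of the motion envelope, which lands between the
      immobile and mobile envelope modes whenever both states occupy more
      than ~5% of the session;
    * ``robust_z`` — ``median + motion_threshold × MAD`` of the envelope
      (gain-invariant, but unstable when the envelope is strongly bimodal);
    * ``absolute`` — ``motion_threshold`` in raw load-cell units.
    """

    motion_threshold: float = 0.0        # used by robust_z / absolute modes
    threshold_mode: str = "auto"         # auto | robust_z | absolute
    smoothing_window: float = 0.2        # s, moving-RMS window
    min_bout: float = 1.0                # s

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("auto", "robust_z", "absolute"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "absolute" and self.motion_threshold <= 0:
            raise ValueError("absolute motion_threshold must be positive")
        if self.min_bout <= 0 or self.smoothing_window <= 0:
            raise ValueError("durations must be positive")


def motion_envelope(loadcell: Timeseries, smoothing_window: float = 0.2
                    ) -> np.ndarray:
    """Moving RMS of the detrended load-cell signal."""
    x = sps.detrend(loadcell.samples, type="linear")
    w = max(1, int(round(smoothing_window * loadcell.fs)))
    kernel = np.ones(w) / w
    pad = np.pad(x ** 2, (w // 2, w - 1 - w // 2), mode="edge")
    return np.sqrt(np.convolve(pad, kernel, mode="valid"))


def detect_freezing(loadcell: Timeseries, params: FreezingParams | None = None
                    ) -> list[tuple[float, float]]:
    """Freezing bouts as half-open ``[start, stop)`` intervals in seconds."""
    params = params or FreezingParams()
    if loadcell.duration <= params.min_bout:
        raise ValueError("trace shorter than the minimum bout duration")
    env = motion_envelope(loadcell, params.smoothing_window)
    if params.threshold_mode == "auto":
        lo, hi = np.percentile(env, [5, 95])
        thr = float(np.sqrt(max(lo, 1e-12) * max(hi, 1e-12)))
    elif params.threshold_mode == "robust_z":
        med = np.median(env)
        mad = 1.4826 * np.median(np.abs(env - med))
        thr = med + params.motion_threshold * mad if mad > 0 else np.inf
    else:
        thr = params.motion_threshold
    immobile = env < thr
    fs = loadcell.fs
    min_run = int(round(params.min_bout * fs))
    bouts: list[tuple[float, float]] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], immobile.view(np.int8), [0]))))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        if i1 - i0 >= min_run:
            bouts.append((loadcell.t0 + i0 / fs, loadcell.t0 + i1 / fs))
    return bouts


def freezing_mask(bouts: list[tuple[float, float]], times: np.ndarray) -> np.ndarray:
    """Boolean per-sample freezing indicator for agreement scoring."""
    m = np.zeros(times.size, dtype=bool)
    for a, b in bouts:
        m |= (times >= a) & (times < b)
    return m


def epoch_freezing(bouts: list[tuple[float, float]], events: EventTable,
                   kinds: tuple[str, ...] = ("baseline", "CS")) -> pd.DataFrame:
    """Percent time frozen per epoch: 100 × bout-epoch overlap / duration."""
    rows = []
    for _, row in events.df.iterrows():
        if row["kind"] not in kinds:
            continue
        dur = row["offset"] - row["onset"]
        if dur <= 0:
            raise ValueError(f"zero-length epoch {row['kind']} "
                             f"trial {row['trial_index']}")
        overlap = sum(max(0.0, min(b, row["offset"]) - max(a, row["onset"]))
                      for a, b in bouts)
        rows.append({"kind": row["kind"], "trial_index": int(row["trial_index"]),
                     "pct_freezing": 100.0 * overlap / dur})
    return pd.DataFrame(rows, columns=["kind", "trial_index", "pct_freezing"])
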