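"""Spectral power and coherence estimation.

Implements the analysis set used to characterize state-dependent theta:

* Welch power spectral density per trial, averaged across trials to one
  estimate per subject;
* relative power — the PSD normalized to its total (trapezoidal) power in
  the 2–12 Hz reference band, which removes between-subject differences in
  overall signal strength;
* band summaries over the low-theta (3–6 Hz) and high-theta (6–9 Hz) bands
  (band edges are closed, so 6 Hz belongs to both);
* magnitude-squared coherence (Welch cross-spectra) with the peak-in-band
  summary (maximum value over the band, plus the frequency at the maximum);
* a sliding-window multitaper coherogram / spectrogram (3 s window, 100 ms
  step, time-bandwidth 3 with 5 DPSS tapers by default);
* baseline-normalized evoked power: per-frequency z-scores against the 2 s
  pre-event window.

Welch defaults are 2 s Hann windows with 50% overlap (0.5 Hz resolution),
enough to separate the 3–6 and 6–9 Hz bands on 10 s trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import dpss


@dataclass
class BandDef:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: need lo < hi")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        # closed interval: a bin at 6 Hz counts for both 3-6 and 6-9
        return (freqs >= self.lo) & (freqs <= self.hi)


LOW_THETA = BandDef("low_theta", 3.0, 6.0)
HIGH_THETA = BandDef("high_theta", 6.0, 9.0)
NORM_BAND = BandDef("norm", 2.0, 12.0)


@dataclass
class SpectralEstimate:
    freqs: np.ndarray
    values: np.ndarray
    kind: str = "psd"  # psd | relative_psd | coherence
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.kind in ("psd", "relative_psd") and np.any(self.values < -1e-12):
            raise ValueError("PSD values must be non-negative")
        if self.kind == "coherence" and (np.any(self.values < -1e-9)
                                         or np.any(self.values > 1 + 1e-9)):
            raise ValueError("coherence values must lie in [0, 1]")


@dataclass
class TimeFrequencyMap:
    times: np.ndarray   # window centers, absolute session time
    freqs: np.ndarray
    values: np.ndarray  # freqs x times
    kind: str = "power"

    def __post_init__(self) -> None:
        if self.values.shape != (self.freqs.size, self.times.size):
            raise ValueError("values must be freqs x times")


def _welch_args(fs: float, n: int, window_len: float, overlap: float) -> dict:
    nperseg = int(round(window_len * fs))
    if nperseg > n:
        raise ValueError(f"epoch of {n} samples shorter than the "
                         f"{window_len} s Welch window")
    return dict(fs=fs, window="hann", nperseg=nperseg,
                noverlap=int(round(overlap * nperseg)))


def n_segments(n: int, fs: float, window_len: float, overlap: float) -> int:
    nperseg = int(round(window_len * fs))
    step = nperseg - int(round(overlap * nperseg))
    return max(0, (n - nperseg) // step + 1)


def welch_psd(epochs: np.ndarray, fs: float, window_len: float = 2.0,
              overlap: float = 0.5) -> SpectralEstimate:
    """Welch PSD; a 2-D input (trials × samples) is averaged across trials."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    kw = _welch_args(fs, epochs.shape[1], window_len, overlap)
    f, p = sps.welch(epochs, **kw)
    return SpectralEstimate(f, p.mean(axis=0), kind="psd",
                            params=dict(window_len=window_len, overlap=overlap,
                                        n_trials=epochs.shape[0]))


def relative_power(psd: SpectralEstimate, norm_band: BandDef = NORM_BAND
                   ) -> SpectralEstimate:
    """Normalize a PSD by its trapezoidal integral over the reference band."""
    m = norm_band.mask(psd.freqs)
    if m.sum() < 2:
        raise ValueError(f"PSD does not cover the {norm_band.name} band")
    total = np.trapezoid(psd.values[m], psd.freqs[m])
    if total <= 0:
        raise ValueError("zero total power in the normalization band")
    return SpectralEstimate(psd.freqs, psd.values / total, kind="relative_psd",
                            params={**psd.params, "norm_band": (norm_band.lo, norm_band.hi)})


def band_power(est: SpectralEstimate, band: BandDef) -> float:
    """Mean spectral value over the band's bins (closed interval)."""
    m = band.mask(est.freqs)
    if not m.any():
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}] Hz outside "
                         f"the spectral support")
    return float(est.values[m].mean())


def coherence(x: np.ndarray, y: np.ndarray, fs: float, window_len: float = 2.0,
              overlap: float = 0.5) -> SpectralEstimate:
    """Magnitude-squared coherence from Welch cross-spectra.

    2-D inputs (trials × samples) have their coherence estimated per trial
    and averaged across trials.  A single Welch segment is rejected: the
    estimator is identically 1 at K = 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y must have equal shape")
    kw = _welch_args(fs, x.shape[1], window_len, overlap)
    if n_segments(x.shape[1], fs, window_len, overlap) < 2:
        raise ValueError("coherence needs at least 2 Welch segments "
                         "(K=1 is degenerate at 1)")
    f, c = sps.coherence(x, y, **kw)
    return SpectralEstimate(f, np.clip(c.mean(axis=0), 0.0, 1.0), kind="coherence",
                            params=dict(window_len=window_len, overlap=overlap,
                                        n_trials=x.shape[0]))


def peak_band_coherence(coh: SpectralEstimate, band: BandDef) -> tuple[float, float]:
    """Maximum coherence over the band and the frequency where it occurs."""
    m = band.mask(coh.freqs)
    if not m.any():
        raise ValueError(f"band {band.name} outside coherence support")
    idx = np.argmax(coh.values[m])
    return float(coh.values[m][idx]), float(coh.freqs[m][idx])


# ---------------------------------------------------------------------------
# multitaper time-frequency maps

def _mt_windows(n: int, fs: float, window: float, step: float) -> tuple[np.ndarray, int, int]:
    nwin = int(round(window * fs))
    nstep = int(round(step * fs))
    if n < nwin:
        raise ValueError("signal shorter than one multitaper window")
    n_frames = (n - nwin) // nstep + 1
    starts = np.arange(n_frames) * nstep
    return starts, nwin, nstep

def _tapered_ffts(x: np.ndarray, starts: np.ndarray, nwin: int,
                  tapers: np.ndarray) -> np.ndarray:
    # frames x tapers x freqs
    segs = np.stack([x[s:s + nwin] for s in starts])
    return np.fft.rfft(segs[:, None, :] * tapers[None, :, :], axis=-1)


def mt_spectrogram(x: np.ndarray, fs: float, window: float = 3.0,
                   step: float = 0.1, nw: float = 3.0, n_tapers: int = 5,
                   t0: float = 0.0, fmax: float | None = None) -> TimeFrequencyMap:
    """Sliding-window multitaper power (3 s window, 100 ms step defaults)."""
    x = np.asarray(x, dtype=float)
    starts, nwin, _ = _mt_windows(x.size, fs, window, step)
    tapers = dpss(nwin, nw, n_tapers)
    X = _tapered_ffts(x, starts, nwin, tapers)
    pxx = np.mean(np.abs(X) ** 2, axis=1).T  # freqs x frames
    freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    times = t0 + (starts + nwin / 2.0) / fs
    if fmax is not None:
        keep = freqs <= fmax
        freqs, pxx = freqs[keep], pxx[keep]
    return TimeFrequencyMap(times, freqs, pxx, kind="power")


def coherogram(x: np.ndarray, y: np.ndarray, fs: float, window: float = 3.0,
               step: float = 0.1, nw: float = 3.0, n_tapers: int = 5,
               t0: float = 0.0, fmax: float | None = None) -> TimeFrequencyMap:
    """Sliding-window multitaper magnitude-squared coherence."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    starts, nwin, _ = _mt_windows(x.size, fs, window, step)
    tapers = dpss(nwin, nw, n_tapers)
    X = _tapered_ffts(x, starts, nwin, tapers)
    Y = _tapered_ffts(y, starts, nwin, tapers)
    sxx = np.mean(np.abs(X) ** 2, axis=1)
    syy = np.mean(np.abs(Y) ** 2, axis=1)
    sxy = np.mean(X * np.conj(Y), axis=1)
    coh = (np.abs(sxy) ** 2 / (sxx * syy)).T  # freqs x frames
    freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    times = t0 + (starts + nwin / 2.0) / fs
    if fmax is not None:
        keep = freqs <= fmax
        freqs, coh = freqs[keep], coh[keep]
    return TimeFrequencyMap(times, freqs, np.clip(coh, 0.0, 1.0), kind="coherence")


def evoked_power_z(tfmap: TimeFrequencyMap, event_time: float,
                   baseline: float = 2.0) -> TimeFrequencyMap:
    """Per-frequency z-score of a time-frequency map against its pre-event
    baseline (the ``baseline`` seconds before ``event_time``).

    Frequencies with zero baseline SD are returned as NaN rows rather than
    silently zeroed.
    """
    bmask = (tfmap.times >= event_time - baseline) & (tfmap.times < event_time)
    if bmask.sum() < 2:
        raise ValueError("baseline window must contain at least 2 frames")
    base = tfmap.values[:, bmask]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (tfmap.values - mu) / sd
    z[(sd == 0).ravel(), :] = np.nan
    return TimeFrequencyMap(tfmap.times, tfmap.freqs, z, kind="zscore")
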