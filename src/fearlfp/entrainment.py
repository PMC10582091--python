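"""Single-unit analyses around sinusoidal optogenetic stimulation.

Spikes inside laser-on epochs are assigned a stimulus phase
``φ = 360 · frac(f_stim · (t − onset))`` degrees, with the light-intensity
convention ``intensity ∝ (1 + sin φ)/2`` — maximal light power at 90°,
minimal at 270°.  Phase locking is summarized by the mean resultant length
(MRL) and tested with the Rayleigh test of circular uniformity
(Z = n·MRL², p by the finite-n corrected approximation).  A unit is
classified entrained when its Rayleigh p falls below alpha (0.05 default,
uncorrected, per unit); group counts feed a 2×2 table for Fisher's exact
test.  Peri-event time histograms and baseline-normalized evoked firing
(z against the 2 s pre-laser window) complete the set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import EventTable, SpikeTrain


@dataclass
class PhaseSample:
    """Stimulus phases (degrees in [0, 360)) of spikes within laser epochs."""

    phases_deg: np.ndarray
    n_excluded: int = 0  # spikes outside laser intervals

    def __post_init__(self) -> None:
        self.phases_deg = np.asarray(self.phases_deg, dtype=float)
        if self.phases_deg.size and (self.phases_deg.min() < 0
                                     or self.phases_deg.max() >= 360.0):
            raise ValueError("phases must lie in [0, 360)")

    @property
    def n(self) -> int:
        return self.phases_deg.size


@dataclass
class EntrainmentResult:
    unit_id: str
    n_spikes: int
    mrl: float
    preferred_phase_deg: float
    rayleigh_z: float
    p: float
    entrained: bool
    alpha: float = 0.05


def stim_phase(spikes: SpikeTrain | np.ndarray, laser_events: EventTable,
               stim_freq: float = 8.0) -> PhaseSample:
    """Assign each in-laser spike its phase on the sinusoidal stimulus."""
    if stim_freq <= 0:
        raise ValueError("stim_freq must be positive")
    ts = spikes.timestamps if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    lasers = laser_events.of_kind("laser")
    phases = []
    in_any = np.zeros(ts.size, dtype=bool)
    for _, row in lasers.iterrows():
        m = (ts >= row["onset"]) & (ts < row["offset"])
        in_any |= m
        phases.append((360.0 * stim_freq * (ts[m] - row["onset"])) % 360.0)
    ph = np.concatenate(phases) if phases else np.empty(0)
    return PhaseSample(ph, n_excluded=int((~in_any).sum()))


def rayleigh_p(z: float, n: int) -> float:
    """Rayleigh p with the standard finite-n correction (Zar).

    p ≈ exp(sqrt(1 + 4n + 4(n² − R²)) − (1 + 2n)), R = n·MRL.
    """
    r_n2 = z * n  # (n*mrl)^2
    arg = 1.0 + 4.0 * n + 4.0 * (n * n - r_n2)
    p = float(np.exp(np.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n)))
    return min(max(p, np.finfo(float).tiny), 1.0)


def rayleigh_mrl(ph: PhaseSample, unit_id: str = "", alpha: float = 0.05
                 ) -> EntrainmentResult:
    """MRL, preferred phase, and the Rayleigh uniformity test for one unit."""
    n = ph.n
    if n == 0:
        return EntrainmentResult(unit_id, 0, np.nan, np.nan, np.nan, np.nan,
                                 False, alpha)
    if n < 8:
        warnings.warn(f"unit {unit_id!r}: Rayleigh test unreliable at n={n}",
                      stacklevel=2)
    rad = np.deg2rad(ph.phases_deg)
    vec = np.mean(np.exp(1j * rad))
    mrl = float(np.abs(vec))
    pref = float(np.rad2deg(np.angle(vec)) % 360.0)
    z = n * mrl ** 2
    p = rayleigh_p(z, n)
    return EntrainmentResult(unit_id, n, mrl, pref, float(z), p,
                             entrained=p < alpha, alpha=alpha)


def classify_entrained(results_by_group: dict[str, list[EntrainmentResult]],
                       alpha: float = 0.05) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-group entrained counts and the 2×2 table for Fisher's exact test.

    Rows of the table are groups (in dict order, first two groups), columns
    are (entrained, not entrained).
    """
    rows = []
    for group, results in results_by_group.items():
        if not results:
            raise ValueError(f"group {group!r} has no units")
        n_ent = sum(r.p < alpha for r in results if np.isfinite(r.p))
        rows.append({"group": group, "n_units": len(results),
                     "n_entrained": n_ent,
                     "n_not_entrained": len(results) - n_ent})
    counts = pd.DataFrame(rows)
    table = counts[["n_entrained", "n_not_entrained"]].to_numpy()[:2]
    return counts, table


@dataclass
class PETH:
    """Peri-event time histogram summed over events."""

    bin_edges: np.ndarray  # seconds relative to event
    counts: np.ndarray
    n_events: int
    bin_width: float

    @property
    def rate(self) -> np.ndarray:
        """Firing rate per bin (Hz), averaged over events."""
        return self.counts / (self.n_events * self.bin_width)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def peth(spikes: SpikeTrain, events: EventTable, kind: str = "laser",
         window: tuple[float, float] = (-2.0, 5.0),
         bin_width: float = 0.1) -> PETH:
    """Spike counts in ``bin_width`` bins around each event onset, summed
    over events.  Standard bin sizes are 100 ms and 1.25 ms."""
    ev = events.of_kind(kind)
    if len(ev) == 0:
        raise ValueError(f"no events of kind {kind!r}")
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_width))
    if abs(n_bins * bin_width - (hi - lo)) > 1e-9:
        raise ValueError("bin_width must divide the window length")
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for onset in ev["onset"]:
        rel = spikes.timestamps - onset
        counts += np.histogram(rel, bins=edges)[0]
    return PETH(edges, counts, len(ev), bin_width)


def evoked_rate_z(p: PETH, baseline: float = 2.0) -> np.ndarray:
    """Per-bin firing-rate z-score against the pre-event baseline bins.

    Returns NaN for every bin when the baseline SD is zero (flagged
    undefined rather than silently zeroed).
    """
    bmask = (p.bin_centers >= -baseline) & (p.bin_centers < 0)
    if bmask.sum() < 2:
        raise ValueError("need at least 2 baseline bins")
    rate = p.rate
    mu = rate[bmask].mean()
    sd = rate[bmask].std(ddof=1)
    if sd == 0:
        return np.full_like(rate, np.nan)
    return (rate - mu) / sd


def results_to_frame(results: list[EntrainmentResult], group: str = ""
                     ) -> pd.DataFrame:
    return pd.DataFrame([{
        "unit_id": r.unit_id, "group": group, "n_spikes": r.n_spikes,
        "mrl": r.mrl, "preferred_phase_deg": r.preferred_phase_deg,
        "rayleigh_z": r.rayleigh_z, "p": r.p, "entrained": r.entrained,
    } for r in results])
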