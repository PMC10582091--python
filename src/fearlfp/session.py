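"""Core data model for one recording session.

A session bundles together the continuously sampled signals (LFP channels
and the load-cell motion trace), a table of behavioural/stimulation events,
and the sorted spike trains of any recorded single units.  Times are
session-relative seconds (t = 0 at recording start) stored as float64, and
all event intervals are half-open ``[onset, offset)`` so that epoch
arithmetic at 1 kHz is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Region vocabulary accepted by default.  Free-form labels are allowed when
#: validation is relaxed, but the pipeline's own outputs stick to these.
KNOWN_REGIONS = ("PL", "IL", "HPC", "RE", "loadcell", "other")

EVENT_KINDS = ("CS", "US", "laser", "baseline", "session")

EVENT_COLUMNS = ("onset", "offset", "kind", "trial_index")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class Timeseries:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude values (µV for LFP, arbitrary units for the load cell).
    fs : float
        Sampling rate in Hz.
    t0 : float
        Session time of the first sample, seconds.
    channel_id : str
        Channel label.
    region : str
        Anatomical region (``PL``, ``IL``, ``HPC``, ``RE``) or ``loadcell``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel_id: str = ""
    region: str = "other"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"non-finite samples in channel {self.channel_id!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def copy_with(self, samples: np.ndarray, fs: float | None = None) -> "Timeseries":
        return Timeseries(samples, self.fs if fs is None else fs,
                          self.t0, self.channel_id, self.region)


class EventTable:
    """Sorted table of half-open event intervals.

    Columns: onset (s), offset (s), kind, trial_index.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing columns {missing}")
        df = df[list(EVENT_COLUMNS)]
        if (df["offset"] < df["onset"]).any():
            bad = df.index[df["offset"] < df["onset"]].tolist()
            raise ValidationError(f"event offset < onset at rows {bad}")
        unknown = set(df["kind"]) - set(EVENT_KINDS)
        if unknown:
            raise ValidationError(f"unknown event kinds {sorted(unknown)}")
        self.df = df.sort_values("onset", kind="stable").reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "EventTable":
        return cls(pd.DataFrame(records, columns=list(EVENT_COLUMNS)))

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self.df.equals(other.df)

    def to_csv(self, path) -> None:
        out = self.df.rename(columns={"onset": "onset_s", "offset": "offset_s"})
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "EventTable":
        df = pd.read_csv(path)
        df = df.rename(columns={"onset_s": "onset", "offset_s": "offset"})
        return cls(df)


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (seconds) of one unit."""

    unit_id: str
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if self.timestamps.size:
            if np.any(np.diff(self.timestamps) <= 0):
                raise ValidationError(
                    f"unit {self.unit_id!r}: timestamps must be strictly increasing")
            if self.timestamps[0] < 0:
                raise ValidationError(f"unit {self.unit_id!r}: negative timestamp")

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass
class SessionBundle:
    """One subject-session: signals + events + spikes + metadata."""

    signals: list[Timeseries]
    events: EventTable
    spikes: list[SpikeTrain] = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        lfp_rates = {s.fs for s in self.signals if s.region != "loadcell"}
        if len(lfp_rates) > 1:
            raise ValidationError(f"LFP channels disagree on fs: {sorted(lfp_rates)}")
        if self.signals and len(self.events):
            end = max(s.t0 + s.duration for s in self.signals)
            if (self.events.df["offset"] > end + 1e-9).any():
                raise ValidationError("events extend beyond the recorded span")

    def channel(self, region: str) -> Timeseries:
        for s in self.signals:
            if s.region == region:
                return s
        raise KeyError(f"no channel with region {region!r}; "
                       f"have {[s.region for s in self.signals]}")

    @property
    def lfp_channels(self) -> list[Timeseries]:
        return [s for s in self.signals if s.region != "loadcell"]


@dataclass
class EpochSet:
    """Fixed-length signal epochs cut around events of one kind.

    ``data`` is trials × samples; row i corresponds to ``trial_index[i]``.
    ``t_rel`` gives the time of each column relative to event onset.
    """

    data: np.ndarray
    fs: float
    trial_index: np.ndarray
    t_rel: np.ndarray
    kind: str = ""
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def slice_epochs(signal: Timeseries, events: EventTable, kind: str,
                 pre: float = 0.0, post: float = 10.0) -> EpochSet:
    """Cut one fixed-length epoch per event of ``kind``.

    The window is ``[onset - pre, onset + post)``: the sample at onset is
    included, the sample at ``onset + post`` excluded.  Events whose window
    falls outside the recording are dropped (counted in ``n_dropped``),
    never an error.
    """
    ev = events.of_kind(kind)
    fs = signal.fs
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    n_len = n_pre + n_post
    if n_len < 1:
        raise ValueError("epoch window must contain at least one sample")
    rows, kept, dropped = [], [], 0
    for _, row in ev.iterrows():
        i0 = int(round((row["onset"] - signal.t0) * fs)) - n_pre
        i1 = i0 + n_len
        if i0 < 0 or i1 > signal.samples.size:
            dropped += 1
            continue
        rows.append(signal.samples[i0:i1])
        kept.append(row["trial_index"])
    data = np.vstack(rows) if rows else np.empty((0, n_len))
    t_rel = (np.arange(n_len) - n_pre) / fs
    return EpochSet(data, fs, np.asarray(kept), t_rel, kind=kind, n_dropped=dropped)
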