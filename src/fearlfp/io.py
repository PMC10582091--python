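"""Reading and writing session bundles.

One HDF5 file per session holds the continuous signals and spike trains:

* ``/lfp`` — channels × samples float64, with ``fs``, ``t0``, ``regions``
  and ``channel_ids`` attributes;
* ``/loadcell`` — the motion trace (own ``fs``/``t0`` attributes);
* ``/spikes/<unit_id>`` — sorted spike times in seconds;
* root attributes — session metadata (subject, group, session kind, laser
  condition, ...).

The event table travels as a sibling CSV (``<stem>.events.csv``) and any
generator ground truth as a JSON sidecar (``<stem>.truth.json``), keeping
every non-signal artifact human-readable.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .session import (EventTable, SessionBundle, SpikeTrain, Timeseries,
                      ValidationError)


class BundleParseError(ValueError):
    """Raised when a bundle file is malformed; names the offending dataset."""


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(str(stem) + ".events.csv"), Path(str(stem) + ".truth.json")


def write_bundle(bundle: SessionBundle, path) -> None:
    """Write a session to ``path`` (HDF5) plus CSV/JSON sidecars."""
    path = Path(path)
    events_path, truth_path = _sidecars(path)
    lfp = bundle.lfp_channels
    with h5py.File(path, "w") as f:
        if lfp:
            d = f.create_dataset("lfp", data=np.vstack([s.samples for s in lfp]))
            d.attrs["fs"] = lfp[0].fs
            d.attrs["t0"] = lfp[0].t0
            d.attrs["regions"] = [s.region for s in lfp]
            d.attrs["channel_ids"] = [s.channel_id for s in lfp]
        try:
            lc = bundle.channel("loadcell")
        except KeyError:
            lc = None
        if lc is not None:
            d = f.create_dataset("loadcell", data=lc.samples)
            d.attrs["fs"] = lc.fs
            d.attrs["t0"] = lc.t0
            d.attrs["channel_id"] = lc.channel_id
        g = f.create_group("spikes")
        for st in bundle.spikes:
            g.create_dataset(st.unit_id, data=st.timestamps)
        for k, v in bundle.meta.items():
            f.attrs[k] = v
    bundle.events.to_csv(events_path)
    if bundle.ground_truth is not None:
        truth_path.write_text(json.dumps(bundle.ground_truth, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"cannot serialize {type(o)}")


def read_bundle(path) -> SessionBundle:
    """Read a session bundle written by :func:`write_bundle`.

    Raises :class:`BundleParseError` naming the offending dataset on
    malformed files, and :class:`ValidationError` if channels disagree on
    sampling rate or events violate their invariants.
    """
    path = Path(path)
    events_path, truth_path = _sidecars(path)
    signals: list[Timeseries] = []
    spikes: list[SpikeTrain] = []
    with h5py.File(path, "r") as f:
        if "lfp" in f:
            d = f["lfp"]
            try:
                fs = float(d.attrs["fs"])
                t0 = float(d.attrs.get("t0", 0.0))
                regions = [str(r) for r in d.attrs["regions"]]
                chan_ids = [str(c) for c in d.attrs["channel_ids"]]
            except KeyError as e:
                raise BundleParseError(f"dataset 'lfp' missing attribute {e}") from e
            arr = d[()]
            if arr.ndim != 2 or len(regions) != arr.shape[0]:
                raise BundleParseError("dataset 'lfp' shape/label mismatch")
            for i, (reg, cid) in enumerate(zip(regions, chan_ids)):
                signals.append(Timeseries(arr[i], fs, t0, cid, reg))
        if "loadcell" in f:
            d = f["loadcell"]
            try:
                fs = float(d.attrs["fs"])
            except KeyError as e:
                raise BundleParseError("dataset 'loadcell' missing attribute 'fs'") from e
            signals.append(Timeseries(d[()], fs, float(d.attrs.get("t0", 0.0)),
                                      str(d.attrs.get("channel_id", "loadcell")),
                                      "loadcell"))
        if "spikes" in f:
            for uid in sorted(f["spikes"]):
                spikes.append(SpikeTrain(uid, f["spikes"][uid][()]))
        meta = {k: (v.item() if isinstance(v, np.generic) else str(v))
                for k, v in f.attrs.items()}
    if not events_path.exists():
        raise BundleParseError(f"event table sidecar not found: {events_path}")
    events = EventTable.read_csv(events_path)
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return SessionBundle(signals, events, spikes, meta, ground_truth=truth)
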