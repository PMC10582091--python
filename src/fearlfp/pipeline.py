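"""Per-session and group-level orchestration.

``run_session`` executes the fixed stage order — preprocess → behavior →
spectral → entrainment — on one session bundle and writes tidy CSV tables:
freezing per epoch, relative band power per region and CS trial, peak
theta-band coherence per region pair, and per-unit entrainment results.
``run_group_stats`` consumes those tables across sessions and runs the
configured ANOVA / regression / Fisher set.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, entrainment, preprocess, spectral, stats
from .config import AnalysisParams, RunManifest
from .session import SessionBundle, slice_epochs
from .spectral import BandDef

log = logging.getLogger("fearlfp")


def _bands(params: AnalysisParams) -> tuple[BandDef, BandDef, BandDef]:
    return (BandDef("low_theta", *params.low_band),
            BandDef("high_theta", *params.high_band),
            BandDef("norm", *params.norm_band))


def _epoch_kind(bundle: SessionBundle) -> str:
    """Analysis epochs are CS trials when present, else laser epochs
    (naive stimulation sessions have no CS)."""
    return "CS" if len(bundle.events.of_kind("CS")) else "laser"


def analyze_band_power(bundle: SessionBundle, params: AnalysisParams
                       ) -> tuple[pd.DataFrame, int]:
    """Relative 3–6 / 6–9 Hz band power per region and CS trial.

    Returns the tidy table and the number of artifact-rejected trials.
    """
    low, high, norm = _bands(params)
    pp = preprocess.PreprocessParams(
        target_fs=params.target_fs, notch_band=params.notch_band,
        artifact_z_thresh=params.artifact_z_thresh,
        artifact_min_frac=params.artifact_min_frac)
    kind = _epoch_kind(bundle)
    rows, n_rejected = [], 0
    for sig in bundle.lfp_channels:
        clean = preprocess.preprocess_signal(sig, pp)
        epochs = slice_epochs(clean, bundle.events, kind, pre=0.0,
                              post=params.cs_duration)
        if epochs.n_trials == 0:
            continue
        kept, _report = preprocess.reject_artifact_trials(
            epochs, pp, session_reference=clean.samples)
        n_rejected += int((~kept).sum())
        if not kept.any():
            raise RuntimeError(f"all {kind} trials rejected on {sig.region}")
        for i in np.flatnonzero(kept):
            psd = spectral.welch_psd(epochs.data[i], clean.fs,
                                     params.welch_window, params.welch_overlap)
            rel = spectral.relative_power(psd, norm)
            rows.append({"region": sig.region,
                         "trial_index": int(epochs.trial_index[i]),
                         "low_theta": spectral.band_power(rel, low),
                         "high_theta": spectral.band_power(rel, high)})
    return pd.DataFrame(rows), n_rejected


def analyze_coherence(bundle: SessionBundle, params: AnalysisParams
                      ) -> pd.DataFrame:
    """Trial-averaged coherence and its in-band peak per region pair."""
    low, high, _ = _bands(params)
    pp = preprocess.PreprocessParams(target_fs=params.target_fs,
                                     notch_band=params.notch_band)
    cleaned = {s.region: preprocess.preprocess_signal(s, pp)
               for s in bundle.lfp_channels}
    kind = _epoch_kind(bundle)
    regions = list(cleaned)
    rows = []
    for i, r1 in enumerate(regions):
        for r2 in regions[i + 1:]:
            e1 = slice_epochs(cleaned[r1], bundle.events, kind, 0.0,
                              params.cs_duration)
            e2 = slice_epochs(cleaned[r2], bundle.events, kind, 0.0,
                              params.cs_duration)
            if e1.n_trials == 0:
                continue
            coh = spectral.coherence(e1.data, e2.data, params.target_fs,
                                     params.welch_window, params.welch_overlap)
            for band in (low, high):
                peak, f_at = spectral.peak_band_coherence(coh, band)
                rows.append({"pair": f"{r1}-{r2}", "band": band.name,
                             "peak_coherence": peak, "freq_at_peak": f_at})
    return pd.DataFrame(rows)


def analyze_freezing(bundle: SessionBundle, params: AnalysisParams
                     ) -> pd.DataFrame:
    fp = behavior.FreezingParams(min_bout=params.min_bout,
                                 smoothing_window=params.smoothing_window)
    bouts = behavior.detect_freezing(bundle.channel("loadcell"), fp)
    return behavior.epoch_freezing(bouts, bundle.events, ("baseline", "CS", "laser"))


def analyze_entrainment(bundle: SessionBundle, params: AnalysisParams
                        ) -> pd.DataFrame:
    results = []
    for st in bundle.spikes:
        ph = entrainment.stim_phase(st, bundle.events, params.stim_freq)
        results.append(entrainment.rayleigh_mrl(ph, st.unit_id, params.alpha))
    return entrainment.results_to_frame(
        results, group=str(bundle.meta.get("group", "")))


def run_session(bundle: SessionBundle, params: AnalysisParams,
                outdir) -> dict[str, Path]:
    """Run the full per-session analysis set and write CSV outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    freezing = analyze_freezing(bundle, params)
    outputs["freezing"] = outdir / "freezing.csv"
    freezing.to_csv(outputs["freezing"], index=False)
    log.info("freezing: %d epochs", len(freezing))

    band, n_rej = analyze_band_power(bundle, params)
    outputs["band_power"] = outdir / "band_power.csv"
    band.to_csv(outputs["band_power"], index=False)
    log.info("band power: %d rows, %d trials rejected", len(band), n_rej)

    if len(bundle.lfp_channels) >= 2:
        coh = analyze_coherence(bundle, params)
        outputs["coherence"] = outdir / "peak_coherence.csv"
        coh.to_csv(outputs["coherence"], index=False)

    if bundle.spikes and len(bundle.events.of_kind("laser")):
        ent = analyze_entrainment(bundle, params)
        outputs["entrainment"] = outdir / "entrainment.csv"
        ent.to_csv(outputs["entrainment"], index=False)

    manifest = RunManifest(config_hash=params.digest(), seed=params.seed,
                           stage_counts={"freezing_epochs": len(freezing),
                                         "band_power_rows": len(band)},
                           rejected_trials=n_rej)
    manifest.write(outdir / "manifest.json")
    outputs["manifest"] = outdir / "manifest.json"
    return outputs


def run_group_stats(band_tables: dict[str, pd.DataFrame],
                    freezing_tables: dict[str, pd.DataFrame] | None = None,
                    band: str = "low_theta", alpha: float = 0.05
                    ) -> pd.DataFrame:
    """Condition-level statistics across sessions.

    ``band_tables`` maps condition name → per-session band-power table
    (one table per subject-session, concatenated with a ``subject``
    column).  Runs the one-way RM ANOVA across conditions on per-subject
    band means and, when freezing tables are provided, the freezing-vs-power
    regression.
    """
    if len(band_tables) < 2:
        raise ValueError("need at least 2 conditions for group statistics")
    per = []
    for cond, table in band_tables.items():
        if "subject" not in table.columns:
            raise ValueError(f"condition {cond!r}: band table lacks 'subject'")
        m = table.groupby("subject")[band].mean().rename(cond)
        per.append(m)
    wide = pd.concat(per, axis=1)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"design/table mismatch; missing cells for subjects "
                         f"{missing}")
    table = stats.one_way_rm_anova(wide)
    results = [table.effect("condition")]

    if freezing_tables is not None:
        xs, ys = [], []
        for cond, ft in freezing_tables.items():
            fz = ft.groupby("subject")["pct_freezing"].mean()
            bp = band_tables[cond].groupby("subject")[band].mean()
            joined = pd.concat([fz, bp], axis=1).dropna()
            xs.append(joined[band].to_numpy())
            ys.append(joined["pct_freezing"].to_numpy())
        x, y = np.concatenate(xs), np.concatenate(ys)
        reg = stats.linregress(x, y)
        results.append(stats.StatResult(
            "linregress", reg.F, reg.df, reg.p,
            effect_label=f"freezing vs {band} (slope={reg.slope:.3g}, "
                         f"r2={reg.r2:.3f})"))
    return stats.results_to_frame(results)
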