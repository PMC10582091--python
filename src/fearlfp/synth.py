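"""Synthetic session generator with ground truth.

Emulates the statistical structure of rodent fear-extinction recordings so
every downstream analysis is testable without animal data:

* a two-state freeze/move behavioural trace with exponential dwell times
  (minimum 1 s bouts);
* multichannel LFPs built from state-gated narrowband oscillators — a low
  theta generator around 4 Hz amplified during freezing and a high theta
  generator around 8 Hz amplified during movement — shared across regions
  with a fixed conduction lag, so inter-region coherence is controllable;
* 1/f pink background, 60 Hz line noise, and occasional large motion
  artifacts (the inputs the notch and artifact-rejection stages exist for);
* spike trains phase-locked to a sinusoidal laser stimulus by a von Mises
  rate modulation (concentration ``kappa``, preferred phase ``phi0``),
  normalized so phase locking does not by itself change the mean rate;
* a load-cell trace whose variance tracks the behavioural state.

Oscillators are narrowband-filtered Gaussian noise (not pure sinusoids) so
simulated spectra have realistic band shape, and state gating uses a 100 ms
amplitude cross-fade to limit spectral leakage at bout edges.

The laser intensity convention is ``intensity ∝ (1 + sin φ)/2`` with φ = 0
at laser onset: maximal light power occurs at φ = 90°.

Ground truth (state trace, per-unit kappa/phi0, shared-source fraction) is
stored on each bundle for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .session import EventTable, SessionBundle, SpikeTrain, Timeseries

FREEZE, MOVE = 0, 1
CROSSFADE_S = 0.1  # amplitude cross-fade at state transitions


@dataclass
class StateTrace:
    """Freeze/move state per sample on a uniform grid."""

    times: np.ndarray
    state: np.ndarray  # 0 = freeze, 1 = move
    fs: float

    def fraction_frozen(self) -> float:
        return float(np.mean(self.state == FREEZE))


@dataclass
class OscSpec:
    """One state-gated narrowband oscillator, shared across regions."""

    center_freq: float = 8.0
    bandwidth: float = 2.0
    amp_freeze: float = 0.0
    amp_move: float = 1.0
    channel_gains: dict | None = None   # region -> gain; default 1 everywhere
    inter_region_lag_ms: float = 0.0    # delay per region index

    def __post_init__(self) -> None:
        if self.center_freq <= 0 or self.bandwidth <= 0:
            raise ValueError("center_freq and bandwidth must be positive")
        if self.amp_freeze < 0 or self.amp_move < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class NoiseSpec:
    """Background noise: pink 1/f^alpha, 60 Hz line, sparse artifacts."""

    pink_exponent: float = 1.0
    pink_scale: float = 1.0
    line_amp: float = 0.2
    line_freq: float = 60.0
    artifact_rate_per_min: float = 0.0
    artifact_amp: float = 20.0
    artifact_dur_s: float = 0.05

    def __post_init__(self) -> None:
        if not 0.5 <= self.pink_exponent <= 2.0:
            raise ValueError("pink_exponent must lie in [0.5, 2]")
        for a in (self.pink_scale, self.line_amp, self.artifact_amp):
            if a < 0:
                raise ValueError("noise amplitudes must be non-negative")


@dataclass
class SpikeGenSpec:
    """Von Mises phase-locked spiking around a sinusoidal laser stimulus."""

    base_rate: float = 10.0
    kappa: float = 0.0
    phi0_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        self.base_rate = float(self.base_rate)
        self.kappa = float(self.kappa)
        self.phi0_deg = float(self.phi0_deg) % 360.0


@dataclass
class ProtocolSpec:
    """Session protocol: trial counts and timings.

    Defaults follow the standard auditory fear paradigm: conditioning is a
    180 s baseline then five 10 s CS presentations (each co-terminating
    with a 2 s US) at 60 s ITIs; extinction is 45 CS-alone trials at 30 s
    ITIs; sinusoidal-laser sessions switch the laser on 5 s before each CS
    onset and off 5 s after its offset; naive stimulation is twenty 5 s
    laser epochs.
    """

    session_kind: str = "extinction"
    n_trials: int = 45
    cs_duration: float = 10.0
    us_duration: float = 2.0
    iti: float = 30.0
    baseline_duration: float = 180.0
    laser: str = "none"           # none | constant | sine
    laser_freq: float = 8.0
    laser_margin: float = 5.0     # pre/post CS
    stim_duration: float = 5.0    # naive_stim epochs
    stim_iti: float = 15.0

    KINDS = ("conditioning", "context_exposure", "extinction",
             "retrieval", "renewal", "naive_stim")

    def __post_init__(self) -> None:
        if self.session_kind not in self.KINDS:
            raise ValueError(f"unknown session_kind {self.session_kind!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for d in (self.cs_duration, self.iti, self.baseline_duration):
            if d <= 0:
                raise ValueError("all durations must be positive")

    @classmethod
    def conditioning(cls, **kw) -> "ProtocolSpec":
        kw.setdefault("n_trials", 5)
        kw.setdefault("iti", 60.0)
        return cls(session_kind="conditioning", **kw)

    @classmethod
    def extinction(cls, **kw) -> "ProtocolSpec":
        kw.setdefault("n_trials", 45)
        kw.setdefault("iti", 30.0)
        return cls(session_kind="extinction", **kw)

    @classmethod
    def retrieval(cls, laser: str = "none", **kw) -> "ProtocolSpec":
        kw.setdefault("n_trials", 5)
        kw.setdefault("iti", 30.0)
        return cls(session_kind="retrieval", laser=laser, **kw)

    @classmethod
    def naive_stim(cls, **kw) -> "ProtocolSpec":
        kw.setdefault("n_trials", 20)
        kw.setdefault("baseline_duration", 60.0)
        return cls(session_kind="naive_stim", laser="sine", **kw)


def default_oscs() -> list[OscSpec]:
    """The study-condition oscillator pair: ~4 Hz freezing / ~8 Hz movement."""
    return [
        OscSpec(center_freq=4.0, bandwidth=2.0, amp_freeze=1.0, amp_move=0.25,
                inter_region_lag_ms=20.0),
        OscSpec(center_freq=8.0, bandwidth=2.0, amp_freeze=0.25, amp_move=1.0,
                inter_region_lag_ms=20.0),
    ]


# ---------------------------------------------------------------------------
# behavioural state

def gen_state_trace(duration: float, mean_dwell_freeze: float = 10.0,
                    mean_dwell_move: float = 10.0, seed: int | None = None,
                    fs: float = 1000.0, start_state: int = FREEZE) -> StateTrace:
    """Alternating freeze/move bouts with exponential dwell times (min 1 s)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if min(mean_dwell_freeze, mean_dwell_move) < 1.0:
        raise ValueError("mean dwell times must be >= 1 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    state = np.empty(n, dtype=np.int8)
    t, cur = 0.0, start_state
    while t < duration:
        mean = mean_dwell_freeze if cur == FREEZE else mean_dwell_move
        if np.isinf(mean):
            dwell = duration - t
        else:
            dwell = max(1.0, rng.exponential(mean))
        i0, i1 = int(round(t * fs)), min(int(round((t + dwell) * fs)), n)
        state[i0:i1] = cur
        t += dwell
        cur = MOVE if cur == FREEZE else FREEZE
    return StateTrace(np.arange(n) / fs, state, fs)


def constant_state(duration: float, state: int, fs: float = 1000.0) -> StateTrace:
    n = int(round(duration * fs))
    return StateTrace(np.arange(n) / fs, np.full(n, state, dtype=np.int8), fs)


def _state_envelope(trace: StateTrace) -> np.ndarray:
    """Freeze-fraction envelope in [0, 1] with a 100 ms cross-fade."""
    freeze = (trace.state == FREEZE).astype(np.float64)
    w = max(1, int(round(CROSSFADE_S * trace.fs)))
    kernel = np.ones(w) / w
    pad = np.pad(freeze, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


# ---------------------------------------------------------------------------
# signals

def narrowband_noise(n: int, fs: float, center: float, bandwidth: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise bandpassed around ``center``."""
    lo = max(center - bandwidth / 2.0, 0.1)
    hi = min(center + bandwidth / 2.0, 0.99 * fs / 2.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def pink_noise(n: int, fs: float, exponent: float,
               rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power spectrum ∝ 1/f^exponent (FFT shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    return x / np.sqrt(np.mean(x ** 2))


def gen_lfp(state: StateTrace, oscs: list[OscSpec], noise: NoiseSpec,
            fs: float | None = None, regions: tuple[str, ...] = ("PL", "IL", "HPC"),
            seed: int | None = None,
            independent_noise_scale: float = 1.0) -> list[Timeseries]:
    """Multichannel LFP from shared state-gated oscillators plus noise.

    Each channel is the sum over oscillators of a shared band-limited source
    — delayed by ``inter_region_lag_ms`` × region index and scaled by the
    region's channel gain — amplitude-gated by the behavioural state, plus
    independent pink noise, 60 Hz line noise, and sparse artifacts.
    """
    fs = state.fs if fs is None else fs
    if not regions:
        raise ValueError("need at least one region")
    if oscs and fs < 4.0 * max(o.center_freq for o in oscs):
        raise ValueError(f"fs={fs} too low for the requested oscillators")
    rng = np.random.default_rng(seed)
    n = state.state.size
    env_freeze = _state_envelope(state)
    env_move = 1.0 - env_freeze

    max_lag = max((o.inter_region_lag_ms for o in oscs), default=0.0)
    pad = int(np.ceil(max_lag / 1000.0 * fs)) * (len(regions) - 1) + 1
    sources = []
    for o in oscs:
        src = narrowband_noise(n + pad, fs, o.center_freq, o.bandwidth, rng)
        amp = o.amp_freeze * env_freeze + o.amp_move * env_move
        sources.append((o, src, amp))

    out = []
    for r_idx, region in enumerate(regions):
        ch = np.zeros(n)
        for o, src, amp in sources:
            lag = int(round(o.inter_region_lag_ms / 1000.0 * fs)) * r_idx
            gain = 1.0 if o.channel_gains is None else o.channel_gains.get(region, 1.0)
            ch += gain * amp * src[pad - lag: pad - lag + n]
        if noise.pink_scale > 0:
            ch += (noise.pink_scale * independent_noise_scale
                   * pink_noise(n, fs, noise.pink_exponent, rng))
        if noise.line_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            ch += noise.line_amp * np.sin(
                2 * np.pi * noise.line_freq * np.arange(n) / fs + phase)
        if noise.artifact_rate_per_min > 0:
            n_art = rng.poisson(noise.artifact_rate_per_min * n / fs / 60.0)
            w = int(round(noise.artifact_dur_s * fs))
            for _ in range(n_art):
                i0 = rng.integers(0, max(1, n - w))
                ch[i0:i0 + w] += noise.artifact_amp * rng.choice([-1.0, 1.0])
        out.append(Timeseries(ch, fs, 0.0, f"ch{r_idx}", region))
    return out


def gen_loadcell(state: StateTrace, noise_sd_freeze: float = 0.1,
                 noise_sd_move: float = 1.0, seed: int | None = None) -> Timeseries:
    """Zero-mean load-cell trace whose variance tracks the freeze/move state."""
    if not noise_sd_move > noise_sd_freeze >= 0:
        raise ValueError("require noise_sd_move > noise_sd_freeze >= 0")
    rng = np.random.default_rng(seed)
    env_freeze = _state_envelope(state)
    sd = noise_sd_freeze * env_freeze + noise_sd_move * (1.0 - env_freeze)
    x = sd * rng.standard_normal(state.state.size)
    return Timeseries(x, state.fs, 0.0, "loadcell", "loadcell")


# ---------------------------------------------------------------------------
# spikes

def laser_phase(t: np.ndarray, onset: float, stim_freq: float) -> np.ndarray:
    """Stimulus phase in degrees: 0 at onset, intensity max at 90 degrees."""
    return (360.0 * stim_freq * (t - onset)) % 360.0


def gen_spikes(laser_events: EventTable, spec: SpikeGenSpec, duration: float,
               seed: int | None = None, unit_id: str = "unit0",
               stim_freq: float = 8.0) -> SpikeTrain:
    """Inhomogeneous Poisson spikes phase-locked to the sinusoidal laser.

    During laser-on epochs the rate is ``base_rate · exp(κ cos(φ − φ0)) /
    I0(κ)``, which averages to ``base_rate`` over a stimulation cycle —
    entrainment without a mean-rate change.  Outside the laser the process
    is homogeneous at ``base_rate``.  Sampled by thinning.
    """
    from scipy.special import i0 as bessel_i0
    rng = np.random.default_rng(seed)
    lasers = laser_events.of_kind("laser")
    k, phi0 = spec.kappa, np.deg2rad(spec.phi0_deg)
    rmax = spec.base_rate * max(1.0, float(np.exp(k) / bessel_i0(k)))
    n_cand = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    rate = np.full(cand.size, float(spec.base_rate))
    for _, row in lasers.iterrows():
        in_laser = (cand >= row["onset"]) & (cand < row["offset"])
        phi = np.deg2rad(laser_phase(cand[in_laser], row["onset"], stim_freq))
        rate[in_laser] = (spec.base_rate * np.exp(k * np.cos(phi - phi0))
                          / bessel_i0(k))
    keep = rng.uniform(0.0, 1.0, cand.size) < rate / rmax
    ts = cand[keep]
    ts = ts[np.concatenate(([True], np.diff(ts) > 0))]  # drop exact ties
    return SpikeTrain(unit_id, ts)


# ---------------------------------------------------------------------------
# protocols and full sessions

def protocol_events(protocol: ProtocolSpec) -> tuple[EventTable, float]:
    """Event table and total session duration implied by a protocol."""
    rows: list[tuple] = []
    t = protocol.baseline_duration
    rows.append((0.0, t, "baseline", -1))
    if protocol.session_kind == "naive_stim":
        for i in range(protocol.n_trials):
            rows.append((t, t + protocol.stim_duration, "laser", i))
            t += protocol.stim_duration + protocol.stim_iti
        total = t
    else:
        for i in range(protocol.n_trials):
            cs_on, cs_off = t, t + protocol.cs_duration
            if protocol.laser in ("constant", "sine"):
                rows.append((cs_on - protocol.laser_margin,
                             cs_off + protocol.laser_margin, "laser", i))
            rows.append((cs_on, cs_off, "CS", i))
            if protocol.session_kind == "conditioning":
                rows.append((cs_off, cs_off + protocol.us_duration, "US", i))
            t = cs_off + protocol.iti
        total = t
        if protocol.session_kind == "conditioning":
            total += 60.0  # post-shock period
    rows.append((0.0, total, "session", -1))
    return EventTable.from_records(rows), total


@dataclass
class SessionSpec:
    """Everything needed to simulate one session."""

    protocol: ProtocolSpec
    oscs: list[OscSpec] = field(default_factory=default_oscs)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    spike_specs: list[SpikeGenSpec] = field(default_factory=list)
    mean_dwell_freeze: float = 10.0
    mean_dwell_move: float = 10.0
    cs_freeze_bias: float | None = None  # dwell multiplier during CS, unused by default
    fs: float = 1000.0
    regions: tuple[str, ...] = ("PL", "IL", "HPC")
    loadcell_sd: tuple[float, float] = (0.1, 1.0)
    meta: dict = field(default_factory=dict)


def gen_session(spec: SessionSpec, seed: int | None = None) -> SessionBundle:
    """Simulate a complete annotated session bundle."""
    rng = np.random.default_rng(seed)
    events, duration = protocol_events(spec.protocol)
    state = gen_state_trace(duration, spec.mean_dwell_freeze, spec.mean_dwell_move,
                            seed=int(rng.integers(2 ** 31)), fs=spec.fs)
    signals = gen_lfp(state, spec.oscs, spec.noise, spec.fs, spec.regions,
                      seed=int(rng.integers(2 ** 31)))
    signals.append(gen_loadcell(state, *spec.loadcell_sd,
                                seed=int(rng.integers(2 ** 31))))
    spikes = [gen_spikes(events, s, duration, seed=int(rng.integers(2 ** 31)),
                         unit_id=f"unit{i}")
              for i, s in enumerate(spec.spike_specs)]
    truth = {
        "fraction_frozen": state.fraction_frozen(),
        "state_fs": spec.fs,
        "state": state.state.astype(int),
        "units": [{"unit_id": f"unit{i}", "kappa": s.kappa,
                   "phi0_deg": s.phi0_deg, "base_rate": s.base_rate}
                  for i, s in enumerate(spec.spike_specs)],
    }
    meta = {"session_kind": spec.protocol.session_kind,
            "laser_condition": spec.protocol.laser, **spec.meta}
    return SessionBundle(signals, events, spikes, meta, ground_truth=truth)
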