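"""Analysis configuration.

Every analysis constant lives here and nowhere else: sampling rate, notch
band, normalization and theta bands, Welch and multitaper windows, baseline
length, PETH bin sizes, minimum freezing bout, and the entrainment alpha.
Configs round-trip through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisParams:
    target_fs: float = 1000.0
    notch_band: tuple[float, float] = (58.0, 62.0)
    norm_band: tuple[float, float] = (2.0, 12.0)
    low_band: tuple[float, float] = (3.0, 6.0)
    high_band: tuple[float, float] = (6.0, 9.0)
    welch_window: float = 2.0        # s
    welch_overlap: float = 0.5       # fraction
    mt_window: float = 3.0           # s
    mt_step: float = 0.1             # s
    mt_nw: float = 3.0
    mt_tapers: int = 5
    baseline: float = 2.0            # s pre-event
    peth_bin: float = 0.1            # s; 0.00125 for fine PETHs
    min_bout: float = 1.0            # s
    smoothing_window: float = 0.2    # s
    alpha: float = 0.05
    artifact_z_thresh: float = 6.0
    artifact_min_frac: float = 0.001
    cs_duration: float = 10.0        # s analysis epoch per CS
    stim_freq: float = 8.0           # Hz, sinusoidal laser
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("notch_band", "norm_band", "low_band", "high_band"):
            band = tuple(float(v) for v in getattr(self, name))
            if len(band) != 2 or not band[0] < band[1]:
                raise ValueError(f"{name} must be (lo, hi) with lo < hi")
            setattr(self, name, band)
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in asdict(self).items()}, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisParams":
        raw = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record emitted with every pipeline run."""

    config_hash: str
    seed: int
    inputs: list[str] = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)
    rejected_trials: int = 0

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
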