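"""Run configuration: one serializable object covering every stage.

Defaults follow the deployed system: 1 cm spacing, 340 m/s, 44.1 kHz,
1024/512 Hamming framing, cepstral update weight 0.85, 16-band CI table.
YAML (human) and JSON (machine) both round-trip losslessly; CLI flags win
over file values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ArrayGeometry
from .enhancer import CepstralTracker, FrameConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    mic_spacing_m: float = 0.01
    sound_speed_mps: float = 340.0
    sample_rate_hz: float = 44100.0
    frame_len: int = 1024
    hop: int = 512
    window: str = "hamming"
    beta: float = 0.85
    cep_order: int = 12
    scale_a: float = 1.0
    threshold: float | None = None
    n_init_frames: int = 10
    forgetting: float = 0.5
    power_smooth: float = 1.0
    per_bin_min_frames: int = 25
    vad_power_smooth: float = 0.6
    vad_patience: int = 4
    vad_growth: float = 1.5
    compensation_mode: str = "band_table"
    phase_source: str = "ch1"
    envelope_cutoff_hz: float = 400.0
    vocoder_filter_order: int = 4
    seed: int = 0
    log_level: str = "INFO"

    def geometry(self) -> ArrayGeometry:
        return ArrayGeometry(self.mic_spacing_m, self.sound_speed_mps, self.sample_rate_hz)

    def frame_config(self) -> FrameConfig:
        return FrameConfig(self.frame_len, self.hop, self.window)

    def tracker(self) -> CepstralTracker:
        return CepstralTracker(self.beta, self.cep_order, self.scale_a, self.threshold)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)

    def merged(self, **overrides) -> "RunConfig":
        """A copy with the non-None overrides applied (CLI flags win)."""
        d = self.to_dict()
        for k, v in overrides.items():
            if v is not None:
                d[k] = v
        return self.from_dict(d)
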