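"""Core carriers: sampled waveforms and the two-microphone array geometry."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AudioSignal:
    """A sampled waveform with its sample rate.

    The universal carrier between pipeline stages. ``data`` is a 1-D float64
    array; amplitudes are dimensionless (full scale ~ 1).
    """

    data: np.ndarray
    sample_rate_hz: float = 44100.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 1:
            raise ValueError("AudioSignal carries a single channel (1-D array)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    def rms(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.data**2)))


@dataclass(frozen=True)
class ArrayGeometry:
    """Geometry of the two-omnidirectional-microphone pair.

    The inter-microphone acoustic travel time d/c sets every delay and gain
    constant in the algorithm. With the defaults (1 cm spacing, 340 m/s,
    44.1 kHz) the inter-mic delay is 1.297 samples.
    """

    mic_spacing_m: float = 0.01
    sound_speed_mps: float = 340.0
    sample_rate_hz: float = 44100.0

    def __post_init__(self) -> None:
        for name in ("mic_spacing_m", "sound_speed_mps", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def delay_s(self) -> float:
        """Acoustic travel time between the microphones, d/c, in seconds."""
        return self.mic_spacing_m / self.sound_speed_mps

    @property
    def delay_samples(self) -> float:
        """d/c expressed in sampling points (1.297 for the defaults)."""
        return self.delay_s * self.sample_rate_hz
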