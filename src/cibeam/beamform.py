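"""First-order differential beamforming: the dual-channel front end.

The two microphone signals are cross-delayed by the acoustic travel time
d/c and subtracted:

    ch1(t) = MIC1(t) - MIC2(t - d/c)
    ch2(t) = MIC2(t) - MIC1(t - d/c)

For a front source (azimuth 0) the delayed MIC1 equals MIC2, so ch2 nulls
the desired speech; for a rear source (180) ch1 nulls the interferer. The
per-bin noise power ratio between the channels is a pure function of the
noise azimuth (the directivity coefficient, ~cot^4(phi/2)), which is what
the spectral stage exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ArrayGeometry, AudioSignal
from .delay import DelayFilter, apply_delay, design_maxflat_delay

__all__ = ["MicPair", "DualChannels", "form_channels", "channel_power_ratio_theory"]


@dataclass
class MicPair:
    """The two raw, time-aligned microphone waveforms."""

    mic1: AudioSignal
    mic2: AudioSignal

    def __post_init__(self) -> None:
        if len(self.mic1) != len(self.mic2):
            raise ValueError("microphone channels must have equal length")
        if self.mic1.sample_rate_hz != self.mic2.sample_rate_hz:
            raise ValueError("microphone channels must share a sample rate")


@dataclass
class DualChannels:
    """The two differential beamformer outputs and how they were formed."""

    ch1: AudioSignal
    ch2: AudioSignal
    geom: ArrayGeometry
    delay_filter: DelayFilter


def form_channels(
    mics: MicPair, geom: ArrayGeometry, filt: DelayFilter | None = None
) -> DualChannels:
    """Form the differential channels with the runtime fractional delay.

    If no filter is given, the 4th-order maximally-flat design for the
    geometry's d/c delay is used. A supplied filter must match the
    geometry's delay to within 0.01 samples.
    """
    if filt is None:
        filt = design_maxflat_delay(geom.delay_samples, order=4)
    if abs(filt.nominal_delay_samples - geom.delay_samples) > 0.01:
        raise ValueError(
            "delay filter nominal delay does not match the array geometry "
            f"({filt.nominal_delay_samples} vs {geom.delay_samples} samples)"
        )
    d1 = apply_delay(mics.mic1, filt)
    d2 = apply_delay(mics.mic2, filt)
    ch1 = AudioSignal(mics.mic1.data - d2.data, mics.mic1.sample_rate_hz)
    ch2 = AudioSignal(mics.mic2.data - d1.data, mics.mic2.sample_rate_hz)
    return DualChannels(ch1=ch1, ch2=ch2, geom=geom, delay_filter=filt)


def channel_power_ratio_theory(f_hz: np.ndarray | float, phi_deg: float, geom: ArrayGeometry) -> np.ndarray:
    """Exact |CH1|^2 / |CH2|^2 for a single source at azimuth phi.

    sin^2(0.5 w d/c (1 + cos phi)) / sin^2(0.5 w d/c (1 - cos phi)); the
    small-argument limit is cot^4(phi/2).
    """
    w_dc = 2.0 * np.pi * np.asarray(f_hz, dtype=float) * geom.delay_s
    c = np.cos(np.deg2rad(phi_deg))
    num = np.sin(0.5 * w_dc * (1.0 + c)) ** 2
    den = np.sin(0.5 * w_dc * (1.0 - c)) ** 2
    return num / np.where(den == 0, np.nan, den)
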