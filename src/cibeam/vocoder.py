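"""CIS sine-vocoder simulation of cochlear-implant processing.

The acoustic model of the CIS strategy: the signal is split by the 16-band
CI filter bank, each band's temporal envelope is extracted (full-wave
rectification + low-pass), and one sinusoidal carrier per band — at the
band's center frequency — is modulated by that envelope and summed. The
output therefore keeps the time-domain energy contour but concentrates the
spectral energy at the 16 center frequencies, which is why spectral
differences *within* a band (where enhancement distortion lives) are
smoothed away after vocoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .broadband import BandTable, build_default_band_table
from .core import AudioSignal

__all__ = ["VocoderConfig", "analyze_bands", "extract_envelope", "vocode"]


@dataclass
class VocoderConfig:
    """Band table plus envelope-extraction parameters.

    ``filter_order`` is the design order of each Butterworth band-pass
    (applied forward-backward, so zero-phase and effectively doubled).
    ``envelope_cutoff_hz`` may exceed the lowest band's width; that simply
    leaves more carrier ripple in the low bands.
    """

    band_table: BandTable = field(default_factory=build_default_band_table)
    envelope_cutoff_hz: float = 400.0
    filter_order: int = 4
    envelope_order: int = 2
    pre_emphasis: float | None = None  # optional first-difference coefficient

    def __post_init__(self) -> None:
        if self.filter_order < 2 or self.envelope_order < 1:
            raise ValueError("filter orders too low")
        if self.envelope_cutoff_hz <= 0:
            raise ValueError("envelope_cutoff_hz must be positive")


def _maybe_preemph(x: np.ndarray, coeff: float | None) -> np.ndarray:
    if coeff is None:
        return x
    return np.concatenate([[x[0]], x[1:] - coeff * x[:-1]])


def analyze_bands(x: AudioSignal, cfg: VocoderConfig | None = None) -> list[AudioSignal]:
    """Split into the 16 band-limited waveforms (zero-phase filtering)."""
    if cfg is None:
        cfg = VocoderConfig()
    top = cfg.band_table.bands[-1].hi_hz
    if x.sample_rate_hz < 2 * top:
        raise ValueError(
            f"sample rate {x.sample_rate_hz} too low for the {top} Hz band edge"
        )
    data = _maybe_preemph(x.data, cfg.pre_emphasis)
    out = []
    for b in cfg.band_table.bands:
        sos = sps.butter(cfg.filter_order, [b.lo_hz, b.hi_hz], btype="bandpass",
                         fs=x.sample_rate_hz, output="sos")
        out.append(AudioSignal(sps.sosfiltfilt(sos, data), x.sample_rate_hz))
    return out


def extract_envelope(band: AudioSignal, cfg: VocoderConfig | None = None) -> AudioSignal:
    """Full-wave rectification followed by a low-pass; non-negative output."""
    if cfg is None:
        cfg = VocoderConfig()
    sos = sps.butter(cfg.envelope_order, cfg.envelope_cutoff_hz, btype="lowpass",
                     fs=band.sample_rate_hz, output="sos")
    env = sps.sosfiltfilt(sos, np.abs(band.data))
    return AudioSignal(np.maximum(env, 0.0), band.sample_rate_hz)


def vocode(x: AudioSignal, cfg: VocoderConfig | None = None) -> AudioSignal:
    """Sum of per-band envelopes riding on sine carriers at band centers.

    Peak-normalized to the input's peak (no loudness mapping / amplitude
    compression is applied — identity compression, with this function the
    hook for future maps).
    """
    if cfg is None:
        cfg = VocoderConfig()
    bands = analyze_bands(x, cfg)
    t = np.arange(len(x)) / x.sample_rate_hz
    y = np.zeros(len(x))
    for b, band in zip(cfg.band_table.bands, bands):
        env = extract_envelope(band, cfg)
        y += env.data * np.sin(2.0 * np.pi * b.center_hz * t)
    in_peak = float(np.max(np.abs(x.data))) if len(x) else 0.0
    out_peak = float(np.max(np.abs(y))) if len(y) else 0.0
    if in_peak > 0 and out_peak > 0:
        y *= in_peak / out_peak
    return AudioSignal(y, x.sample_rate_hz)
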