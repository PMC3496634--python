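"""WAV input/output.

Reads 16/24-bit PCM and 32-bit float WAV files (mono or 2-channel) into
float64 arrays scaled to [-1, 1]; writes 32-bit float so that a
read -> write round trip of float data is bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .core import AudioSignal

__all__ = ["read_wav", "write_wav", "UnsupportedWavError"]


class UnsupportedWavError(ValueError):
    """The WAV file uses an encoding this package does not handle."""


_PCM_SCALE = {np.dtype(np.int16): 2.0**15, np.dtype(np.int32): 2.0**31}


def read_wav(path: str | Path) -> list[AudioSignal]:
    """Read a WAV file; returns one AudioSignal per channel.

    16-bit and 24-bit PCM are scaled to [-1, 1); 32/64-bit float is passed
    through unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        fs, data = wavfile.read(path)
    except ValueError as exc:
        raise UnsupportedWavError(f"cannot read {path}: {exc}") from exc
    if data.dtype in _PCM_SCALE:
        arr = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype in (np.float32, np.float64):
        arr = data.astype(np.float64)
    else:
        raise UnsupportedWavError(
            f"{path}: unsupported sample encoding {data.dtype} "
            "(supported: 16/24-bit PCM, 32-bit float)"
        )
    if arr.ndim == 1:
        return [AudioSignal(arr, fs)]
    return [AudioSignal(arr[:, ch], fs) for ch in range(arr.shape[1])]


def write_wav(path: str | Path, *signals: AudioSignal) -> None:
    """Write one (mono) or two (stereo) signals as 32-bit float WAV."""
    if not 1 <= len(signals) <= 2:
        raise ValueError("write_wav takes one or two channels")
    fs = signals[0].sample_rate_hz
    if any(s.sample_rate_hz != fs for s in signals):
        raise ValueError("all channels must share a sample rate")
    if len({len(s) for s in signals}) != 1:
        raise ValueError("all channels must have equal length")
    if len(signals) == 1:
        data = signals[0].data.astype(np.float32)
    else:
        data = np.stack([s.data for s in signals], axis=1).astype(np.float32)
    wavfile.write(Path(path), int(round(fs)), data)
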