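"""Maximally-flat FIR fractional-delay filter.

The runtime d/c delay (about 1.297 samples at 44.1 kHz for a 1 cm pair) is
realized by a short FIR filter whose frequency-response error and all its
derivatives vanish at DC — the maximally-flat criterion, whose closed-form
solution is the Lagrange interpolation kernel

    h(n) = prod_{k != n} (D - k) / (n - k),  n = 0..N.

For N = 4 and D = 1.297 this yields the tap set
(-0.0400, 0.6995, 0.4433, -0.1220, 0.0192), accurate to better than 0.3 %
in magnitude and 0.4 % in phase over 0–6000 Hz, which covers the CI filter
bank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core import AudioSignal

__all__ = ["DelayFilter", "design_maxflat_delay", "apply_delay", "response_error"]


@dataclass(frozen=True)
class DelayFilter:
    """FIR fractional-delay filter: taps h(0..N) approximating z^{-D}."""

    taps: np.ndarray
    nominal_delay_samples: float
    order: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "taps", np.asarray(self.taps, dtype=np.float64))
        if len(self.taps) != self.order + 1:
            raise ValueError("len(taps) must equal order + 1")
        if abs(self.taps.sum() - 1.0) > 0.01:
            raise ValueError("DC gain of a maximally-flat delay must be 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "taps": self.taps.tolist(),
                    "nominal_delay_samples": self.nominal_delay_samples,
                    "order": self.order,
                },
                indent=2,
            )
        )


def design_maxflat_delay(delay_samples: float, order: int = 4) -> DelayFilter:
    """Design the order-N maximally-flat (Lagrange) FIR fractional delay.

    Parameters
    ----------
    delay_samples
        Desired delay D in sampling points; must lie in [0, order], where
        the design is well conditioned.
    order
        Filter order N (the filter has N + 1 taps).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0.0 <= delay_samples <= order:
        raise ValueError(
            f"delay_samples must lie in [0, {order}] (got {delay_samples}); "
            "the Lagrange design is ill-conditioned outside the tap span"
        )
    n = np.arange(order + 1)
    taps = np.ones(order + 1)
    for k in range(order + 1):
        mask = n != k
        taps[mask] *= (delay_samples - k) / (n[mask] - k)
    return DelayFilter(taps=taps, nominal_delay_samples=float(delay_samples), order=order)


def apply_delay(x: AudioSignal, filt: DelayFilter) -> AudioSignal:
    """Convolve with the delay taps, causal, output truncated to len(x).

    The first ``order`` output samples are transient (zero-padded history);
    sessions are expected to start with a noise-only lead-in so the transient
    never overlaps speech.
    """
    y = sps.lfilter(filt.taps, [1.0], x.data)
    return AudioSignal(y, x.sample_rate_hz)


def response_error(
    filt: DelayFilter,
    f_lo_hz: float,
    f_hi_hz: float,
    fs_hz: float,
    n_grid: int = 2048,
) -> tuple[float, float]:
    """Maximal deviation from the ideal all-pass delay e^{-j w D}.

    Returns ``(max_mag_err, max_phase_err)`` as fractions: the magnitude
    error is max ||H| - 1|; the phase error is the maximum of
    |(arg H + w D) / (w D)| on the grid, excluding DC where the relative
    measure is undefined.
    """
    if not (0 <= f_lo_hz < f_hi_hz <= fs_hz / 2):
        raise ValueError("need 0 <= f_lo < f_hi <= fs/2")
    w = 2.0 * np.pi * np.linspace(f_lo_hz, f_hi_hz, n_grid) / fs_hz
    _, h = sps.freqz(filt.taps, [1.0], worN=w)
    mag_err = float(np.max(np.abs(np.abs(h) - 1.0)))
    phase = np.unwrap(np.angle(h))
    ideal = -w * filt.nominal_delay_samples
    nz = np.abs(ideal) > 0
    if not np.any(nz):
        return mag_err, 0.0
    phase_err = float(np.max(np.abs((phase[nz] - ideal[nz]) / ideal[nz])))
    return mag_err, phase_err
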