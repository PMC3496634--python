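"""Broadband gain compensation for the differential array's frequency tilt.

A first-order differential pair attenuates a front source by
2·sin(2*pi*f*d/c): a steep low-frequency roll-off. The spectral magnitude
estimate is therefore re-equalized by

    lambda(f) = 1 / (2 sin(2 pi f d/c)),

monotone decreasing on 100-6000 Hz (roughly 27 down to 0.6 for a 1 cm
pair). Two realizations are provided:

* ``band_table`` — lambda evaluated at the 16 CI filter-bank band centers
  and transferred as per-band adjusting coefficients (the filter-bank
  strategy path);
* ``butterworth`` — a 1st-order band-pass (cutoffs 0.00045*fs and
  0.0045*fs) whose response approximates lambda(f)/30, followed by a fixed
  30x (29.54 dB) gain (the no-filter-bank path).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core import ArrayGeometry

__all__ = [
    "Band",
    "BandTable",
    "CompensationFilter",
    "lambda_gain",
    "build_default_band_table",
    "design_butterworth_approx",
    "apply_compensation",
    "DEFAULT_BAND_EDGES",
    "DEFAULT_BAND_CENTERS",
    "VERBATIM_COEFFS",
]

# 16-band CI filter bank: [lo, hi] edges and center frequencies, Hz
DEFAULT_BAND_EDGES: list[tuple[float, float]] = [
    (156, 276), (276, 410), (410, 560), (560, 730), (730, 922), (922, 1138),
    (1138, 1380), (1380, 1653), (1653, 1960), (1960, 2305), (2305, 2694),
    (2694, 3131), (3131, 3623), (3623, 4176), (4176, 4798), (4798, 5498),
]
DEFAULT_BAND_CENTERS: list[float] = [
    216, 343, 485, 645, 826, 1030, 1259, 1517, 1807, 2133, 2500, 2913, 3377,
    3840, 4487, 5148,
]
# Published adjusting coefficients. Channels 10 and 14 (1.2135, 0.7578) are
# inconsistent with lambda evaluated at their centers (~1.302, ~0.767) and
# look typographical; the default table recomputes every coefficient from
# lambda, while verbatim=True reproduces this list as printed.
VERBATIM_COEFFS: list[float] = [
    12.5294, 7.8934, 5.5861, 4.2047, 3.2883, 2.6428, 2.1685, 1.8071, 1.5255,
    1.2135, 1.1217, 0.9752, 0.8557, 0.7578, 0.6781, 0.6141,
]


@dataclass(frozen=True)
class Band:
    lo_hz: float
    hi_hz: float
    center_hz: float
    adjust_coeff: float


@dataclass
class BandTable:
    """The CI filter-bank bands with their adjusting coefficients."""

    bands: list[Band]

    def __post_init__(self) -> None:
        prev_hi = None
        for b in self.bands:
            if b.lo_hz >= b.hi_hz or not (b.lo_hz <= b.center_hz <= b.hi_hz):
                raise ValueError(f"malformed band {b}")
            if b.adjust_coeff <= 0:
                raise ValueError("adjust_coeff must be positive")
            if prev_hi is not None and b.lo_hz != prev_hi:
                raise ValueError("bands must be contiguous and increasing")
            prev_hi = b.hi_hz

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center_hz for b in self.bands])

    @property
    def coeffs(self) -> np.ndarray:
        return np.array([b.adjust_coeff for b in self.bands])

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.bands[0].lo_hz] + [b.hi_hz for b in self.bands])

    def coeff_for_freqs(self, f_hz: np.ndarray) -> np.ndarray:
        """Per-frequency coefficient: the containing band's, or the nearest
        band's for out-of-range frequencies (lambda diverges toward DC)."""
        idx = np.searchsorted(self.edges, f_hz, side="right") - 1
        idx = np.clip(idx, 0, len(self.bands) - 1)
        return self.coeffs[idx]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_dict(self) -> list[dict]:
        return [
            {"channel": i + 1, "lo_hz": b.lo_hz, "hi_hz": b.hi_hz,
             "center_hz": b.center_hz, "coeff": b.adjust_coeff}
            for i, b in enumerate(self.bands)
        ]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["channel", "lo_hz", "hi_hz", "center_hz", "coeff"])
            for row in self.to_dict():
                w.writerow([row["channel"], row["lo_hz"], row["hi_hz"],
                            row["center_hz"], row["coeff"]])

    @classmethod
    def from_json(cls, path: str | Path) -> "BandTable":
        rows = json.loads(Path(path).read_text())
        return cls([Band(r["lo_hz"], r["hi_hz"], r["center_hz"], r["coeff"]) for r in rows])


@dataclass
class CompensationFilter:
    """How the lambda(f) re-equalization is applied."""

    mode: str = "band_table"  # or "butterworth"
    butter_low_hz: float = 0.00045 * 44100.0
    butter_high_hz: float = 0.0045 * 44100.0
    post_gain_linear: float = 30.0
    sample_rate_hz: float = 44100.0

    def __post_init__(self) -> None:
        if self.mode not in ("band_table", "butterworth"):
            raise ValueError("mode must be 'band_table' or 'butterworth'")
        if self.post_gain_linear <= 0:
            raise ValueError("post_gain_linear must be positive")
        if not (0 < self.butter_low_hz < self.butter_high_hz < self.sample_rate_hz / 2):
            raise ValueError("cutoffs must lie inside (0, fs/2) and be ordered")

    @property
    def post_gain_db(self) -> float:
        return float(20.0 * np.log10(self.post_gain_linear))

    def butter_ba(self) -> tuple[np.ndarray, np.ndarray]:
        return sps.butter(
            1, [self.butter_low_hz, self.butter_high_hz], btype="bandpass",
            fs=self.sample_rate_hz,
        )

    def magnitude_at(self, f_hz: np.ndarray) -> np.ndarray:
        """|Butter(f)| * post_gain on the given frequency grid."""
        b, a = self.butter_ba()
        w = 2.0 * np.pi * np.asarray(f_hz, dtype=float) / self.sample_rate_hz
        _, h = sps.freqz(b, a, worN=w)
        return np.abs(h) * self.post_gain_linear


def lambda_gain(f_hz: float | np.ndarray, geom: ArrayGeometry | None = None) -> float | np.ndarray:
    """The re-equalization gain lambda(f) = 1/(2 sin(2 pi f d/c))."""
    if geom is None:
        geom = ArrayGeometry()
    f = np.asarray(f_hz, dtype=float)
    arg = 2.0 * np.pi * f * geom.delay_s
    s = np.sin(arg)
    if np.any(s <= 0):
        raise ValueError("lambda(f) requires sin(2 pi f d/c) > 0 (f below c/(2d))")
    out = 1.0 / (2.0 * s)
    return float(out) if np.isscalar(f_hz) else out


def build_default_band_table(geom: ArrayGeometry | None = None, verbatim: bool = False) -> BandTable:
    """The 16-band table with coefficients from lambda at each band center.

    ``verbatim=True`` returns the published coefficient list instead
    (including its two inconsistent entries).
    """
    if geom is None:
        geom = ArrayGeometry()
    bands = []
    for (lo, hi), c, v in zip(DEFAULT_BAND_EDGES, DEFAULT_BAND_CENTERS, VERBATIM_COEFFS):
        coeff = v if verbatim else float(lambda_gain(c, geom))
        bands.append(Band(lo, hi, c, coeff))
    return BandTable(bands)


def design_butterworth_approx(fs_hz: float = 44100.0, geom: ArrayGeometry | None = None) -> CompensationFilter:
    """First-order band-pass approximation of lambda(f)/30, plus 30x gain."""
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    return CompensationFilter(
        mode="butterworth",
        butter_low_hz=0.00045 * fs_hz,
        butter_high_hz=0.0045 * fs_hz,
        post_gain_linear=30.0,
        sample_rate_hz=fs_hz,
    )


def apply_compensation(
    magnitudes: np.ndarray,
    freqs_hz: np.ndarray,
    comp: CompensationFilter | None = None,
    table: BandTable | None = None,
) -> np.ndarray:
    """Multiply per-bin magnitudes by the broadband adjusting gain."""
    magnitudes = np.asarray(magnitudes, dtype=float)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    mode = comp.mode if comp is not None else "band_table"
    if mode == "band_table":
        if table is None:
            table = build_default_band_table()
        return magnitudes * table.coeff_for_freqs(freqs_hz)
    if comp is None:
        raise ValueError("butterworth mode needs a CompensationFilter")
    return magnitudes * comp.magnitude_at(freqs_hz)
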