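"""Synthetic two-microphone acoustic scenes.

Deterministic, seeded stand-ins for chamber recordings: a front speech
source and one directional (optionally moving) interferer rendered onto a
pair of omnidirectional microphones 1 cm apart under an anechoic far-field
plane-wave model. Each source reaches the second microphone with a pure
inter-channel delay of (d/c)·cos(azimuth) seconds and unit gain — no
spherical spreading difference, no reverberation.

The rendering delay here is an *oracle*: a 129-tap Kaiser-windowed sinc
interpolator whose error is negligible against the 5-tap runtime filter
under test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ArrayGeometry, AudioSignal

__all__ = [
    "SourceSpec",
    "SceneSession",
    "synth_speech_like",
    "synth_noise",
    "apply_azimuth_delay",
    "fractional_delay_oracle",
    "simulate_scene",
    "sweep_trajectory",
]

#: half-width of the windowed-sinc interpolation kernel (order 128)
_SINC_HALF = 64
_KAISER_BETA = 8.6


@dataclass
class SourceSpec:
    """Direction (and optional motion) of one far-field source.

    ``azimuth_deg`` uses the broadside convention: 0° is the array's forward
    axis, 90° is to the side where the interferer usually sits. Mirror
    symmetry about the array axis is inherent: phi and 360° − phi are
    indistinguishable to the pair. ``trajectory`` is an optional list of
    (time_s, azimuth_deg) breakpoints, linearly interpolated; it overrides
    ``azimuth_deg`` while active.
    """

    azimuth_deg: float = 0.0
    trajectory: list[tuple[float, float]] | None = None
    rms_level: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.azimuth_deg < 360.0:
            raise ValueError("azimuth_deg must lie in [0, 360)")
        if self.rms_level < 0:
            raise ValueError("rms_level must be >= 0")
        if self.trajectory is not None:
            for _, az in self.trajectory:
                if not 0.0 <= az < 360.0:
                    raise ValueError("trajectory azimuths must lie in [0, 360)")

    def azimuth_at(self, t_s: np.ndarray | float) -> np.ndarray | float:
        if self.trajectory is None:
            return np.broadcast_to(self.azimuth_deg, np.shape(t_s)) if np.ndim(t_s) else self.azimuth_deg
        ts = np.array([p[0] for p in self.trajectory])
        azs = np.array([p[1] for p in self.trajectory])
        return np.interp(t_s, ts, azs)


@dataclass
class SceneSession:
    """A rendered scene: the microphone pair plus clean per-source references.

    ``mic1 = clean_speech_ref + clean_noise_ref`` holds exactly (linear
    mixing). ``speech_pair`` / ``noise_pair`` keep each component at *both*
    microphones so the enhancement gains can later be shadow-applied to the
    isolated components.
    """

    mic1: AudioSignal
    mic2: AudioSignal
    clean_speech_ref: AudioSignal
    clean_noise_ref: AudioSignal
    speech_pair: tuple[AudioSignal, AudioSignal]
    noise_pair: tuple[AudioSignal, AudioSignal]
    segment_marks: dict[str, int]
    geom: ArrayGeometry

    def __post_init__(self) -> None:
        n = len(self.mic1)
        for sig in (self.mic2, self.clean_speech_ref, self.clean_noise_ref):
            if len(sig) != n:
                raise ValueError("all session waveforms must have equal length")

    @property
    def speech_slice(self) -> slice:
        return slice(self.segment_marks["speech_start"], self.segment_marks["speech_end"])


def _seeded(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *salt]))


def synth_speech_like(
    duration_s: float, f0_hz: float = 120.0, seed: int = 0, sample_rate_hz: float = 44100.0
) -> AudioSignal:
    """An amplitude-modulated harmonic complex that mimics voiced speech.

    Harmonics of ``f0_hz`` up to 5.5 kHz with 1/k spectral roll-off and
    random phases, a syllabic-rate (2–8 Hz) envelope, and a slow pitch
    vibrato. Peak-normalized to 0.95. Deterministic for a fixed seed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not 50.0 <= f0_hz <= 400.0:
        raise ValueError("f0_hz must lie in [50, 400] Hz")
    rng = _seeded(seed, 101)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz

    # gentle pitch modulation keeps the harmonics speech-like, not organ-like
    vibrato = 1.0 + 0.01 * np.sin(2 * np.pi * rng.uniform(4.0, 6.0) * t + rng.uniform(0, 2 * np.pi))
    phase0 = np.cumsum(2 * np.pi * f0_hz * vibrato / sample_rate_hz)
    n_harm = int(5500.0 // f0_hz)
    x = np.zeros(n)
    for k in range(1, n_harm + 1):
        x += (1.0 / k) * np.sin(k * phase0 + rng.uniform(0, 2 * np.pi))

    # syllabic envelope: a few random sinusoids in 2-8 Hz, rectified upward
    env = np.ones(n)
    for _ in range(3):
        env += 0.5 * np.sin(2 * np.pi * rng.uniform(2.0, 8.0) * t + rng.uniform(0, 2 * np.pi))
    env = np.clip(env, 0.05, None)
    ramp = min(n // 20, int(0.02 * sample_rate_hz))
    if ramp > 0:
        fade = np.linspace(0.0, 1.0, ramp)
        env[:ramp] *= fade
        env[-ramp:] *= fade[::-1]
    x *= env
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.95 / peak
    return AudioSignal(x, sample_rate_hz)


def synth_noise(
    duration_s: float, kind: str = "babble", seed: int = 0, sample_rate_hz: float = 44100.0
) -> AudioSignal:
    """Seeded interferer waveforms: ``babble``, ``tonal_music`` or ``white``.

    babble: sum of 5 independent speech-like voices. tonal_music: a slowly
    changing chord of sinusoids with percussive onsets (strongly
    non-stationary). white: flat-spectrum Gaussian noise. Peak <= 1.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _seeded(seed, 202)
    n = int(round(duration_s * sample_rate_hz))
    if kind == "white":
        x = rng.standard_normal(n)
    elif kind == "babble":
        x = np.zeros(n)
        for v in range(5):
            f0 = float(rng.uniform(90.0, 280.0))
            x += synth_speech_like(duration_s, f0, seed=int(rng.integers(2**31)), sample_rate_hz=sample_rate_hz).data[:n]
    elif kind == "tonal_music":
        x = np.zeros(n)
        t = np.arange(n) / sample_rate_hz
        note_len = int(0.4 * sample_rate_hz)
        for start in range(0, n, note_len):
            stop = min(start + note_len, n)
            seg = np.zeros(stop - start)
            ts = t[start:stop] - t[start]
            for _ in range(4):  # a chord of four partials
                f = float(rng.uniform(200.0, 2500.0))
                seg += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * f * ts + rng.uniform(0, 2 * np.pi))
            seg *= np.exp(-ts / 0.15)  # percussive onset + decay
            x[start:stop] += seg
    else:
        raise ValueError(f"unknown noise kind: {kind!r} (use babble, tonal_music or white)")
    peak = np.max(np.abs(x))
    if peak > 0:
        x /= peak
    return AudioSignal(x, sample_rate_hz)


def fractional_delay_oracle(x: np.ndarray, delay_samples: float) -> np.ndarray:
    """High-accuracy fractional delay (windowed sinc, order 128).

    Positive delays shift the signal later; negative delays advance it.
    Output has the same length, zero-filled at the edges. This is the
    reference delay used to *render* scenes, deliberately far more accurate
    than the 5-tap runtime filter being tested against it.
    """
    x = np.asarray(x, dtype=np.float64)
    int_d = int(np.floor(delay_samples))
    frac = delay_samples - int_d
    if frac == 0.0:
        y = x.copy()
    else:
        k = np.arange(-_SINC_HALF, _SINC_HALF + 1)
        taps = np.sinc(k - frac) * np.kaiser(2 * _SINC_HALF + 1, _KAISER_BETA)
        taps /= taps.sum()
        y = sps.fftconvolve(x, taps, mode="full")[_SINC_HALF : _SINC_HALF + len(x)]
    out = np.zeros_like(x)
    if int_d >= 0:
        if int_d < len(x):
            out[int_d:] = y[: len(x) - int_d]
    else:
        if -int_d < len(x):
            out[: len(x) + int_d] = y[-int_d:]
    return out


def apply_azimuth_delay(
    src: AudioSignal, azimuth_deg: float, geom: ArrayGeometry
) -> tuple[AudioSignal, AudioSignal]:
    """Render a far-field source at ``azimuth_deg`` onto the microphone pair.

    Returns ``(at_mic1, at_mic2)`` where mic2 receives the signal delayed by
    (d/c)·cos(azimuth) seconds (negative beyond 90°: mic2 leads).
    """
    if len(src) == 0:
        raise ValueError("source waveform must be non-empty")
    tau = geom.delay_samples * np.cos(np.deg2rad(azimuth_deg))
    at_mic2 = fractional_delay_oracle(src.data, tau)
    return AudioSignal(src.data.copy(), src.sample_rate_hz), AudioSignal(at_mic2, src.sample_rate_hz)


def _render_moving(x: np.ndarray, spec: SourceSpec, geom: ArrayGeometry, block_s: float = 0.01) -> np.ndarray:
    """Block-wise rendering of a moving source onto mic2.

    Each block (<= 10 ms) uses a constant azimuth taken at the block center;
    blocks are delayed on a padded neighbourhood and concatenated without
    overlap. At walking speed the per-block azimuth change is < 0.4 deg.
    """
    fs = geom.sample_rate_hz
    block = max(1, int(round(block_s * fs)))
    pad = _SINC_HALF + int(np.ceil(geom.delay_samples)) + 2
    out = np.zeros_like(x)
    for start in range(0, len(x), block):
        stop = min(start + block, len(x))
        t_mid = (start + stop) / 2 / fs
        az = float(spec.azimuth_at(t_mid))
        tau = geom.delay_samples * np.cos(np.deg2rad(az))
        lo, hi = max(0, start - pad), min(len(x), stop + pad)
        seg = fractional_delay_oracle(x[lo:hi], tau)
        out[start:stop] = seg[start - lo : stop - lo]
    return out


def simulate_scene(
    speech: AudioSignal,
    speech_src: SourceSpec,
    noise: AudioSignal,
    noise_src: SourceSpec,
    geom: ArrayGeometry | None = None,
    snr_db: float = 0.0,
    lead_in_s: float = 3.0,
    tail_s: float = 0.5,
) -> SceneSession:
    """Mix one speech source and one interferer into a two-mic session.

    The noise spans the whole session and is scaled so that the
    speech-active region at MIC1 has the requested input SNR
    (10·log10(sum s² / sum n²)). Speech occupies
    [lead_in, lead_in + len(speech)); the lead-in is the noise-only interval
    the enhancer needs to learn the noise directivity (>= ~0.45 s in
    practice). Moving sources are rendered block-wise along their
    trajectory.
    """
    if geom is None:
        geom = ArrayGeometry(sample_rate_hz=speech.sample_rate_hz)
    if lead_in_s < 0:
        raise ValueError("lead_in_s must be >= 0")
    fs = geom.sample_rate_hz
    lead = int(round(lead_in_s * fs))
    tail = int(round(tail_s * fs))
    n_total = lead + len(speech) + tail
    if len(noise) < n_total:
        raise ValueError(
            f"noise ({len(noise)} samples) shorter than session ({n_total} samples)"
        )

    s1 = np.zeros(n_total)
    s1[lead : lead + len(speech)] = speech.data * speech_src.rms_level
    if speech_src.trajectory is None:
        _, s2sig = apply_azimuth_delay(AudioSignal(s1, fs), speech_src.azimuth_deg, geom)
        s2 = s2sig.data
    else:
        s2 = _render_moving(s1, speech_src, geom)

    n1 = noise.data[:n_total] * noise_src.rms_level
    if noise_src.trajectory is None:
        _, n2sig = apply_azimuth_delay(AudioSignal(n1, fs), noise_src.azimuth_deg, geom)
        n2 = n2sig.data
    else:
        n2 = _render_moving(n1, noise_src, geom)

    region = slice(lead, lead + len(speech))
    p_s = np.sum(s1[region] ** 2)
    p_n = np.sum(n1[region] ** 2)
    if p_n <= 0:
        raise ValueError("noise has no energy in the speech-active region")
    g = np.sqrt(p_s / p_n * 10.0 ** (-snr_db / 10.0))
    n1 = n1 * g
    n2 = n2 * g

    marks = {
        "lead_in_end": lead,
        "speech_start": lead,
        "speech_end": lead + len(speech),
    }
    return SceneSession(
        mic1=AudioSignal(s1 + n1, fs),
        mic2=AudioSignal(s2 + n2, fs),
        clean_speech_ref=AudioSignal(s1, fs),
        clean_noise_ref=AudioSignal(n1, fs),
        speech_pair=(AudioSignal(s1, fs), AudioSignal(s2, fs)),
        noise_pair=(AudioSignal(n1, fs), AudioSignal(n2, fs)),
        segment_marks=marks,
        geom=geom,
    )


def sweep_trajectory(
    lo_deg: float, hi_deg: float, rate_deg_s: float, duration_s: float, start_deg: float | None = None
) -> list[tuple[float, float]]:
    """Triangular azimuth sweep lo->hi->lo... at a constant angular rate.

    ``rate_deg_s`` of about 38.2 deg/s corresponds to 1 m/s tangential
    motion (normal walking speed) at a 1.5 m radius.
    """
    if hi_deg <= lo_deg or rate_deg_s <= 0:
        raise ValueError("need hi > lo and a positive rate")
    leg = (hi_deg - lo_deg) / rate_deg_s
    pts = []
    t, az, direction = 0.0, lo_deg if start_deg is None else start_deg, 1.0
    pts.append((t, az))
    while t < duration_s:
        target = hi_deg if direction > 0 else lo_deg
        dt = abs(target - az) / rate_deg_s
        t = t + dt
        az = target
        pts.append((t, az))
        direction = -direction
    return pts
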