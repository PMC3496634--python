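"""Spectral core of the enhancer.

Per 1024-sample Hamming frame (50 % overlap) the two differential channels
yield power spectra P1, P2. Frames are labelled noise-only by a cepstral
change detector tracked against a noise template; on those frames the
per-bin noise power ratio P1/P2 (the directivity coefficient, ~cot^4(phi/2)
for interferer azimuth phi) is updated with an exponential forgetting
factor. The speech magnitude is then the floored spectral subtraction

    |S_hat|^2 proportional to max(0, P1 - ratio * P2),

re-equalized for the differential array's 2 sin(2 pi f d/c) attenuation
(see :mod:`cibeam.broadband`), and resynthesized by overlap-add with the
channel-1 phase.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .beamform import DualChannels, MicPair, form_channels
from .broadband import BandTable, CompensationFilter, apply_compensation, build_default_band_table
from .core import ArrayGeometry, AudioSignal
from .delay import design_maxflat_delay

__all__ = [
    "FrameConfig",
    "SpectralFrames",
    "CepstralTracker",
    "FrameLabels",
    "DirectivityProfile",
    "DirectivityUnavailableError",
    "stft",
    "istft_overlap_add",
    "update_cepstrum",
    "classify_frames",
    "estimate_directivity",
    "directivity_to_azimuth",
    "estimate_speech_magnitude",
    "enhance",
    "EnhanceDiagnostics",
]


class DirectivityUnavailableError(RuntimeError):
    """Raised when no noise-only frame is available to estimate directivity."""


@dataclass(frozen=True)
class FrameConfig:
    """Short-time framing: 1024-point Hamming frames at 50 % overlap."""

    frame_len: int = 1024
    hop: int = 512
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.frame_len & (self.frame_len - 1):
            raise ValueError("frame_len must be a power of two")
        if self.hop * 2 != self.frame_len:
            raise ValueError("hop must be frame_len/2 (50% overlap)")

    def get_window(self) -> np.ndarray:
        return sps.get_window(self.window, self.frame_len)

    def bin_freqs(self, fs_hz: float) -> np.ndarray:
        return np.fft.rfftfreq(self.frame_len, d=1.0 / fs_hz)


@dataclass
class SpectralFrames:
    """Windowed short-time complex spectra and their power spectra."""

    complex_spectra: np.ndarray  # (n_frames, frame_len//2 + 1)
    frame_times: np.ndarray
    sample_rate_hz: float
    config: FrameConfig
    signal_len: int

    @property
    def power_spectra(self) -> np.ndarray:
        return np.abs(self.complex_spectra) ** 2

    @property
    def n_frames(self) -> int:
        return self.complex_spectra.shape[0]

    @property
    def bin_freqs(self) -> np.ndarray:
        return self.config.bin_freqs(self.sample_rate_hz)


def stft(x: AudioSignal, cfg: FrameConfig | None = None) -> SpectralFrames:
    """Frame, window (Hamming) and transform; hop = frame_len/2."""
    if cfg is None:
        cfg = FrameConfig()
    n = len(x)
    if n < cfg.frame_len:
        raise ValueError(f"signal ({n}) shorter than one frame ({cfg.frame_len})")
    n_frames = (n - cfg.frame_len) // cfg.hop + 1
    win = cfg.get_window()
    starts = np.arange(n_frames) * cfg.hop
    idx = starts[:, None] + np.arange(cfg.frame_len)[None, :]
    spectra = np.fft.rfft(x.data[idx] * win, axis=1)
    times = (starts + cfg.frame_len / 2) / x.sample_rate_hz
    return SpectralFrames(spectra, times, x.sample_rate_hz, cfg, signal_len=n)


def istft_overlap_add(frames: SpectralFrames) -> AudioSignal:
    """Inverse transform + overlap-add, normalized by the summed window.

    Analysis-window-only scheme: each inverse frame still carries the
    Hamming taper; dividing the overlap-added stream by the per-sample sum
    of shifted windows makes stft -> istft the identity (everywhere the
    frames cover, including the partially overlapped edges).
    """
    cfg = frames.config
    win = cfg.get_window()
    n_frames = frames.n_frames
    out_len = (n_frames - 1) * cfg.hop + cfg.frame_len
    out = np.zeros(out_len)
    wsum = np.zeros(out_len)
    time_frames = np.fft.irfft(frames.complex_spectra, n=cfg.frame_len, axis=1)
    for i in range(n_frames):
        start = i * cfg.hop
        out[start : start + cfg.frame_len] += time_frames[i]
        wsum[start : start + cfg.frame_len] += win
    out /= np.maximum(wsum, 1e-12)
    if frames.signal_len > out_len:
        out = np.pad(out, (0, frames.signal_len - out_len))
    return AudioSignal(out[: frames.signal_len], frames.sample_rate_hz)


# ---------------------------------------------------------------------------
# cepstral noise-frame detection

@dataclass
class CepstralTracker:
    """Tracked noise cepstrum and the distance parameters.

    The template is blended toward each accepted noise frame with weight
    ``beta`` (0.85): heavy weighting of the current frame lets the template
    follow non-stationary interferers. The distance between a frame's
    cepstrum c' and the template c is

        d = A (c0' - c0)^2 + 2 sum_{n=1..p} (cn' - cn)^2.
    """

    beta: float = 0.85
    p: int = 12
    scale_A: float = 1.0
    threshold: float | None = None  # None -> auto-calibrated by classify_frames
    cepstrum: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be positive")


def _frame_cepstrum(frame_power: np.ndarray, p: int) -> np.ndarray | None:
    """Real cepstrum of one power spectrum, truncated to c0..cp.

    Returns None for an all-zero (silent) spectrum. The log is floored 100 dB
    below the spectral peak to keep empty bins from dominating.
    """
    frame_power = np.asarray(frame_power, dtype=float)
    if np.any(frame_power < 0):
        raise ValueError("frame_power must be non-negative")
    peak = frame_power.max()
    if peak <= 0:
        return None
    logp = np.log(np.maximum(frame_power, peak * 1e-10))
    c = np.fft.irfft(logp)
    return c[: p + 1]


def _cep_distance(c_new: np.ndarray, c_old: np.ndarray, scale_A: float) -> float:
    d0 = scale_A * (c_new[0] - c_old[0]) ** 2
    return float(d0 + 2.0 * np.sum((c_new[1:] - c_old[1:]) ** 2))


def update_cepstrum(
    tracker: CepstralTracker, frame_power: np.ndarray
) -> tuple[CepstralTracker, float]:
    """Distance of one frame to the tracked cepstrum, then blend it in.

    Returns ``(tracker', distance)``; the distance is computed *before*
    blending. A silent (all-zero) frame returns distance 0 and leaves the
    tracker unchanged. An uninitialized tracker adopts the frame's cepstrum
    with distance 0.
    """
    c_new = _frame_cepstrum(frame_power, tracker.p)
    if c_new is None:
        return tracker, 0.0
    if tracker.cepstrum is None:
        return dataclasses.replace(tracker, cepstrum=c_new), 0.0
    dist = _cep_distance(c_new, tracker.cepstrum, tracker.scale_A)
    blended = tracker.beta * c_new + (1.0 - tracker.beta) * tracker.cepstrum
    return dataclasses.replace(tracker, cepstrum=blended), dist


@dataclass
class FrameLabels:
    """Per-frame noise-only flags with the distances that produced them."""

    noise_only: np.ndarray
    distances: np.ndarray
    threshold: float

    def __len__(self) -> int:
        return len(self.noise_only)


def classify_frames(
    ch1_frames: SpectralFrames,
    tracker_cfg: CepstralTracker | None = None,
    n_init: int = 10,
    k_sigma: float = 3.0,
    power_smooth: float = 0.6,
    reacquire_patience: int = 25,
    reacquire_growth: float = 1.07,
) -> FrameLabels:
    """Label each frame noise-only or speech by cepstral distance.

    Cepstra are computed on the running statistical average of the frame
    power spectra (exponential smoothing, weight ``power_smooth`` on the
    current frame); the raw per-frame spectra of non-stationary interferers
    are too erratic to threshold. The first ``n_init`` frames are assumed
    noise (the mandatory noise-only lead-in) and initialize the template;
    unless an explicit threshold is configured, the decision threshold is
    auto-calibrated as median + k_sigma * 1.4826 MAD of the initialization
    distances (the robust equivalent of mean + k sigma, insensitive to the
    occasional init outlier). The template is updated only on frames
    accepted as noise, so it tracks the (possibly moving) interferer without
    absorbing speech.

    A moving interferer can deadlock such a detector: while speech holds the
    template frozen the noise keeps changing direction, and when speech ends
    no frame is ever again close enough to be accepted. A watchdog guards
    against this: after ``reacquire_patience`` consecutive speech-labelled
    frames the effective threshold grows by ``reacquire_growth`` per frame
    until a frame is re-accepted (the threshold then resets). Re-latching
    happens at the much smaller moved-noise distance long before typical
    speech distances are reached.
    """
    if tracker_cfg is None:
        tracker_cfg = CepstralTracker()
    power = ch1_frames.power_spectra.copy()
    n = power.shape[0]
    if n <= n_init:
        raise ValueError(f"need more than n_init={n_init} frames (got {n})")
    if not 0.0 < power_smooth <= 1.0:
        raise ValueError("power_smooth must lie in (0, 1]")
    for i in range(1, n):
        power[i] = power_smooth * power[i] + (1.0 - power_smooth) * power[i - 1]
    # session-relative silence floor: frames whose peak power sits at the
    # numerical-noise level of the session carry no usable spectrum
    silence_floor = float(power.max()) * 1e-12
    power[power.max(axis=1) <= silence_floor] = 0.0
    tracker = dataclasses.replace(tracker_cfg, cepstrum=None)
    distances = np.zeros(n)
    labels = np.zeros(n, dtype=bool)
    init_d = []
    for i in range(n_init):
        tracker, d = update_cepstrum(tracker, power[i])
        distances[i] = d
        labels[i] = True
        if i > 0:
            init_d.append(d)
    if tracker_cfg.threshold is not None:
        threshold = tracker_cfg.threshold
    else:
        med = float(np.median(init_d))
        mad = float(np.median(np.abs(np.asarray(init_d) - med)))
        threshold = med + k_sigma * 1.4826 * mad + 1e-12
    # An all-silent lead-in leaves the template uninitialized; the first loud
    # frame is then most plausibly speech onset, not noise, so nothing is
    # adopted and no subtraction will be learned (the pipeline passes the
    # compensated channel through).
    template_valid = tracker.cepstrum is not None
    stale = 0
    for i in range(n_init, n):
        c_new = _frame_cepstrum(power[i], tracker.p)
        if c_new is None:
            distances[i] = 0.0
            labels[i] = True
            stale = 0
            continue
        if not template_valid:
            labels[i] = False
            continue
        d = _cep_distance(c_new, tracker.cepstrum, tracker.scale_A)
        distances[i] = d
        eff = threshold * reacquire_growth ** max(0, stale - reacquire_patience)
        if d <= eff:
            labels[i] = True
            stale = 0
            tracker = dataclasses.replace(
                tracker, cepstrum=tracker.beta * c_new + (1.0 - tracker.beta) * tracker.cepstrum
            )
        else:
            stale += 1
    return FrameLabels(noise_only=labels, distances=distances, threshold=threshold)


# ---------------------------------------------------------------------------
# noise directivity

@dataclass
class DirectivityProfile:
    """Tracked noise power ratio E|CH1|^2 / E|CH2|^2 on noise-only frames."""

    ratio_per_bin: np.ndarray
    scalar_ratio: float
    azimuth_deg_est: float | None
    frames_used: int
    forgetting: float = 0.9


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    if cw[-1] <= 0:
        return float(np.median(v))
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def _scalar_from_bins(
    ratio: np.ndarray, weight: np.ndarray, freqs: np.ndarray, band=(300.0, 5000.0)
) -> float:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return _weighted_median(ratio[sel], weight[sel])


def estimate_directivity(
    ch1: SpectralFrames,
    ch2: SpectralFrames,
    labels: FrameLabels,
    forgetting: float = 0.9,
) -> DirectivityProfile:
    """Exponentially-weighted noise power ratio over the labelled noise frames.

    The per-bin numerator/denominator powers are updated recursively
    (new = forgetting * old + (1 - forgetting) * current) so the profile
    tracks a moving interferer; the scalar ratio is the energy-weighted
    median of the per-bin ratios over 300-5000 Hz, the band where the
    cot^4(phi/2) approximation is reliable.
    """
    if not np.any(labels.noise_only):
        raise DirectivityUnavailableError("no noise-only frames: directivity unavailable")
    p1, p2 = ch1.power_spectra, ch2.power_spectra
    num = den = None
    used = 0
    for i in np.flatnonzero(labels.noise_only):
        if num is None:
            num, den = p1[i].copy(), p2[i].copy()
        else:
            num = forgetting * num + (1 - forgetting) * p1[i]
            den = forgetting * den + (1 - forgetting) * p2[i]
        used += 1
    # regularize against the session's channel-2 power scale so that
    # numerically-silent accumulations yield ratio ~ 0, not garbage
    eps = 1e-12 * float(np.max(p2)) + 1e-300
    ratio = num / (den + eps)
    scalar = _scalar_from_bins(ratio, den, ch1.bin_freqs)
    az = directivity_to_azimuth(scalar) if scalar > 0 else None
    return DirectivityProfile(ratio, scalar, az, used, forgetting)


def directivity_to_azimuth(ratio: float) -> float:
    """Invert cot^4(phi/2): phi = 2 atan(ratio^(-1/4)), in (0, 180) degrees."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return float(np.degrees(2.0 * np.arctan(ratio ** (-0.25))))


# ---------------------------------------------------------------------------
# magnitude estimation

def _denominator(freqs: np.ndarray, geom: ArrayGeometry) -> np.ndarray:
    """2 sin(2 pi f d/c), clamped below at its 100 Hz value (DC guard) and
    set to 1 above 6 kHz where the compensation model does not apply."""
    arg = 2.0 * np.pi * freqs * geom.delay_s
    den = 2.0 * np.sin(arg)
    floor = 2.0 * np.sin(2.0 * np.pi * 100.0 * geom.delay_s)
    den = np.maximum(den, floor)
    den[freqs > 6000.0] = 1.0
    return den


def estimate_speech_magnitude(
    ch1_power: np.ndarray,
    ch2_power: np.ndarray,
    profile: DirectivityProfile,
    geom: ArrayGeometry,
    freqs: np.ndarray,
    per_bin_min_frames: int = 25,
    mode: str = "exact",
) -> np.ndarray:
    """Per-bin speech magnitude by floored directivity-weighted subtraction.

    numerator = sqrt(max(0, P1 - ratio * P2)); negative differences are
    floored to zero. The per-bin ratio is used once at least
    ``per_bin_min_frames`` noise frames back it; before that the scalar
    cot^4 form is the robust cold start. ``mode='exact'`` divides by the
    guarded 2 sin(2 pi f d/c) (the full closed form); ``mode='none'``
    returns the bare numerator for a separate broadband-compensation stage.
    """
    ch1_power = np.asarray(ch1_power, dtype=float)
    ch2_power = np.asarray(ch2_power, dtype=float)
    if profile.frames_used >= per_bin_min_frames:
        ratio = profile.ratio_per_bin
    else:
        ratio = profile.scalar_ratio
    num = np.sqrt(np.maximum(0.0, ch1_power - ratio * ch2_power))
    if mode == "none":
        return num
    if mode != "exact":
        raise ValueError("mode must be 'exact' or 'none'")
    return num / _denominator(freqs, geom)


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class EnhanceDiagnostics:
    """What the pipeline decided, frame by frame."""

    labels: FrameLabels | None
    scalar_ratio_trace: np.ndarray
    azimuth_trace: np.ndarray
    gain_mask: np.ndarray  # per-frame, per-bin real gain applied to CH1
    frames_used_final: int
    passthrough: bool = False

    def to_dict(self) -> dict:
        return {
            "threshold": None if self.labels is None else self.labels.threshold,
            "noise_only": None if self.labels is None else self.labels.noise_only.tolist(),
            "cepstral_distances": None if self.labels is None else self.labels.distances.tolist(),
            "scalar_ratio_trace": self.scalar_ratio_trace.tolist(),
            "azimuth_trace": self.azimuth_trace.tolist(),
            "frames_used_final": self.frames_used_final,
            "passthrough": self.passthrough,
        }


def _resample_to(x: AudioSignal, fs: float) -> AudioSignal:
    if x.sample_rate_hz == fs:
        return x
    frac = Fraction(int(round(fs)), int(round(x.sample_rate_hz))).limit_denominator(1000)
    y = sps.resample_poly(x.data, frac.numerator, frac.denominator)
    return AudioSignal(y, fs)


def enhance(
    mics: MicPair,
    geom: ArrayGeometry | None = None,
    frame_cfg: FrameConfig | None = None,
    tracker_cfg: CepstralTracker | None = None,
    n_init: int = 10,
    forgetting: float = 0.5,
    comp: CompensationFilter | None = None,
    table: BandTable | None = None,
    phase_source: str = "ch1",
    power_smooth: float = 1.0,
    per_bin_min_frames: int = 25,
    vad_power_smooth: float = 0.6,
    vad_patience: int = 4,
    vad_growth: float = 1.5,
) -> tuple[AudioSignal, EnhanceDiagnostics]:
    """Run the full dual-channel enhancement pipeline.

    delay design -> differential channels -> STFT -> cepstral noise-frame
    detection -> tracked directivity -> floored spectral subtraction ->
    broadband compensation -> channel-1 phase -> overlap-add.

    ``phase_source`` selects the reconstruction phase: the differential
    channel 1 (``"ch1"``, default) or the raw first microphone
    (``"mic1"``); the cochlea is relatively phase-insensitive, so either
    works. ``power_smooth`` is the current-frame weight of the running
    statistical average of the powers fed to the subtraction; the default
    1.0 uses each frame's own periodogram — for a point interferer the
    per-frame channel power ratio is deterministic, so per-frame powers
    cancel exactly and temporal smoothing only smears onsets.
    ``vad_power_smooth``, ``vad_patience`` and ``vad_growth`` condition the
    noise-frame detector (see :func:`classify_frames`).
    """
    if geom is None:
        geom = ArrayGeometry(sample_rate_hz=44100.0)
    if frame_cfg is None:
        frame_cfg = FrameConfig()
    if tracker_cfg is None:
        tracker_cfg = CepstralTracker()
    if phase_source not in ("ch1", "mic1"):
        raise ValueError("phase_source must be 'ch1' or 'mic1'")
    mics = MicPair(_resample_to(mics.mic1, geom.sample_rate_hz),
                   _resample_to(mics.mic2, geom.sample_rate_hz))
    if table is None and (comp is None or comp.mode == "band_table"):
        table = build_default_band_table(geom)

    filt = design_maxflat_delay(geom.delay_samples, order=4)
    duals = form_channels(mics, geom, filt)
    f1 = stft(duals.ch1, frame_cfg)
    f2 = stft(duals.ch2, frame_cfg)
    freqs = f1.bin_freqs
    comp_gain = apply_compensation(np.ones_like(freqs), freqs, comp, table)
    phase_frames = f1 if phase_source == "ch1" else stft(mics.mic1, frame_cfg)

    n_frames = f1.n_frames
    if n_frames <= n_init:
        warnings.warn(
            "no noise-only lead-in available; passing through compensated "
            "channel-1 magnitude without subtraction",
            RuntimeWarning,
        )
        mags = np.abs(f1.complex_spectra) * comp_gain
        phases = np.angle(phase_frames.complex_spectra)
        out = istft_overlap_add(
            SpectralFrames(mags * np.exp(1j * phases), f1.frame_times,
                           f1.sample_rate_hz, frame_cfg, f1.signal_len)
        )
        gain = mags / np.maximum(np.abs(f1.complex_spectra), 1e-300)
        diag = EnhanceDiagnostics(None, np.zeros(0), np.zeros(0), gain, 0, passthrough=True)
        return out, diag

    labels = classify_frames(
        f1, tracker_cfg, n_init=n_init, power_smooth=vad_power_smooth,
        reacquire_patience=vad_patience, reacquire_growth=vad_growth,
    )
    p1, p2 = f1.power_spectra, f2.power_spectra

    num_ew = den_ew = None
    used = 0
    den_floor = 1e-12 * float(np.max(p2)) + 1e-300
    p1s = p2s = None
    # motion detector: azimuth estimates from recent accepted noise frames;
    # the interferer counts as moving when they span more than 3 degrees
    # within the last half second (~8 deg/s, well below walking speed)
    az_history: list[tuple[int, float]] = []
    motion_window = max(1, int(0.5 * geom.sample_rate_hz / frame_cfg.hop))
    interferer_moving = False
    out_spectra = np.empty_like(f1.complex_spectra)
    gain_mask = np.empty((n_frames, len(freqs)))
    scalar_trace = np.zeros(n_frames)
    az_trace = np.full(n_frames, np.nan)
    for i in range(n_frames):
        if labels.noise_only[i]:
            if num_ew is None:
                num_ew, den_ew = p1[i].copy(), p2[i].copy()
            else:
                num_ew = forgetting * num_ew + (1 - forgetting) * p1[i]
                den_ew = forgetting * den_ew + (1 - forgetting) * p2[i]
            used += 1
        elif interferer_moving and num_ew is not None and np.max(den_ew) > den_floor:
            # speech frame while the interferer is in motion: keep tracking it
            # in the bins it still dominates (recursive-averaging style
            # per-bin update) so the direction is not lost across the
            # utterance. A bin counts as noise-dominated when the current
            # powers are consistent with the tracked ratio, i.e. the
            # subtraction there would floor to ~0. For a static interferer
            # the ratio is simply held instead — cheaper and free of the slow
            # speech-absorption bias this update carries.
            nd = p1[i] <= 2.0 * (num_ew / (den_ew + den_floor)) * p2[i]
            num_ew[nd] = forgetting * num_ew[nd] + (1 - forgetting) * p1[i][nd]
            den_ew[nd] = forgetting * den_ew[nd] + (1 - forgetting) * p2[i][nd]
        if num_ew is not None and np.max(den_ew) > den_floor:
            ratio_bins = num_ew / (den_ew + den_floor)
            scalar = _scalar_from_bins(ratio_bins, den_ew, freqs)
        else:
            ratio_bins = np.zeros_like(freqs)
            scalar = 0.0
        scalar_trace[i] = scalar
        if scalar > 0:
            az_trace[i] = directivity_to_azimuth(scalar)
            if labels.noise_only[i]:
                az_history.append((i, az_trace[i]))
                recent = [a for j, a in az_history if i - j <= motion_window]
                if len(recent) >= 6:
                    half = len(recent) // 2
                    drift = abs(float(np.median(recent[half:])) - float(np.median(recent[:half])))
                    interferer_moving = drift > 2.0
        profile = DirectivityProfile(ratio_bins, scalar, None, used, forgetting)

        if p1s is None:
            p1s, p2s = p1[i].copy(), p2[i].copy()
        else:
            p1s = power_smooth * p1[i] + (1 - power_smooth) * p1s
            p2s = power_smooth * p2[i] + (1 - power_smooth) * p2s
        mag = estimate_speech_magnitude(
            p1s, p2s, profile, geom, freqs,
            per_bin_min_frames=per_bin_min_frames, mode="none",
        )
        out_mag = mag * comp_gain
        ch1_mag = np.abs(f1.complex_spectra[i])
        gain = out_mag / np.maximum(ch1_mag, 1e-300 + 1e-12 * ch1_mag.max())
        gain_mask[i] = gain
        phase = np.angle(phase_frames.complex_spectra[i])
        out_spectra[i] = out_mag * np.exp(1j * phase)

    out = istft_overlap_add(
        SpectralFrames(out_spectra, f1.frame_times, f1.sample_rate_hz, frame_cfg, f1.signal_len)
    )
    diag = EnhanceDiagnostics(labels, scalar_trace, az_trace, gain_mask, used)
    return out, diag
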