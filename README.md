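# cibeam

Dual-microphone speech enhancement for cochlear-implant (CI) front ends:
first-order differential beamforming combined with directivity-informed
spectral estimation, plus a CIS sine-vocoder stage and evaluation metrics,
with a seeded synthetic scene simulator standing in for chamber recordings.

## Who this is for

Hearing-prosthetics and audio-DSP researchers who need a tested, scriptable
reference implementation of the dual-channel enhancement chain: two
omnidirectional microphones 1 cm apart, a desired talker near the forward
axis, and one directional interferer (competing talker, music) at a
comparable level — the situation in which CI users lose most speech
recognition.

## The method

Two microphones receive `MIC1(t) = s(t) + n(t)` and
`MIC2(t) = s(t − d/c·cosθ) + n(t − d/c·cosφ)` (far-field plane waves,
spacing d, sound speed c). Cross-delayed differences

    ch1 = MIC1 − MIC2(t − d/c),   ch2 = MIC2 − MIC1(t − d/c)

put a null on the front talker in ch2 and on a rear source in ch1. The
d/c = 1.297-sample delay is realized by a 4th-order maximally-flat
(Lagrange) FIR filter with taps (−0.0400, 0.6995, 0.4433, −0.1220, 0.0192),
accurate to <0.3 % magnitude and <0.4 % phase over 0–6000 Hz.

On noise-only frames — found by a cepstral-distance detector
(d = A·Δc₀² + 2Σ Δcₙ², template update weight β = 0.85) — the per-bin power
ratio of the channels estimates the noise *directivity coefficient*

    E|CH1|² / E|CH2|² ≈ cot⁴(φ/2),

a pure function of the interferer azimuth φ, tracked with exponential
forgetting so it follows a moving source. Per 1024-point Hamming frame the
speech magnitude is the floored subtraction
`sqrt(max(0, P1 − ratio·P2))`, re-equalized for the array's low-frequency
roll-off by λ(f) = 1/(2 sin(2πf·d/c)) — transferred as 16 per-band
"adjusting coefficients" of the CI filter bank (156–5498 Hz), or as a
1st-order Butterworth band-pass with a 30× (29.54 dB) post-gain — and
resynthesized by overlap-add with the channel-1 phase.

Evaluation uses shadow decomposition (the pipeline's recorded gain mask
applied separately to the clean speech and noise components) to measure the
broadband and band-weighted SNR improvement, and a clean-power-weighted
speech distortion index. A CIS sine vocoder (16 band envelopes modulating
sine carriers at the band centers) models the CI coding stage, under which
enhancement distortion largely collapses.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```bash
cibeam demo --seed 1 --out-dir demo_run
```

simulates a 0 dB scene (front speech-like utterance, tonal-music interferer
at 90°, 3 s noise-only lead-in), enhances it, vocodes the result, and
evaluates. It prints

```
INFO cibeam: broadband dSNR = 17.28 dB, distortion = -4.85 dB
```

and writes `demo_run/report.json`:

```json
{
  "snr_in_db": -4.64,
  "snr_out_db": 12.63,
  "broadband_delta_snr_db": 17.28,
  "delta_snr_db": 20.51,
  "distortion_index_db": -4.85,
  ...
}
```

`snr_in_db` is the whole-session input SNR at MIC1 (negative because the
session includes noise before and after the 1.5 s utterance even
though speech and noise play at equal power); `broadband_delta_snr_db` is
the output-minus-input SNR measured by shadow decomposition — the headline
improvement; `delta_snr_db` is the uniformly band-weighted version over the
16-band CI bank; `distortion_index_db` is the speech distortion index over
the speech-active interval (more negative = less distortion). The command
exits nonzero if the broadband improvement falls under 10 dB.

The same stages are scriptable individually:

```bash
cibeam simulate --noise-kind babble --noise-azimuth 90 --snr-db 0 \
    --lead-in 3.0 --seed 7 --out-prefix scene
cibeam enhance --in scene_mics.wav --out enhanced.wav \
    --dump-diagnostics diag.json
cibeam vocode --in enhanced.wav --out vocoded.wav
cibeam evaluate --scene-prefix scene --enhanced enhanced.wav \
    --report report.json
```

or from Python:

```python
from cibeam import *
from cibeam.beamform import MicPair

geom = ArrayGeometry()                      # 1 cm, 340 m/s, 44.1 kHz
speech = synth_speech_like(1.0, f0_hz=120, seed=7)
noise = synth_noise(7.2, "babble", seed=8)
scene = simulate_scene(speech, SourceSpec(0.0), noise, SourceSpec(90.0),
                       geom=geom, snr_db=0.0, lead_in_s=3.0, tail_s=3.0)
enhanced, diag = enhance(MicPair(scene.mic1, scene.mic2), geom=geom)
s_hat, n_hat = shadow_decompose(diag, scene)
report = delta_snr(scene, s_hat, n_hat)
print(report.broadband_delta_snr_db)
```

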