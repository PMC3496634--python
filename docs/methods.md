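# Methods

## Problem and signal model

`cibeam` implements a front-end speech enhancer for cochlear-implant (CI)
processors: two omnidirectional microphones spaced d = 1 cm apart pick up a
desired talker near the forward axis (azimuth θ ≈ 0°) and one directional
interferer at azimuth φ (music, a competing talker), typically at a
comparable level (input SNR around 0 dB). Under a far-field, anechoic
plane-wave model the microphones receive

    MIC1(t) = s(t) + n(t)
    MIC2(t) = s(t − d/c·cos θ) + n(t − d/c·cos φ),

with c the speed of sound. At 44.1 kHz and c = 340 m/s the travel time d/c
is 1.297 samples — a fractional delay.

## Pipeline

1. **Fractional delay.** Both microphone signals are delayed by d/c using a
   4th-order maximally-flat FIR filter, equivalent to the Lagrange
   interpolation kernel h(n) = Π_{k≠n}(D−k)/(n−k) with D = 1.297, giving
   taps (−0.0400, 0.6995, 0.4433, −0.1220, 0.0192). Over 0–6000 Hz (the CI
   band) its worst-case magnitude error is 0.21 % and its worst-case
   relative phase error 0.34 %, both computed on a dense frequency grid.
   The first `order` output samples of the convolution are transient; the
   mandatory noise-only lead-in absorbs them.

2. **Differential channels.** ch1 = MIC1 − delay(MIC2) and
   ch2 = MIC2 − delay(MIC1). ch2 nulls a front source exactly; ch1 nulls a
   rear source. For a point source at azimuth φ the per-bin power ratio
   |CH1|²/|CH2|² equals sin²(½ωd/c(1+cos φ)) / sin²(½ωd/c(1−cos φ)), which
   for ωd/c ≪ 1 is the frequency-flat directivity coefficient cot⁴(φ/2).

3. **Framing.** 1024-point Hamming frames, 50 % overlap (≈23 ms at
   44.1 kHz). Reconstruction is overlap-add of the inverse transforms,
   normalized by the per-sample sum of shifted analysis windows, so the
   analysis–synthesis chain is the identity when spectra are untouched.

4. **Noise-frame detection.** A real cepstrum (c0…cp, p = 12) is computed
   per frame from the flooring-protected log power spectrum of channel 1.
   Because raw periodograms of non-stationary interferers fluctuate too
   much to threshold, the cepstrum is taken on the running statistical
   average of the frame powers (exponential smoothing, weight 0.6 on the
   current frame). A tracked noise template is compared with each frame by
   d = A(c0′−c0)² + 2Σ(cn′−cn)², A = 1; frames with d at or below a
   threshold are noise-only and blend into the template with weight
   β = 0.85 on the current frame. The first 10 frames (~0.12 s) are forced
   noise and calibrate the threshold as median + 3·1.4826·MAD of their
   distances — the robust equivalent of a mean + 3σ rule, chosen because
   init distances of onset-rich interferers are heavy-tailed and a moment
   threshold collapses the detector's sensitivity.

   Updating the template only on accepted noise frames keeps speech out of
   it, but can deadlock against a *moving* interferer: while speech holds
   the template frozen the noise moves on, and afterwards no frame is ever
   close enough to re-latch. A watchdog handles this: after 4 consecutive
   rejections the effective threshold grows by ×1.5 per frame until a frame
   is accepted, then resets. Re-latching occurs at the moved-noise distance,
   well below typical speech distances; the deliberate side effect is that
   very long uninterrupted speech slowly bleeds into the template, trading
   some extra speech attenuation for tracking robustness — in character for
   this aggressively noise-suppressing method.

5. **Directivity estimation.** On noise-only frames the per-bin powers of
   both channels accumulate in exponentially-forgetting averages
   (new = λ·old + (1−λ)·current, λ = 0.5 per accepted frame). Their ratio
   is the per-bin directivity coefficient; an energy-weighted median over
   300–5000 Hz gives the scalar cot⁴(φ/2) estimate, inverted to an azimuth
   by φ = 2·arctan(ratio^(−1/4)). The per-bin ratio is deployed once ≥ 25
   noise frames back it; before that the scalar form is the cold start. The
   default forgetting of 0.5 is deliberately fast: for a point interferer
   the per-frame ratio is essentially deterministic (the same source excites
   both channels), so averaging buys little variance reduction but costs
   tracking lag against walking-speed motion (cot⁴ changes ≈7 %/° near 90°).

   A moving interferer also needs tracking *through* the utterance, when
   whole frames are rarely noise-only. A motion detector watches the azimuth
   estimates of accepted noise frames (median drift >2° within 0.5 s ≈
   8 °/s); while motion is flagged, speech-labelled frames still update the
   ratio recursively, but only in bins the interferer dominates — those
   whose current powers are consistent with the tracked ratio
   (P1 ≤ 2·ratio·P2), i.e. where the subtraction would floor anyway. This
   is the recursive-averaging idea from minima-controlled noise estimation;
   its measured distortion cost is ~0.3 dB, and static interferers bypass it
   entirely (frozen ratio, no speech-absorption bias).

6. **Magnitude estimation.** Per frame and bin, the speech power is the
   floored difference P1 − ratio·P2 (negative values → 0), and the speech
   magnitude its square root. Powers enter unsmoothed (each frame's own
   periodogram): temporal smoothing mixes frames across azimuth changes and
   onsets and measurably degrades cancellation, so the running-average
   weight is 1.0 by default and configurable.

7. **Broadband compensation.** The differential front end attenuates a
   front source by 2·sin(2πf·d/c); the estimate is re-equalized by
   λ(f) = 1/(2 sin(2πf·d/c)). Two realizations: per-band constants — λ at
   the 16 CI filter-bank band centers (156–5498 Hz), transferred as the
   band "adjusting coefficients" (default) — or a 1st-order Butterworth
   band-pass (cutoffs 0.00045·fs, 0.0045·fs) followed by a fixed ×30
   (29.54 dB) gain. Out-of-band bins reuse the nearest band's coefficient
   because λ diverges toward DC. The standalone magnitude-estimator API also
   offers the exact per-bin division, with the denominator clamped at its
   100 Hz value and set to 1 above 6 kHz. Two of the sixteen published
   coefficients (channels 10 and 14) are inconsistent with λ at their own
   centers and look typographical; the default table recomputes all sixteen
   from λ and a `verbatim` switch reproduces the printed list.

8. **Reconstruction.** The compensated magnitude is combined with the phase
   of the channel-1 spectrum (a config switch selects raw-MIC1 phase
   instead; the cochlea is relatively phase-insensitive) and
   overlap-added. The whole pipeline is equivalent to a per-frame, per-bin
   real gain mask applied to CH1, which is recorded in the diagnostics.

9. **CIS sine vocoder.** The post-processing model of CI coding: 16
   zero-phase Butterworth band-passes at the table's bands, full-wave
   rectification plus a 2nd-order 400 Hz low-pass per band for the
   envelope, and one sine carrier per band at the band center. The cutoff
   and orders are standard CIS-simulation practice; the carrier stage has
   an identity compression map with a hook for loudness mapping.
   Zero-phase filtering is used because this stage is an offline simulation,
   not the implant DSP. Vocoding collapses within-band spectral detail, so
   enhancement artifacts (which live within bands) largely disappear after
   it — the motivation for pairing an aggressive enhancer with CI coding.

## Evaluation

**Shadow decomposition.** A magnitude-domain enhancer is nonlinear, so the
output SNR is measured by re-applying the recorded gain mask to the
speech-only and noise-only microphone pairs rendered through the same
front end. The mask is linear once fixed, so ŝ + n̂ equals the enhanced
output to numerical precision, and SNRout = 10·log10(Σŝ²/Σn̂²).

**ΔSNR.** Output minus input SNR, summed with per-band weights over the
16-band bank (uniform weights by default; any convex vector can be
supplied) and also reported broadband. The sums run over the whole session
by default: protocol sessions deliberately include ~3 s noise-only periods
before and after the utterance, and muting them is part of the delivered
improvement; a `region="speech"` option restricts the sums to the
speech-active interval for a lead-in-independent figure.

**Speech distortion index.** Over speech-active frames the per-bin
effective gain h = |Enhanced|/|Clean| is compared with unity, weighted by
the clean per-bin power: v_sd = Σλᵢ(1−hᵢ)²/Σλᵢ, reported as 10·log10(v_sd)
(floored at −60 dB; a uniform 0.5 gain gives −6.02 dB, total attenuation
0 dB). This spectral-power-weighted realization is this package's stated
interpretation of the filter-vector form; it is validated against its own
closed-form cases. Speech-active frames come from the simulator's ground
truth marks, decoupling the metric from detector errors.

## Synthetic scenes

The simulator replaces chamber recordings. It renders point sources at
configurable azimuths onto the microphone pair with a 129-tap
Kaiser-windowed-sinc fractional delay (far more accurate than the 5-tap
runtime filter under test), scales the interferer so the speech-active
region at MIC1 hits the requested input SNR, and stores clean per-source
references at both microphones for shadow evaluation. Moving sources are
rendered in ≤10 ms blocks of constant azimuth (at walking speed the
azimuth changes <0.4° per block). Sources:

- *speech-like*: harmonic complex of a 50–400 Hz fundamental up to
  5.5 kHz with 1/k roll-off, vibrato and a 2–8 Hz syllabic envelope;
- *babble*: five independent speech-like voices;
- *tonal music*: 0.4 s chord notes with percussive onsets (strongly
  non-stationary);
- *white*: flat-spectrum Gaussian noise.

Everything is seeded and bit-reproducible.

The standard protocol session is 3 s noise lead-in + 1 s utterance + 3 s
noise tail at 0 dB input SNR, the layout under which the method is meant
to operate (the noise-only intervals initialize and refresh the
directivity estimate). The azimuth-grid evaluation uses speech deviations
{0, 10, 20}° × noise azimuths {60, 90, 120, 150, 180}° with 3 seeds per
cell; the moving-noise evaluation sweeps 75°–105° triangularly at
38.2 °/s (1 m/s tangential at 1.5 m) with 5 seeds.

What the simulator does **not** model — room reverberation, microphone
self-noise and mismatch, source spectra of real loudspeakers, head
shadow — means passing tests demonstrate correctness of the algorithm
under its own assumptions, not field performance. Reverberation in
particular is known to reduce the improvement by a few dB.

## Numerical choices and degenerate inputs

- Log spectra are floored 100 dB below each frame's peak before the
  cepstrum; frames whose peak power is below 10⁻¹² of the session maximum
  are treated as silent (distance 0, template untouched) — this also makes
  the enhancer exactly transparent on scenes whose lead-in is digital
  silence rather than noise.
- The directivity ratio is regularized by 10⁻¹² of the session's peak
  channel-2 frame power, so numerically-silent accumulations yield ratio
  ≈ 0 (no subtraction) instead of garbage.
- Negative power differences floor at zero (standard spectral-subtraction
  flooring).
- Inputs at other sample rates are polyphase-resampled to the geometry's
  rate on ingest; all constants (1.297 samples, bin frequencies, λ) are
  derived from the geometry, never hard-coded.
- If a session is too short to contain the initialization frames, the
  pipeline warns and passes the λ-compensated channel-1 magnitude through
  unmodified.
- `snr_db` returns ±inf (not an exception) for zero-energy components.

## Known limitations

- One directional interferer is assumed; diffuse or multi-source noise
  violates the point-source ratio model and degrades gracefully toward
  plain spectral subtraction.
- The enhancer is offline (whole-session frame loop); a fixed-latency
  streaming variant would need a causal threshold calibration.
- Speech deviations beyond ~20° erode the front null and with it the
  subtraction's speech protection.
- The distortion index and band weights are this package's documented
  realizations where the underlying references do not pin them down; their
  absolute values should be compared within this package only.
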