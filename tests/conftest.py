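"""Shared fixtures: geometry and a couple of expensive rendered scenes."""

from __future__ import annotations

import numpy as np
import pytest

from cibeam import (
    ArrayGeometry,
    SourceSpec,
    enhance,
    simulate_scene,
    synth_noise,
    synth_speech_like,
)
from cibeam.beamform import MicPair


@pytest.fixture(scope="session")
def geom() -> ArrayGeometry:
    return ArrayGeometry()


def make_scene(
    geom: ArrayGeometry,
    noise_azimuth: float = 90.0,
    speech_azimuth: float = 0.0,
    kind: str = "babble",
    seed: int = 7,
    snr_db: float = 0.0,
    lead_in_s: float = 3.0,
    tail_s: float = 3.0,
    speech_s: float = 1.0,
    trajectory=None,
):
    speech = synth_speech_like(speech_s, 120.0 + 7 * (seed % 5), seed=seed)
    noise = synth_noise(lead_in_s + speech_s + tail_s + 0.2, kind, seed=seed + 1)
    return simulate_scene(
        speech,
        SourceSpec(azimuth_deg=speech_azimuth),
        noise,
        SourceSpec(azimuth_deg=noise_azimuth, trajectory=trajectory),
        geom=geom,
        snr_db=snr_db,
        lead_in_s=lead_in_s,
        tail_s=tail_s,
    )


@pytest.fixture(scope="session")
def babble_scene(geom):
    """0 dB babble interferer at 90 deg, 3 s noise lead-in and tail."""
    return make_scene(geom)


@pytest.fixture(scope="session")
def babble_enhanced(geom, babble_scene):
    out, diag = enhance(MicPair(babble_scene.mic1, babble_scene.mic2), geom=geom)
    return out, diag


@pytest.fixture(scope="session")
def clean_speech_session(geom):
    """Front speech only, silent elsewhere: the identity-check input."""
    speech = synth_speech_like(1.0, 120.0, seed=9)
    n = int(2.0 * geom.sample_rate_hz)
    onset = int(0.5 * geom.sample_rate_hz)
    s1 = np.zeros(n)
    s1[onset : onset + len(speech)] = speech.data
    from cibeam import AudioSignal, apply_azimuth_delay

    at1, at2 = apply_azimuth_delay(AudioSignal(s1), 0.0, geom)
    return at1, at2, onset, len(speech)
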