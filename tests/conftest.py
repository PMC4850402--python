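"""Shared fixtures: session-cached synthetic recordings.

Everything is generated programmatically from seeded presets, so the suite
needs no data files and every expected value traces back to a generator
parameter.
"""

from __future__ import annotations

import dataclasses

import pytest

from zfecg import preset, synth_recording
from zfecg.simulate import NoiseSpec, SimConfig


def quiet_noise() -> NoiseSpec:
    return NoiseSpec(powerline_amplitude=0.0, wander_amplitude=0.0, white_sd=0.0)


def make_recording(
    name: str,
    duration_s: float = 30.0,
    seed: int = 0,
    noiseless: bool = False,
    **overrides,
):
    cfg: SimConfig = preset(name)
    cfg.duration_s = duration_s
    cfg.seed = seed
    if noiseless:
        cfg.noise = quiet_noise()
        cfg.rhythm.rr_jitter_sd = 0.0
    for key, val in overrides.items():
        setattr(cfg, key, val)
    trace, truth = synth_recording(cfg)
    return cfg, trace, truth


@pytest.fixture(scope="session")
def wt_noiseless():
    """30 s noiseless, jitter-free wild-type dual-probe recording."""
    return make_recording("wildtype", noiseless=True)


@pytest.fixture(scope="session")
def wt_noisy():
    """30 s wild-type recording with the default noise model (SNR ~ 10)."""
    return make_recording("wildtype", seed=11)


@pytest.fixture(scope="session")
def bre_noisy():
    return make_recording("bre_longqt", seed=12)


@pytest.fixture(scope="session")
def avb_noisy():
    return make_recording("avb_2to1", seed=13)
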