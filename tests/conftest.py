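"""Shared fixtures: small synthetic atlases and phantoms, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import atlasforge as af


@pytest.fixture(scope="session")
def small_atlas():
    """64³ jagged atlas fixture with 8 regions (7 regular + 1 fragmented)."""
    params = af.AtlasFixtureParams(shape=(64, 64, 64), n_regions=8, seed=3, n_fragments=15)
    return af.make_synthetic_atlas(params)


@pytest.fixture(scope="session")
def small_atlas_clean():
    """64³ atlas with no degradation (degraded == true)."""
    params = af.AtlasFixtureParams(
        shape=(64, 64, 64), n_regions=8, seed=3, jitter=0, fragmented_label=False
    )
    return af.make_synthetic_atlas(params)


@pytest.fixture(scope="session")
def small_phantom():
    """96³ nuclei phantom, 80 nuclei, SNR 5."""
    params = af.NucleiFixtureParams(shape=(96, 96, 96), n_nuclei=80, seed=7)
    return af.make_synthetic_nuclei_volume(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
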