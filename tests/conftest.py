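"""Shared fixtures: landscapes and simulated panning datasets.

Two scales are used: a tiny dataset for fast unit tests, and a session-wide
"desk-scale" dataset (2e4 variants) on which the end-to-end statistical
properties are evaluated.
"""

import numpy as np
import pytest

from kbinding.binding_analysis import (
    call_binders,
    observed_universe,
    profile_variants,
)
from kbinding.synthetic_data import SimConfig, default_landscape, simulate_panning


@pytest.fixture(scope="session")
def landscape():
    return default_landscape()


@pytest.fixture(scope="session")
def tiny_panning(landscape):
    cfg = SimConfig(n_variants=2_000, depth=30_000, seed=5)
    return simulate_panning(landscape, cfg)


@pytest.fixture(scope="session")
def tiny_profiles(landscape, tiny_panning):
    binders = {t: call_binders(tiny_panning, t) for t in landscape.targets}
    return profile_variants(binders, observed_universe(tiny_panning), landscape.targets)


@pytest.fixture(scope="session")
def desk_panning(landscape):
    cfg = SimConfig(n_variants=20_000, depth=300_000, seed=11)
    return simulate_panning(landscape, cfg)


@pytest.fixture(scope="session")
def desk_profiles(landscape, desk_panning):
    binders = {t: call_binders(desk_panning, t) for t in landscape.targets}
    return profile_variants(binders, observed_universe(desk_panning), landscape.targets)
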