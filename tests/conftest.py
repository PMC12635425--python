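"""Shared fixtures: registries and small seeded synthetic datasets."""

import numpy as np
import pytest

from grscreen import (
    SimDesign,
    Stage,
    builtin_registry,
    simulate_organoid,
    simulate_screen,
)


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def noiseless_organoid(registry):
    return simulate_organoid(registry, seed=42, organoid_id="ORG-A")


@pytest.fixture(scope="session")
def noiseless_secondary(registry, noiseless_organoid):
    design = SimDesign(stage=Stage.SECONDARY, noise_cv=0.0)
    return simulate_screen(noiseless_organoid, design, registry, seed=7)


@pytest.fixture(scope="session")
def noiseless_preliminary(registry, noiseless_organoid):
    design = SimDesign(stage=Stage.PRELIMINARY, noise_cv=0.0)
    return simulate_screen(noiseless_organoid, design, registry, seed=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
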