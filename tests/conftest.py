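"""Shared fixtures: small synthetic fields and their rendered artifacts."""

import numpy as np
import pandas as pd
import pytest

import idcpheno as ip


@pytest.fixture(scope="session")
def small_config() -> ip.FieldSimConfig:
    """A compact field: 2 trials x 8 entries x 2 blocks = 32 plots."""
    return ip.FieldSimConfig(n_trials=2, entries_per_trial=8, seed=123)


@pytest.fixture(scope="session")
def small_field(small_config):
    """Rendered small field: (raster, polygons, truth, score simulation)."""
    return ip.simulate_field(small_config)


@pytest.fixture(scope="session")
def default_field():
    """Default-condition field (4 trials x 16 entries), used by several stages."""
    return ip.simulate_field(ip.FieldSimConfig(seed=7))


@pytest.fixture(scope="session")
def segmented_default(default_field):
    raster, polys, truth, sim = default_field
    mask, index, model = ip.segment_canopy(raster, seed=7)
    return mask, index, model


@pytest.fixture(scope="session")
def classified_default(default_field, segmented_default):
    raster, polys, truth, sim = default_field
    mask, _, _ = segmented_default
    colors, model = ip.classify_canopy_colors(raster, mask, seed=7)
    return colors, model
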