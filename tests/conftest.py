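"""Shared synthetic fixtures, generated programmatically at session scope."""

from __future__ import annotations

import numpy as np
import pytest

from wildmeat import synthetic as syn


@pytest.fixture(scope="session")
def landscape():
    """24x24 synthetic landscape, fixed seed."""
    return syn.generate_landscape(syn.LandscapeConfig(n_rows=24, n_cols=24, seed=1))


@pytest.fixture(scope="session")
def taxa_bundle(landscape):
    """(profiles, range masks, mass observation table) for 8 taxa."""
    return syn.generate_taxa(8, landscape.shape, landscape.boundary_mask, seed=2)


@pytest.fixture(scope="session")
def communities(landscape):
    return syn.generate_communities(landscape, 60, true_hunter_ratio=0.178, seed=3)


@pytest.fixture(scope="session")
def ground_truth(landscape, taxa_bundle):
    profiles, ranges, _ = taxa_bundle
    return syn.build_ground_truth(landscape, profiles, ranges, seed=4)


@pytest.fixture(scope="session")
def hunting_data(communities, ground_truth):
    """(records, efforts) simulated on the session landscape."""
    return syn.generate_hunting_records(communities, ground_truth, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
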