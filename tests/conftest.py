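"""Shared fixtures: session-scoped synthetic panels with known truths."""

import numpy as np
import pytest

from infodbn import make_ground_truth, simulate_panel, with_variance_fractions

# fixed fixture seeds, unrelated to any test assertion
GT_SEED = 20603
PANEL_SEED = 977


@pytest.fixture(scope="session")
def default_gt():
    """p=12 truth with 8 feedback pairs and 10 one-way arcs (pure VAR)."""
    return make_ground_truth(12, 8, 10, seed=GT_SEED)


@pytest.fixture(scope="session")
def spatial_gt(default_gt):
    """The same truth with state/county baselines at ~12%/49% of variance."""
    return with_variance_fractions(default_gt)


@pytest.fixture(scope="session")
def default_panel(default_gt):
    """Desk-scale analogue of the real panel: 10 states x 20 counties x 100 weeks."""
    return simulate_panel(default_gt, 10, 20, 100, seed=PANEL_SEED)


@pytest.fixture(scope="session")
def spatial_panel(spatial_gt):
    """Spatially structured default panel (baselines + VAR dynamics)."""
    return simulate_panel(spatial_gt, 10, 20, 100, seed=PANEL_SEED)


@pytest.fixture(scope="session")
def small_gt():
    """p=4 truth used where a small, fast system suffices."""
    return make_ground_truth(4, 1, 2, seed=GT_SEED + 1)


@pytest.fixture(scope="session")
def small_panel(small_gt):
    return simulate_panel(small_gt, 2, 3, 80, seed=PANEL_SEED + 1)
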