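import numpy as np
import pytest
from hypothesis import settings

import stressmap as sm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


SMALL_CFG = dict(
    donor_count=6,
    gene_count=400,
    in_samples=36,
    out_samples=240,
    volume_shape=(20, 20, 20),
    receptor_universe_size=120,
    neuropeptide_size=40,
    gene_set_size=40,
    sc_clusters_per_class=4,
    sc_cells_per_cluster=20,
)


@pytest.fixture(scope="session")
def small_planted():
    """Small planted atlas (delta=1.2, 10% planted) with mask and membership."""
    cfg = sm.SimConfig(**SMALL_CFG, effect_size=1.2, planted_fraction=0.1, seed=7)
    donors, samples, truth = sm.generate_atlas(cfg)
    mask = sm.generate_mask(cfg)
    membership = sm.assign_membership(samples, mask)
    return cfg, donors, samples, truth, mask, membership


@pytest.fixture(scope="session")
def small_null():
    """Small null atlas (no planted effects)."""
    cfg = sm.SimConfig(**SMALL_CFG, effect_size=0.0, planted_fraction=0.1, seed=11)
    donors, samples, truth = sm.generate_atlas(cfg)
    mask = sm.generate_mask(cfg)
    membership = sm.assign_membership(samples, mask)
    return cfg, donors, samples, truth, mask, membership


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
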