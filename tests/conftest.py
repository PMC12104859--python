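import numpy as np
import pandas as pd
import pytest

from harvestmeta.data_model import Dataset
from harvestmeta.synthetic import SyntheticConfig, generate_dataset


def make_obs_frame(rows):
    """Build a raw observation frame from compact tuples."""
    cols = [
        "study_id", "unit_id", "pool", "treatment", "biome", "reference_type",
        "time_since_treatment", "mean_treatment", "mean_control",
        "se_treatment", "se_control", "n_treatment", "n_control", "sampling_depth",
    ]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def tiny_frame():
    return make_obs_frame(
        [
            ("S1", "u1", "live_trees", "clearcut", "boreal", "old_forest",
             10.0, 20.0, 80.0, 2.0, 4.0, 5, 5, None),
            ("S1", "u2", "forest_floor", "clearcut", "boreal", "old_forest",
             10.0, 25.0, 30.0, None, None, None, None, None),
            ("S2", "u1", "mineral_soil", "partial", "temperate", "unmanaged_80plus",
             25.0, 60.0, 55.0, 6.0, 5.0, 4, 4, 45.0),
        ]
    )


@pytest.fixture
def tiny_dataset(tiny_frame):
    return Dataset(df=tiny_frame, provenance="fixture")


def one_stratum_config(theta, tau=0.0, cv=0.0, n_studies=20, seed=0, **kw):
    """Single-pool, single-treatment, single-biome generator config."""
    defaults = dict(
        n_studies=n_studies,
        obs_per_study=(2, 4),
        true_effects={("live_trees", "clearcut", "boreal"): theta},
        time_model={},
        tau=tau,
        cv_within=cv,
        missing_variance_rate=0.0,
        pool_shares={"live_trees": 1.0},
        biome_shares={"boreal": 1.0, "temperate": 0.0},
        partial_share_by_biome={"boreal": 0.0},
        control_mean_range={"live_trees": (50.0, 120.0)},
        inventory_study_rate=0.0,
        zero_mean_before=0.0,
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


@pytest.fixture
def synth_small():
    cfg = one_stratum_config(theta=-0.5, tau=0.15, cv=0.25, n_studies=25, seed=3)
    ds, truth = generate_dataset(cfg)
    return ds, truth
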