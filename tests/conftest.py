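import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import painmap as pm

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """Separable two-group count table (5 animals/group, 10 regions)."""
    data, truth = pm.gen_region_counts(
        pm.RegionCountSpec(
            n_per_group=5,
            region_names=[f"R{i:02d}" for i in range(10)],
            baseline_mean=100.0,
            dispersion=20.0,
            effect_regions=[0, 1],
            effect_log_fold=1.5,
            seed=42,
        )
    )
    return data, truth


@pytest.fixture
def simple_ethogram():
    """Hand-built 4-bout ethogram: A(6 min), B(4 min) alternating."""
    bouts = pd.DataFrame(
        {
            "label": ["A", "B", "A", "B"],
            "start_s": [0.0, 180.0, 360.0, 540.0],
            "end_s": [180.0, 360.0, 540.0, 600.0],
        }
    )
    return pm.Ethogram(bouts=bouts, label_set=("A", "B"), animal_id="m1", group="CON")
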