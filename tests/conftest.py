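import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nachr_hts as nh

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def layout():
    return nh.default_layout()


@pytest.fixture(scope="session")
def small_screen():
    """A small seeded duplicate-run screen (one plate's worth of compounds)."""
    manifest = nh.make_manifest(204)
    truth, groups = nh.default_truth_library(
        manifest, seed=7,
        group_plan={"A3B4_ONLY": 3, "ALL_THREE": 2, "NOT_VALIDATED": 2})
    noise = nh.NoiseModel(seed=7)
    reads, layouts, gt = nh.generate_screen(
        manifest, truth, nh.DEFAULT_CONTEXTS["A4B2"], noise, n_runs=2)
    return {"manifest": manifest, "truth": truth, "groups": groups,
            "reads": reads, "layouts": layouts, "gt": gt, "noise": noise}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
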