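import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from dfcstates import (RegimeSwitchingSpec, TimeCoursePanel, build_taper,
                       simulate_cohort, windowed_connectivity)


@pytest.fixture(scope="session")
def small_spec():
    """Small, strongly separated regime-switching cohort for fast tests."""
    return RegimeSwitchingSpec(n_components=12, n_blocks=4, K=3, T=160,
                               n_per_group=4, noise_sd=0.3, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_dfc(small_cohort):
    taper = build_taper(22, 3.0)
    return {sid: windowed_connectivity(panel, taper)
            for sid, panel in small_cohort["panels"].items()}


def make_panel(data, tr=2.0, subject_id="sub-001"):
    data = np.asarray(data, dtype=float)
    C = data.shape[1]
    return TimeCoursePanel(data=data, tr_seconds=tr,
                           component_ids=[f"ic{i + 1:02d}" for i in range(C)],
                           subnetwork_labels=["net"] * C,
                           subject_id=subject_id)
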