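import numpy as np
import pytest

from stancelab.pipeline import RunConfig
from stancelab.synthgait import (CohortConfig, EffectCell, default_effect_table,
                                 generate_cohort)


def zero_noise_config(n=(2, 2), seed=1) -> CohortConfig:
    """All cell sds and measurement noise zero: planted values = cell means."""
    table = {k: EffectCell(c.ig_pre, c.ig_post, c.cg_pre, c.cg_post, 0.0)
             for k, c in default_effect_table().items()}
    return CohortConfig(n_per_group=n, seed=seed, effect_table=table,
                        noise_sd_marker=0.0, trajectory_noise_sd_deg=0.0)


def exact_run_config(cohort_cfg) -> RunConfig:
    """Pipeline settings for the analytic-recovery oracle: filters disabled
    (a dual-pass filter is not the identity on sampled signals) and the pure
    crossing rule for events."""
    return RunConfig(cohort=cohort_cfg, filter_kin_hz=None, filter_grf_hz=None,
                     min_stance_s=0.0, min_flight_s=0.0)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    cfg = zero_noise_config()
    return generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small cohort under the default (noisy) study conditions."""
    cfg = CohortConfig(n_per_group=(8, 8), seed=11)
    return generate_cohort(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
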