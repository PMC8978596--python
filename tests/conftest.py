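import numpy as np
import pytest

from evprofiler.manifest import default_manifest
from evprofiler.synthetic import (CohortSpec, EffectSpec, EventModel,
                                  SubjectVisitParams, generate_cohort,
                                  generate_event_sample)

CHANNELS = ("CD63", "VAMP3", "THSD1")


def neutral_params(p_sat: float = 0.02) -> SubjectVisitParams:
    zero = {ch: 0.0 for ch in CHANNELS}
    return SubjectVisitParams(
        log_intensity_offset=dict(zero), log_bdi_offset=dict(zero),
        ssc_offset=0.0, ssc_min_scale_mult=1.0,
        bdi_sigma_factor={ch: 1.0 for ch in CHANNELS},
        ssc_min_shift=0.0, p_sat=p_sat)


@pytest.fixture(scope="session")
def fm():
    return default_manifest()


@pytest.fixture(scope="session")
def event_table():
    """A 1000-event synthetic sample (fixed seed)."""
    rng = np.random.default_rng(11)
    return generate_event_sample(neutral_params(), 1000, rng)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced-size cohort (5+5 subjects, few hundred events) with the
    default implanted effects, for pipeline-level tests."""
    spec = CohortSpec(n_high=5, n_low=5, events_min=300, events_max=600)
    return generate_cohort(spec, seed=5)
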