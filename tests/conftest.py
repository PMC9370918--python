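import dataclasses

import numpy as np
import pytest

from liftkin import (
    PipelineConfig,
    SyntheticSessionSpec,
    generate_cohort,
    generate_session,
    process_session,
    run_cohort,
)


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic session (1 mm marker noise), with truth."""
    return generate_session(SyntheticSessionSpec(seed=7))


@pytest.fixture(scope="session")
def noise_free_session():
    spec = dataclasses.replace(SyntheticSessionSpec(seed=7), marker_noise_sd_m=0.0)
    return generate_session(spec)


@pytest.fixture(scope="session")
def processed_default(default_session):
    ts, _ = default_session
    return process_session(ts)


@pytest.fixture(scope="session")
def processed_noise_free(noise_free_session):
    ts, _ = noise_free_session
    return process_session(ts)


@pytest.fixture(scope="session")
def cohort_session1():
    """9-participant session-1 cohort, processed end to end (t6/t7 design)."""
    recs = generate_cohort(SyntheticSessionSpec(seed=11), 9, (1,), {}, seed=11)
    event_table, profile_table, aggregated, _ = run_cohort(recs, PipelineConfig())
    return event_table, profile_table, aggregated


def ground_truth_palletization(gt):
    """Ground-level palletization-half truth rows, time-ordered."""
    ev = gt.events
    return ev[(ev.ground) & (ev.half == "palletization")].reset_index(drop=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
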