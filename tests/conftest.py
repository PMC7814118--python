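import numpy as np
import pytest

import mbscore as m


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-patient cohort with the five-gene reference signature active."""
    cohort, truth = m.simulate_cohort(m.SimulationConfig(n_patients=200, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def reference_model(small_cohort):
    """Score model built from the generator's true cutpoints."""
    _, truth = small_cohort
    comps = tuple(
        m.MBSComponent(gene=g, cutpoint=c, direction=d)
        for g, (c, d) in truth.cutpoint_map().items()
    )
    return m.MBSModel(components=comps)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)


def random_survival(rng, n, censor_scale=40.0):
    """Generic random right-censored survival data."""
    t = rng.exponential(20.0, n)
    c = rng.exponential(censor_scale, n)
    times = np.minimum(t, c) + 1e-9
    events = (t <= c).astype(int)
    return times, events
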