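import pytest

import rhythmostat as r


@pytest.fixture(scope="session")
def age_groups():
    """Packaged per-age parameter sets (the eight calibrated columns)."""
    return r.age_group_params()


@pytest.fixture(scope="session")
def flat_circadian():
    """Circadian process with zero amplitude: the plain homeostatic relay."""
    return r.CircadianParams(amplitude=0.0)


@pytest.fixture(scope="session")
def adult_homeostat():
    """The 18+ homeostat column, convenient for closed-form checks."""
    return r.HomeostatParams(
        lower_asymptote=0.70,
        wake_threshold=0.755,
        sleep_threshold=2.75,
        upper_asymptote=5.00,
        decay_constant=2.40,
        buildup_constant=27.81,
    )


@pytest.fixture(scope="session")
def simulated_weeks(age_groups):
    """Simulated school-week protocols for all eight groups (reused)."""
    out = {}
    for g, p in age_groups.items():
        out[g] = r.simulate_schedule(p.circadian, p.homeostat, schedule=p.schedule)
    return out
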