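import numpy as np
import pandas as pd
import pytest

from mobrisk.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """10 participants x 8 weeks with defaults otherwise; shared read-only."""
    return simulate_cohort(SimConfig(n_participants=10, n_weeks=8, seed=3))


@pytest.fixture(scope="session")
def clean_cohort():
    """No jitter, no missing days: generative truth is exactly recoverable."""
    return simulate_cohort(
        SimConfig(
            n_participants=4,
            n_weeks=4,
            seed=5,
            gps_jitter_m=0.0,
            gps_day_missing_prob=0.0,
        )
    )


@pytest.fixture(scope="session")
def small_daily(small_cohort):
    from mobrisk.features import compute_daily_features

    daily, homes = compute_daily_features(small_cohort.gps)
    return daily, homes


def make_fixes(times_s, lats, lons, pid="p1", day="2022-03-02"):
    """Hand-built fix stream for micro-fixtures (times in seconds of day)."""
    base = pd.Timestamp(day)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "t": [base + pd.Timedelta(seconds=float(s)) for s in times_s],
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
        }
    )
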