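from datetime import datetime

import pandas as pd
import pytest

from cagetrack import SessionConfig
from cagetrack.simulate import SimParams, simulate_cohort


@pytest.fixture
def session_8am() -> SessionConfig:
    """A 72-h session starting at lights-on 08:00."""
    return SessionConfig(session_start=datetime(2023, 1, 10, 8, 0, 0))


@pytest.fixture
def short_session() -> SessionConfig:
    """A 4-h session starting at lights-on (two 2-h bins, all light)."""
    return SessionConfig(session_start=datetime(2023, 1, 10, 8, 0, 0), session_hours=4.0)


def make_traj(rows):
    """Build a trajectory table from (tag, second, x, y[, observed]) tuples."""
    recs = []
    for r in rows:
        tag, second, x, y = r[:4]
        observed = r[4] if len(r) > 4 else True
        recs.append(
            {
                "tag_id": tag,
                "second": second,
                "antenna_id": (y - 1) * 12 + x,
                "x": x,
                "y": y,
                "observed": observed,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-h, 4-mouse clean cohort (no sensor noise), shared across tests."""
    params = SimParams(
        n_mice=4, hours=2.0, p_miss=0.0, p_dup=0.0, p_social=0.4, seed=11
    )
    return simulate_cohort(params)
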