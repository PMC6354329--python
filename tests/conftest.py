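import numpy as np
import pandas as pd
import pytest


_CLAIM_COLS = ["beneficiary_id", "service_start", "service_end", "setting", "dx_codes", "principal_dx", "charge"]


def make_claims(rows):
    """Build a claims frame from terse row dicts (dates as strings)."""
    if not rows:
        df = pd.DataFrame(columns=_CLAIM_COLS)
        df["service_start"] = pd.to_datetime(df["service_start"])
        df["service_end"] = pd.to_datetime(df["service_end"])
        return df
    defaults = {"setting": "OP", "charge": 100.0}
    full = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        d.setdefault("service_end", d["service_start"])
        d.setdefault("principal_dx", str(d["dx_codes"]).split(";")[0])
        full.append(d)
    df = pd.DataFrame(full)
    df["service_start"] = pd.to_datetime(df["service_start"])
    df["service_end"] = pd.to_datetime(df["service_end"])
    return df[["beneficiary_id", "service_start", "service_end", "setting", "dx_codes", "principal_dx", "charge"]]


def make_roster(ids, birth="1940-06-15"):
    n = len(ids)
    return pd.DataFrame(
        {
            "beneficiary_id": list(ids),
            "birth_date": pd.to_datetime([birth] * n),
            "sex": ["F"] * n,
            "race_code": [1] * n,
            "medicare_status_code": ["10"] * n,
            "dual_status_code": ["08"] * n,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_survival_sample(rng, n_max=30, allow_all_censored=False):
    """Small random right-censored sample for oracle comparisons."""
    n = int(rng.integers(3, n_max + 1))
    times = rng.integers(1, 15, size=n).astype(float)
    events = (rng.random(n) < 0.7).astype(int)
    if not allow_all_censored and events.sum() == 0:
        events[int(rng.integers(0, n))] = 1
    return times, events
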