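import numpy as np
import pandas as pd
import pytest

from tkisim.pbpk import DoseRegimen, default_drug, human_physiology


@pytest.fixture(scope="session")
def human():
    return human_physiology()


@pytest.fixture(scope="session")
def gefitinib():
    return default_drug("gefitinib")


@pytest.fixture(scope="session")
def daily_250mg():
    return DoseRegimen(amount=250.0, interval=24.0, n_doses=3)


@pytest.fixture
def toy_event_table():
    """Six-subject two-group table with one censoring, for hand-checked tests."""
    return pd.DataFrame({
        "time": [1.0, 2.0, 3.0, 1.5, 2.5, 4.0],
        "event": [1, 1, 0, 1, 1, 1],
        "group": ["a", "a", "a", "b", "b", "b"],
    })


def brute_force_km(times, events):
    """Independent product-limit oracle: direct evaluation of the formula."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    event_times = np.unique(times[events])
    surv = []
    s = 1.0
    for t in event_times:
        n = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1.0 - d / n
        surv.append(s)
    return event_times, np.array(surv)


def brute_force_logrank_score(times, events, group1):
    """Independent standard log-rank score U (observed minus expected)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group1 = np.asarray(group1, dtype=bool)
    u = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group1).sum()
        d = ((times == t) & events).sum()
        d1 = ((times == t) & events & group1).sum()
        u += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return u, var
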