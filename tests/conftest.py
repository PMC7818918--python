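"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's interval arithmetic: coverage
is checked by day-by-day stock simulation, Kaplan-Meier by hand product
over risk sets, and the log-rank statistic by risk-set enumeration.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from dropcover.claims_model import DrugDictionary, PharmacyClaim

#: anchor date for day-offset test fixtures
D0 = date(2012, 6, 1)


def day(offset: int) -> date:
    return D0 + timedelta(days=int(offset))


def claim(pid: str, offset: int, name: str, bottles: float = 1, dictionary=None) -> PharmacyClaim:
    """A claim at D0 + offset for the given number of bottles."""
    dictionary = dictionary or DrugDictionary.default()
    unit = dictionary.resolve(name).unit_bottle_volume
    return PharmacyClaim(pid, day(offset), name, bottles * unit, int(bottles))


@pytest.fixture(scope="session")
def dictionary() -> DrugDictionary:
    return DrugDictionary.default()


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def stock_covered_days(dispensings, lo: int, hi: int) -> set[int]:
    """Covered days in [lo, hi) by day-by-day supply-stock simulation.

    Each dispensing adds ``days_supplied`` bottle-days of stock on its day;
    one day of stock is consumed per covered day.  This realizes the
    carry-forward (stockpiling) semantics without interval arithmetic.
    """
    if not dispensings:
        return set()
    events: dict[int, int] = {}
    for t, d in dispensings:
        events[t] = events.get(t, 0) + d
    covered = set()
    stock = 0
    for t in range(min(events), hi):
        stock += events.get(t, 0)
        if stock > 0:
            if t >= lo:
                covered.add(t)
            stock -= 1
    return covered


def km_hand(durations, events):
    """Product-limit survival by direct hand computation.

    Returns (event_times, survival values) multiplying (1 - d_i/n_i) over
    distinct event times.
    """
    pairs = sorted(zip(durations, events))
    times = sorted({t for t, e in pairs if e})
    surv = []
    s = 1.0
    for t in times:
        n_at_risk = sum(1 for d, _ in pairs if d >= t)
        d_events = sum(1 for d, e in pairs if d == t and e)
        s *= 1.0 - d_events / n_at_risk
        surv.append(s)
    return times, surv


def logrank_hand(dur_a, ev_a, dur_b, ev_b):
    """Two-group log-rank chi-square by enumeration over risk sets."""
    times = sorted({t for t, e in list(zip(dur_a, ev_a)) + list(zip(dur_b, ev_b)) if e})
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n_a = sum(1 for d in dur_a if d >= t)
        n_b = sum(1 for d in dur_b if d >= t)
        d_a = sum(1 for d, e in zip(dur_a, ev_a) if d == t and e)
        d_b = sum(1 for d, e in zip(dur_b, ev_b) if d == t and e)
        n, d = n_a + n_b, d_a + d_b
        if n < 1:
            continue
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def chi2_2x2_hand(a, b, c, d):
    """Closed-form Pearson chi-square for a 2x2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
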