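"""Shared fixtures: hand-built cohorts and random person-time tables."""

from __future__ import annotations

import numpy as np
import pytest

from riskband import CarrierRecord, PersonTimeTable
from riskband.records import BAND_STARTS, N_BANDS

#: Cumulative-incidence targets (fractions) used to calibrate the simulator:
#: the published prospective male MLH1 all-regions values at decade ages.
MALE_MLH1_TARGETS = {25: 0.0, 30: 0.035, 40: 0.148, 50: 0.321, 60: 0.451, 70: 0.519}


def make_record(**overrides) -> CarrierRecord:
    """A valid default record, overridable per test."""
    defaults = dict(
        carrier_id="c1",
        gene="MLH1",
        sex="male",
        region="Europe",
        entry_age=30.0,
        exit_age=42.0,
        exit_reason="last_observation",
        prior_crc=False,
    )
    defaults.update(overrides)
    return CarrierRecord(**defaults)


@pytest.fixture
def hand_cohort() -> list[CarrierRecord]:
    """Two carriers whose exposure is tabulated by hand in the tests.

    Carrier A: window (30, 42), censored -> 5 y in [30,35), 5 y in [35,40),
    2 y in [40,45).  Carrier B: window (33.5, 36.5), event -> 1.5 y in
    [30,35), 1.5 y in [35,40), event in [35,40).
    """
    return [
        make_record(carrier_id="A", entry_age=30.0, exit_age=42.0),
        make_record(
            carrier_id="B", entry_age=33.5, exit_age=36.5, exit_reason="crc_event"
        ),
    ]


#: Pooled hand tabulation of ``hand_cohort``: person-years and events per band.
HAND_PERSON_YEARS = (0.0, 6.5, 6.5, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0)
HAND_EVENTS = (0, 0, 1, 0, 0, 0, 0, 0, 0)


@pytest.fixture
def hand_table() -> PersonTimeTable:
    return PersonTimeTable(
        gene="MLH1",
        sex="male",
        region="All",
        events=HAND_EVENTS,
        person_years=HAND_PERSON_YEARS,
    )


def random_table(rng: np.random.Generator, max_at_risk: int = 200) -> PersonTimeTable:
    """Random integer-at-risk band table (person-years are multiples of 5)."""
    at_risk = rng.integers(5, max_at_risk, size=N_BANDS)
    events = np.minimum(rng.poisson(5, size=N_BANDS), at_risk)
    return PersonTimeTable(
        gene="MLH1",
        sex="male",
        region="All",
        events=tuple(int(d) for d in events),
        person_years=tuple(float(y * 5) for y in at_risk),
    )


def lifelines_cumhaz(table: PersonTimeTable) -> dict[int, float]:
    """Independent cumulative-hazard oracle via a weighted, left-truncated
    Nelson-Aalen fit on pseudo individual data reproducing the band counts.

    Each band contributes one event pseudo-subject (weight = events, at the
    band midpoint) and one censored pseudo-subject (weight = remaining
    at-risk, spanning the band), with entries at the band start; the at-risk
    weight during band j is then person_years[j] / 5 and the classic
    Nelson-Aalen increments equal the band rates times the band width.
    """
    from lifelines import NelsonAalenFitter

    durations, observed, entries, weights = [], [], [], []
    for j, b in enumerate(BAND_STARTS):
        at_risk = table.person_years[j] / 5.0
        d = table.events[j]
        if d > 0:
            durations.append(b + 2.5)
            observed.append(1)
            entries.append(float(b))
            weights.append(int(d))
        if at_risk - d > 0:
            durations.append(b + 5.0)
            observed.append(0)
            entries.append(float(b))
            weights.append(int(at_risk - d))
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(
        durations=np.array(durations),
        event_observed=np.array(observed),
        entry=np.array(entries),
        weights=np.array(weights),
    )
    ch = naf.cumulative_hazard_
    out = {}
    for age in range(30, 75, 5):
        sub = ch[ch.index <= age]
        out[age] = float(sub.iloc[-1, 0]) if len(sub) else 0.0
    return out


def zero_table() -> PersonTimeTable:
    return PersonTimeTable(
        gene="MLH1",
        sex="male",
        region="All",
        events=(0,) * N_BANDS,
        person_years=(100.0,) * N_BANDS,
    )
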