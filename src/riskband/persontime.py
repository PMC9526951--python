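"""Reduce carrier records to band-stratified events and person-years.

Accounting rules:

* prevalent cases (``prior_crc``) are excluded entirely;
* follow-up starts at the later of the entry age and 25, and ends at the
  earlier of the exit age and 70 (the administrative cap);
* an event at an exit age exactly equal to the entry age is prevalent and the
  carrier contributes nothing;
* the observation window is cut into half-open five-year bands; a counted
  event is assigned to the band in which the final moment of exposure lies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .records import (
    AGE_MAX,
    AGE_MIN,
    BAND_STARTS,
    BAND_WIDTH,
    N_BANDS,
    AgeBand,
    CarrierRecord,
    PersonTimeTable,
)

logger = logging.getLogger(__name__)

DEFAULT_GROUP_BY = ("gene", "sex")


@dataclass(frozen=True)
class ExposureSegment:
    """Exposure contributed by one carrier within one band."""

    band: AgeBand
    years: float
    event_here: bool

    def __post_init__(self) -> None:
        if not 0 <= self.years <= BAND_WIDTH:
            raise ValueError(f"segment years {self.years} outside [0, {BAND_WIDTH}]")


def effective_window(
    record: CarrierRecord,
) -> Optional[tuple[float, float, bool]]:
    """Observation window ``(start_age, stop_age, counts_event)`` or ``None``.

    ``None`` means the carrier contributes nothing: a prevalent case, or a
    window of zero length after left truncation at 25 and capping at 70.
    The event is counted only if the exit reason is an incident event and the
    exit occurred at or before the cap.
    """
    if record.prior_crc:
        return None
    start = max(record.entry_age, AGE_MIN)
    stop = min(record.exit_age, AGE_MAX)
    if stop <= start:
        return None
    counts_event = record.exit_reason == "crc_event" and record.exit_age <= AGE_MAX
    return (start, stop, counts_event)


def _event_band_index(stop_age: float) -> int:
    """Band receiving an event at ``stop_age``.

    An exit exactly on a band boundary goes to the lower band, so the event
    stays inside the observed exposure (stop_age = 70 lands in [65, 70)).
    """
    idx = int((stop_age - AGE_MIN) // BAND_WIDTH)
    if stop_age > AGE_MIN and (stop_age - AGE_MIN) % BAND_WIDTH == 0:
        idx -= 1
    return idx


def segment_exposure(
    start_age: float, stop_age: float, counts_event: bool
) -> list[ExposureSegment]:
    """Split a window into per-band exposure segments.

    Returns only segments with positive exposure; the total years across
    segments equal ``stop_age - start_age`` exactly.
    """
    if not (AGE_MIN <= start_age <= stop_age <= AGE_MAX):
        raise ValueError(
            f"window ({start_age}, {stop_age}) outside [{AGE_MIN}, {AGE_MAX}]"
        )
    if stop_age == start_age:
        return []
    event_idx = _event_band_index(stop_age) if counts_event else -1
    segments = []
    for j, b in enumerate(BAND_STARTS):
        years = min(stop_age, b + BAND_WIDTH) - max(start_age, b)
        if years > 0:
            segments.append(
                ExposureSegment(
                    band=AgeBand(b, b + BAND_WIDTH),
                    years=years,
                    event_here=(j == event_idx),
                )
            )
    return segments


def _stratum_key(record: CarrierRecord, group_by: Sequence[str]) -> tuple[str, str, str]:
    return (
        record.gene if "gene" in group_by else "All",
        record.sex if "sex" in group_by else "All",
        record.region if "region" in group_by else "All",
    )


def tabulate(
    cohort: Iterable[CarrierRecord],
    group_by: Sequence[str] = DEFAULT_GROUP_BY,
) -> list[PersonTimeTable]:
    """Sum events and person-years per band for each requested stratum.

    ``group_by`` names the stratification dimensions to keep (any subset of
    ``gene``, ``sex``, ``region``); pooled dimensions are labelled ``"All"``.
    Carriers excluded by :func:`effective_window` contribute nothing.
    """
    unknown = [g for g in group_by if g not in ("gene", "sex", "region")]
    if unknown:
        raise ValueError(f"unknown group_by dimension(s) {unknown}")
    acc: dict[tuple[str, str, str], tuple[list[int], list[float]]] = {}
    order: list[tuple[str, str, str]] = []
    n_excluded = 0
    n_records = 0
    for record in cohort:
        n_records += 1
        key = _stratum_key(record, group_by)
        if key not in acc:
            acc[key] = ([0] * N_BANDS, [0.0] * N_BANDS)
            order.append(key)
        window = effective_window(record)
        if window is None:
            n_excluded += 1
            continue
        events, years = acc[key]
        for seg in segment_exposure(*window):
            j = BAND_STARTS.index(seg.band.start)
            years[j] += seg.years
            if seg.event_here:
                events[j] += 1
    if n_records == 0:
        logger.warning("tabulate: empty cohort, no tables produced")
    if n_excluded:
        logger.info(
            "tabulate: %d of %d carriers excluded (prevalent or empty window)",
            n_excluded,
            n_records,
        )
    return [
        PersonTimeTable(
            gene=key[0],
            sex=key[1],
            region=key[2],
            events=tuple(acc[key][0]),
            person_years=tuple(acc[key][1]),
        )
        for key in order
    ]


def mean_followup(total_person_years: float, n_included: int) -> Optional[float]:
    """Mean follow-up in years, rounded half-up to one decimal for reporting."""
    if n_included <= 0:
        return None
    mean = total_person_years / n_included
    # round-half-up at one decimal (display convention)
    return int(mean * 10 + 0.5) / 10


@dataclass(frozen=True)
class CohortSummary:
    n_included: int
    total_person_years: float
    mean_followup: Optional[float]
    n_events: int


def summarize_cohort(cohort: Iterable[CarrierRecord]) -> CohortSummary:
    """Headline totals: included carriers, person-years, mean follow-up, events.

    Only carriers with positive person-time count towards ``n_included``.
    """
    n_included = 0
    total = 0.0
    n_events = 0
    for record in cohort:
        window = effective_window(record)
        if window is None:
            continue
        start, stop, counts_event = window
        n_included += 1
        total += stop - start
        if counts_event:
            n_events += 1
    return CohortSummary(
        n_included=n_included,
        total_person_years=total,
        mean_followup=mean_followup(total, n_included),
        n_events=n_events,
    )
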