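"""Domain types, validation, and CSV readers/writers for carrier cohorts.

The central object is :class:`CarrierRecord`, one prospectively followed
mutation carrier with an entry age (first surveillance examination), an exit
age, and an exit reason.  Downstream modules reduce cohorts of records to
:class:`PersonTimeTable` objects — events and person-years on a fixed grid of
nine five-year age bands spanning [25, 70) — which are the sufficient
statistics for all incidence estimation in this package.

All files are plain UTF-8 CSV with a dot decimal separator.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
SEXES = ("male", "female")
EXIT_REASONS = ("crc_event", "death", "last_observation")

#: Follow-up accounting starts at this age; earlier exposure is discarded.
AGE_MIN = 25.0
#: Administrative cap: exposure and events past the 70th birthday are discarded.
AGE_MAX = 70.0
BAND_WIDTH = 5
BAND_STARTS = tuple(range(25, 70, 5))  # 9 bands: [25,30), ..., [65,70)
N_BANDS = len(BAND_STARTS)
#: Ages at which cumulative incidence is reported.
REPORT_AGES = tuple(range(25, 75, 5))

COHORT_COLUMNS = (
    "carrier_id",
    "gene",
    "sex",
    "region",
    "entry_age",
    "exit_age",
    "exit_reason",
    "prior_crc",
)

_TRUE_TOKENS = {"true", "1", "yes", "y", "t"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f"}


class SchemaError(ValueError):
    """The file as a whole cannot be interpreted (missing column, bad header)."""


class RowError(ValueError):
    """A single row violates the record contract."""


@dataclass(frozen=True)
class AgeBand:
    """Half-open five-year age interval [start, end) on the fixed grid."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != BAND_WIDTH:
            raise ValueError(f"band must span {BAND_WIDTH} years: [{self.start}, {self.end})")
        if self.start not in BAND_STARTS:
            raise ValueError(f"band start {self.start} not on the grid {BAND_STARTS}")

    def contains(self, age: float) -> bool:
        return self.start <= age < self.end

    @classmethod
    def grid(cls) -> tuple["AgeBand", ...]:
        """The unique nine-band partition of [25, 70)."""
        return tuple(cls(b, b + BAND_WIDTH) for b in BAND_STARTS)


def band_index(age: float) -> int:
    """Index of the band containing ``age``; raises for ages outside [25, 70)."""
    if not AGE_MIN <= age < AGE_MAX:
        raise ValueError(f"age {age} outside [{AGE_MIN}, {AGE_MAX})")
    return int((age - AGE_MIN) // BAND_WIDTH)


@dataclass(frozen=True)
class CarrierRecord:
    """One prospectively followed carrier.

    ``entry_age`` is the age at the first prospective surveillance examination;
    ``exit_age`` the age at first event, death, or last observation, whichever
    came first.  ``prior_crc`` flags a prevalent case: cancer diagnosed before
    or at entry, which excludes the carrier from all prospective accounting.
    An ``exit_reason`` of ``crc_event`` marks only incident cancer after entry.
    """

    carrier_id: str
    gene: str
    sex: str
    region: str
    entry_age: float
    exit_age: float
    exit_reason: str
    prior_crc: bool

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise RowError(f"unknown gene {self.gene!r} (expected one of {GENES})")
        if self.sex not in SEXES:
            raise RowError(f"unknown sex {self.sex!r} (expected one of {SEXES})")
        if self.exit_reason not in EXIT_REASONS:
            raise RowError(
                f"unknown exit_reason {self.exit_reason!r} (expected one of {EXIT_REASONS})"
            )
        if not self.entry_age > 0:
            raise RowError(f"entry_age must be positive, got {self.entry_age}")
        if self.exit_age < self.entry_age:
            raise RowError(
                f"exit_age {self.exit_age} earlier than entry_age {self.entry_age}"
            )


@dataclass(frozen=True)
class PersonTimeTable:
    """Events and person-years per five-year band for one stratum.

    ``events[j]`` and ``person_years[j]`` refer to the band starting at
    ``BAND_STARTS[j]``.  Stratum labels use ``"All"`` for pooled dimensions.
    """

    gene: str
    sex: str
    region: str
    events: tuple[int, ...]
    person_years: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.events) != N_BANDS or len(self.person_years) != N_BANDS:
            raise ValueError(f"tables carry exactly {N_BANDS} bands")
        for j, (d, t) in enumerate(zip(self.events, self.person_years)):
            if d < 0 or int(d) != d:
                raise ValueError(f"events must be non-negative integers, band {j}: {d}")
            if t < 0:
                raise ValueError(f"person_years must be non-negative, band {j}: {t}")
            if d > 0 and not t > 0:
                raise ValueError(f"band {j} has {d} events but no person-time")

    @property
    def stratum(self) -> tuple[str, str, str]:
        return (self.gene, self.sex, self.region)

    @property
    def total_events(self) -> int:
        return int(sum(self.events))

    @property
    def total_person_years(self) -> float:
        return float(sum(self.person_years))


def _parse_bool(token: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise RowError(f"cannot parse boolean from {token!r}")


def _parse_row(row: dict, rownum: int) -> CarrierRecord:
    try:
        entry_age = float(row["entry_age"])
        exit_age = float(row["exit_age"])
    except ValueError as exc:
        raise RowError(f"row {rownum}: unparseable age ({exc})") from None
    try:
        return CarrierRecord(
            carrier_id=row["carrier_id"].strip(),
            gene=row["gene"].strip(),
            sex=row["sex"].strip().lower(),
            region=row["region"].strip(),
            entry_age=entry_age,
            exit_age=exit_age,
            exit_reason=row["exit_reason"].strip().lower(),
            prior_crc=_parse_bool(row["prior_crc"]),
        )
    except RowError as exc:
        raise RowError(f"row {rownum}: {exc}") from None


def read_cohort(path: str | Path, strict: bool = True) -> list[CarrierRecord]:
    """Read and validate a carrier CSV.

    In strict mode any invalid row aborts with an error naming the row; in
    non-strict mode offending rows are dropped and logged with their row
    numbers.  A missing column is a :class:`SchemaError` in either mode.
    """
    path = Path(path)
    records: list[CarrierRecord] = []
    dropped = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        for rownum, row in enumerate(reader, start=2):  # 1-based, after header
            try:
                records.append(_parse_row(row, rownum))
            except RowError as exc:
                if strict:
                    raise SchemaError(f"{path}: {exc}") from None
                dropped += 1
                logger.warning("%s: dropping invalid %s", path, exc)
    if dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, dropped)
    return records


def write_cohort(records: Iterable[CarrierRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.carrier_id,
                    r.gene,
                    r.sex,
                    r.region,
                    repr(r.entry_age),
                    repr(r.exit_age),
                    r.exit_reason,
                    str(r.prior_crc).lower(),
                ]
            )


PERSONTIME_COLUMNS = ("gene", "sex", "region", "band_start", "events", "person_years")


def write_persontime(tables: Iterable[PersonTimeTable], path: str | Path) -> None:
    """Write one row per stratum and band; empty strata yield nine zero rows."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PERSONTIME_COLUMNS)
        for t in tables:
            for j, b in enumerate(BAND_STARTS):
                writer.writerow(
                    [t.gene, t.sex, t.region, b, t.events[j], repr(t.person_years[j])]
                )


def read_persontime(path: str | Path) -> list[PersonTimeTable]:
    path = Path(path)
    cells: dict[tuple[str, str, str], dict[int, tuple[int, float]]] = {}
    order: list[tuple[str, str, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in PERSONTIME_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        for row in reader:
            key = (row["gene"], row["sex"], row["region"])
            if key not in cells:
                cells[key] = {}
                order.append(key)
            cells[key][int(row["band_start"])] = (
                int(row["events"]),
                float(row["person_years"]),
            )
    tables = []
    for key in order:
        per_band = cells[key]
        missing_bands = [b for b in BAND_STARTS if b not in per_band]
        if missing_bands:
            raise SchemaError(f"{path}: stratum {key} missing bands {missing_bands}")
        tables.append(
            PersonTimeTable(
                gene=key[0],
                sex=key[1],
                region=key[2],
                events=tuple(per_band[b][0] for b in BAND_STARTS),
                person_years=tuple(per_band[b][1] for b in BAND_STARTS),
            )
        )
    return tables


CURVE_COLUMNS = (
    "gene",
    "sex",
    "region",
    "method",
    "age",
    "air",
    "q",
    "ci_lo",
    "ci_hi",
)


def write_curves(curves: Iterable, path: str | Path) -> None:
    """Write incidence curves, one row per report age.

    The ``air`` column carries the annual rate of the band *starting* at the
    row's age (blank on the final age and on curves without band rates).
    """
    import math

    path = Path(path)

    def fmt(x) -> str:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return ""
        return repr(float(x))

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CURVE_COLUMNS)
        for c in curves:
            for i, age in enumerate(c.ages):
                if c.air is not None and age in BAND_STARTS:
                    air_val = fmt(c.air[BAND_STARTS.index(age)])
                else:
                    air_val = ""
                writer.writerow(
                    [
                        c.gene,
                        c.sex,
                        c.region,
                        c.method,
                        age,
                        air_val,
                        fmt(c.q[i]),
                        fmt(c.ci_lo[i]),
                        fmt(c.ci_hi[i]),
                    ]
                )


def read_curves(path: str | Path) -> list:
    """Inverse of :func:`write_curves`."""
    import math

    from .estimate import IncidenceCurve

    path = Path(path)
    groups: dict[tuple[str, str, str, str], list[dict]] = {}
    order: list[tuple[str, str, str, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in CURVE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        for row in reader:
            key = (row["gene"], row["sex"], row["region"], row["method"])
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(row)

    def num(token: str) -> float:
        return float("nan") if token == "" else float(token)

    curves = []
    for key in order:
        rows = sorted(groups[key], key=lambda r: int(r["age"]))
        ages = tuple(int(r["age"]) for r in rows)
        air_vals = {int(r["age"]): num(r["air"]) for r in rows if r["air"] != ""}
        air = None
        if air_vals and all(b in air_vals for b in BAND_STARTS):
            air = tuple(air_vals[b] for b in BAND_STARTS)
        curves.append(
            IncidenceCurve(
                gene=key[0],
                sex=key[1],
                region=key[2],
                method=key[3],
                ages=ages,
                q=tuple(num(r["q"]) for r in rows),
                ci_lo=tuple(num(r["ci_lo"]) for r in rows),
                ci_hi=tuple(num(r["ci_hi"]) for r in rows),
                air=air,
            )
        )
    return curves
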