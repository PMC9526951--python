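"""Interval-overlap comparison of two incidence curves.

The comparison is the heuristic used to read stratified risk tables, not a
formal two-sample test.  At each report age two curves with 95% CIs are
classified three ways:

``disjoint_cis``
    the intervals do not overlap — reported as a significant difference;

``mean_inside_other_ci``
    at least one point estimate lies inside the other curve's interval —
    reported as no significant difference;

``intermediate``
    the intervals overlap but neither mean is covered — inconclusive.

The third class is kept explicit because the two published criteria do not
partition all configurations of four endpoints.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .estimate import IncidenceCurve

logger = logging.getLogger(__name__)

CLASSIFICATIONS = ("disjoint_cis", "mean_inside_other_ci", "intermediate")

#: Packaged reference curves: published cumulative incidences (percent) with
#: 95% CIs for the prospective surveillance series and the retrospective
#: family-based series, by sex, gene, and region.
REFERENCE_SOURCES = ("prospective", "retrospective")
_REFERENCE_RESOURCE = "reference_curves.csv"


@dataclass(frozen=True)
class ComparisonEntry:
    """Classification of two curves at one report age."""

    gene: str
    sex: str
    region: str
    age: int
    classification: str
    direction: str  # "A_higher" | "B_higher" | "equal"
    q_a: float
    lo_a: float
    hi_a: float
    q_b: float
    lo_b: float
    hi_b: float

    @property
    def significant(self) -> bool:
        return self.classification == "disjoint_cis"


def _has_ci(curve: IncidenceCurve, age: int) -> bool:
    if age not in curve.ages:
        return False
    _, lo, hi = curve.at(age)
    return not (math.isnan(lo) or math.isnan(hi))


def classify(
    curve_a: IncidenceCurve, curve_b: IncidenceCurve, age: int
) -> ComparisonEntry:
    """Three-way interval-overlap classification at one age.

    Both curves must carry a CI at the age.  Disjointness is checked first;
    the mean-inside rule applies only to overlapping intervals.
    """
    for name, curve in (("A", curve_a), ("B", curve_b)):
        if not _has_ci(curve, age):
            raise ValueError(
                f"curve {name} {curve.stratum} has no confidence interval at age {age}"
            )
    q_a, lo_a, hi_a = curve_a.at(age)
    q_b, lo_b, hi_b = curve_b.at(age)
    if lo_a > hi_b or lo_b > hi_a:
        classification = "disjoint_cis"
    elif (lo_b <= q_a <= hi_b) or (lo_a <= q_b <= hi_a):
        classification = "mean_inside_other_ci"
    else:
        classification = "intermediate"
    if q_a > q_b:
        direction = "A_higher"
    elif q_b > q_a:
        direction = "B_higher"
    else:
        direction = "equal"
    return ComparisonEntry(
        gene=curve_a.gene,
        sex=curve_a.sex,
        region=curve_a.region,
        age=age,
        classification=classification,
        direction=direction,
        q_a=q_a,
        lo_a=lo_a,
        hi_a=hi_a,
        q_b=q_b,
        lo_b=lo_b,
        hi_b=hi_b,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Full classification grid plus the strata significant at the final age."""

    entries: tuple[ComparisonEntry, ...]
    disjoint_at_final_age: tuple[tuple[str, str, str], ...]
    final_age: int


def compare_series(
    curves_a: Sequence[IncidenceCurve],
    curves_b: Sequence[IncidenceCurve],
    ages: Optional[Sequence[int]] = None,
    final_age: int = 70,
) -> ComparisonResult:
    """Classify matching strata of two curve sets at every comparable age.

    Strata present in only one set are logged and skipped, as are ages where
    either curve lacks an interval (e.g. zero cells printed without a CI).
    """
    index_b = {c.stratum: c for c in curves_b}
    entries: list[ComparisonEntry] = []
    disjoint: list[tuple[str, str, str]] = []
    for a_curve in curves_a:
        b_curve = index_b.get(a_curve.stratum)
        if b_curve is None:
            logger.warning("stratum %s present only in series A; skipped", a_curve.stratum)
            continue
        compare_ages = ages
        if compare_ages is None:
            compare_ages = sorted(set(a_curve.ages) & set(b_curve.ages))
        for age in compare_ages:
            if not (_has_ci(a_curve, age) and _has_ci(b_curve, age)):
                continue
            entry = classify(a_curve, b_curve, age)
            entries.append(entry)
            if age == final_age and entry.significant:
                disjoint.append((entry.gene, entry.sex, entry.region))
    only_b = set(index_b) - {c.stratum for c in curves_a}
    for stratum in sorted(only_b):
        logger.warning("stratum %s present only in series B; skipped", stratum)
    return ComparisonResult(
        entries=tuple(entries),
        disjoint_at_final_age=tuple(disjoint),
        final_age=final_age,
    )


COMPARISON_COLUMNS = (
    "gene",
    "sex",
    "region",
    "age",
    "classification",
    "direction",
    "q_a",
    "lo_a",
    "hi_a",
    "q_b",
    "lo_b",
    "hi_b",
)


def write_comparison(result: ComparisonResult, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COMPARISON_COLUMNS)
        for e in result.entries:
            writer.writerow(
                [
                    e.gene,
                    e.sex,
                    e.region,
                    e.age,
                    e.classification,
                    e.direction,
                    repr(e.q_a),
                    repr(e.lo_a),
                    repr(e.hi_a),
                    repr(e.q_b),
                    repr(e.lo_b),
                    repr(e.hi_b),
                ]
            )


def load_reference_curves(
    source: str, region: Optional[str] = None
) -> list[IncidenceCurve]:
    """Load the packaged published-table fixture as fraction-scale curves.

    ``source`` selects the series (``prospective`` or ``retrospective``);
    ``region`` optionally restricts to one region label (``Europe``/``All``).
    Cells printed without an interval come back with NaN bounds.
    """
    if source not in REFERENCE_SOURCES:
        raise ValueError(f"unknown source {source!r} (expected one of {REFERENCE_SOURCES})")
    text = (
        resources.files("riskband.data").joinpath(_REFERENCE_RESOURCE).read_text("utf-8")
    )
    rows = list(csv.DictReader(text.splitlines()))
    groups: dict[tuple[str, str, str], list[dict]] = {}
    for row in rows:
        if row["source"] != source:
            continue
        if region is not None and row["region"] != region:
            continue
        groups.setdefault((row["gene"], row["sex"], row["region"]), []).append(row)

    def frac(token: str) -> float:
        return float("nan") if token == "" else float(token) / 100.0

    curves = []
    for (gene, sex, reg), cell_rows in sorted(groups.items()):
        cell_rows.sort(key=lambda r: int(r["age"]))
        curves.append(
            IncidenceCurve(
                gene=gene,
                sex=sex,
                region=reg,
                method="reference",
                ages=tuple(int(r["age"]) for r in cell_rows),
                q=tuple(frac(r["q_percent"]) for r in cell_rows),
                ci_lo=tuple(frac(r["lo"]) for r in cell_rows),
                ci_hi=tuple(frac(r["hi"]) for r in cell_rows),
            )
        )
    return curves
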