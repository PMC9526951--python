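"""Synthetic carrier cohorts from known piecewise-constant hazards.

The simulator is the package's testing ground: cohorts are generated from a
:class:`HazardModel` (per-stratum annual hazards on the nine five-year bands),
run through the person-time engine and the estimators, and checked for
parameter recovery, interval coverage, and exact exposure bookkeeping.

Event ages are sampled by exact inversion of the piecewise-linear cumulative
hazard, so the generating truth is analytically available: the true cumulative
incidence by age a is 1 - exp(-integral of the hazard from 25 to a).  The
hazard is zero outside [25, 70) — consistent with the convention that risk
accounting starts at 25 — so carriers entering earlier accrue no event risk
before 25 and events can never occur past 70.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .estimate import estimate_curve
from .persontime import tabulate
from .records import (
    AGE_MAX,
    AGE_MIN,
    BAND_STARTS,
    BAND_WIDTH,
    N_BANDS,
    CarrierRecord,
    PersonTimeTable,
)

Stratum = tuple[str, str]  # (gene, sex)

_BOUNDARIES = np.array(list(BAND_STARTS) + [int(AGE_MAX)], dtype=float)


class CalibrationError(ValueError):
    """Cumulative-incidence targets that no hazard model can reproduce."""


def calibrate_hazards(q_targets: Mapping[int, float]) -> np.ndarray:
    """Annual band hazards whose cumulative incidence hits the given targets.

    ``q_targets`` maps ages (multiples of 5 in [25, 70], starting with
    ``{25: 0}``) to cumulative incidences.  Within each interval between
    consecutive target ages the annual risk is constant:

        a = 1 - ((1 - Q_end) / (1 - Q_start)) ** (1 / width)

    and the returned hazard is ``-log(1 - a)`` for every band in the interval,
    so that feeding the model back through the annual recursion reproduces the
    targets to machine precision.
    """
    ages = sorted(q_targets)
    if not ages or ages[0] != int(AGE_MIN) or q_targets[ages[0]] != 0:
        raise CalibrationError(f"targets must start with {{{int(AGE_MIN)}: 0}}")
    if ages[-1] > AGE_MAX or any(a % 5 for a in ages):
        raise CalibrationError("target ages must be multiples of 5 within [25, 70]")
    hazards = np.zeros(N_BANDS)
    for a0, a1 in zip(ages, ages[1:]):
        q0, q1 = q_targets[a0], q_targets[a1]
        if q1 < q0:
            raise CalibrationError(f"targets decrease between ages {a0} and {a1}")
        if q1 >= 1:
            raise CalibrationError(f"target at age {a1} must be below 1")
        annual_risk = 1.0 - ((1.0 - q1) / (1.0 - q0)) ** (1.0 / (a1 - a0))
        lam = -math.log1p(-annual_risk)
        for j, b in enumerate(BAND_STARTS):
            if a0 <= b < a1:
                hazards[j] = lam
    return hazards


@dataclass(frozen=True)
class HazardModel:
    """Per-stratum annual hazards on the five-year bands (simulator truth)."""

    strata: dict[Stratum, np.ndarray]

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("model needs at least one stratum")
        for key, lam in self.strata.items():
            arr = np.asarray(lam, dtype=float)
            if arr.shape != (N_BANDS,):
                raise ValueError(f"stratum {key}: expected {N_BANDS} hazards")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"stratum {key}: hazards must be finite and >= 0")
            self.strata[key] = arr

    @classmethod
    def from_targets(cls, targets: Mapping[Stratum, Mapping[int, float]]) -> "HazardModel":
        return cls({k: calibrate_hazards(t) for k, t in targets.items()})

    def cumulative_hazard_grid(self, stratum: Stratum) -> np.ndarray:
        """Cumulative hazard at band boundaries 25, 30, ..., 70."""
        lam = self.strata[stratum]
        return np.concatenate([[0.0], np.cumsum(lam * BAND_WIDTH)])

    def true_q(self, age: float, stratum: Optional[Stratum] = None) -> float:
        """Model cumulative incidence at ``age``; mean over strata if pooled."""
        keys = [stratum] if stratum is not None else list(self.strata)
        qs = []
        for key in keys:
            grid = self.cumulative_hazard_grid(key)
            h = float(np.interp(age, _BOUNDARIES, grid))
            qs.append(1.0 - math.exp(-h))
        return float(np.mean(qs))

    def annual_airs(self, stratum: Stratum) -> np.ndarray:
        """Annual risks 1 - exp(-hazard) per band (the recursion's AIR scale)."""
        return 1.0 - np.exp(-self.strata[stratum])


def _draw(spec: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "fixed":
        return np.full(n, float(spec[1]))
    if kind == "uniform":
        return rng.uniform(float(spec[1]), float(spec[2]), size=n)
    raise ValueError(f"unknown distribution spec {spec!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generation knobs; the seed is mandatory for reproducibility."""

    n_carriers: int
    seed: int
    entry_age: tuple = ("uniform", 25.0, 60.0)
    followup: tuple = ("fixed", 15.0)
    prevalent_fraction: float = 0.0
    under25_fraction: float = 0.0
    under25_range: tuple[float, float] = (18.0, 25.0)
    region: str = "sim"

    def __post_init__(self) -> None:
        if self.n_carriers < 1:
            raise ValueError("n_carriers must be >= 1")
        for name in ("prevalent_fraction", "under25_fraction"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class SimulationBookkeeping:
    """Ground-truth exposure and event tallies emitted with the cohort.

    ``tables`` mirror the person-time engine's accounting rules exactly
    (truncation at 25, cap at 70, prevalent exclusion), computed directly from
    the simulated ages so they serve as an independent oracle for ``tabulate``.
    """

    tables: tuple[PersonTimeTable, ...]
    n_included: int
    n_events: int
    total_person_years: float


def _invert_cumhaz(targets: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Ages at which the cumulative hazard reaches ``targets`` (inf if never)."""
    ages = np.full(targets.shape, np.inf)
    reachable = targets <= grid[-1]
    idx = np.searchsorted(grid, targets[reachable], side="left")
    idx = np.clip(idx, 1, len(grid) - 1)
    lo = grid[idx - 1]
    hi = grid[idx]
    width = hi - lo
    frac = np.where(width > 0, (targets[reachable] - lo) / np.where(width > 0, width, 1.0), 0.0)
    ages[reachable] = _BOUNDARIES[idx - 1] + frac * BAND_WIDTH
    return ages


def simulate_cohort(
    model: HazardModel, config: SimulationConfig
) -> tuple[list[CarrierRecord], SimulationBookkeeping]:
    """Generate carrier records plus exact exposure/event bookkeeping.

    Deterministic given the config seed.  Death and loss to follow-up are
    merged into a single administrative censoring draw; prevalent carriers are
    flagged rather than given a simulated disease history, since only the
    exclusion behaviour matters downstream.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_carriers
    strata = sorted(model.strata)
    stratum_idx = rng.integers(len(strata), size=n)
    prevalent = rng.random(n) < config.prevalent_fraction
    under25 = rng.random(n) < config.under25_fraction
    entry = _draw(config.entry_age, n, rng)
    entry_young = rng.uniform(*config.under25_range, size=n)
    entry = np.where(under25, entry_young, entry)
    followup = _draw(config.followup, n, rng)
    exp_draw = rng.exponential(1.0, size=n)

    event_age = np.full(n, np.inf)
    for s, key in enumerate(strata):
        mask = stratum_idx == s
        if not mask.any():
            continue
        grid = model.cumulative_hazard_grid(key)
        start = np.maximum(entry[mask], AGE_MIN)
        h_start = np.interp(start, _BOUNDARIES, grid)
        event_age[mask] = _invert_cumhaz(h_start + exp_draw[mask], grid)

    censor_age = entry + followup
    is_event = event_age <= censor_age
    exit_age = np.where(is_event, event_age, censor_age)

    records = []
    for i in range(n):
        gene, sex = strata[stratum_idx[i]]
        records.append(
            CarrierRecord(
                carrier_id=f"sim{i:06d}",
                gene=gene,
                sex=sex,
                region=config.region,
                entry_age=float(entry[i]),
                exit_age=float(exit_age[i]),
                exit_reason="crc_event" if is_event[i] else "last_observation",
                prior_crc=bool(prevalent[i]),
            )
        )

    # bookkeeping under the engine's accounting rules, computed from arrays
    start = np.maximum(entry, AGE_MIN)
    stop = np.minimum(exit_age, AGE_MAX)
    included = (~prevalent) & (stop > start)
    counted = included & is_event & (exit_age <= AGE_MAX)
    tables = []
    for s, key in enumerate(strata):
        mask = included & (stratum_idx == s)
        years = []
        events = []
        for b in BAND_STARTS:
            overlap = np.minimum(stop, b + BAND_WIDTH) - np.maximum(start, b)
            years.append(float(np.sum(np.where(mask, np.maximum(overlap, 0.0), 0.0))))
        ev_band = np.floor((stop - AGE_MIN) / BAND_WIDTH).astype(int)
        on_boundary = (stop > AGE_MIN) & (np.mod(stop - AGE_MIN, BAND_WIDTH) == 0)
        ev_band = np.where(on_boundary, ev_band - 1, ev_band)
        for j in range(N_BANDS):
            events.append(int(np.sum(counted & (stratum_idx == s) & (ev_band == j))))
        gene, sex = key
        tables.append(
            PersonTimeTable(
                gene=gene,
                sex=sex,
                region=config.region,
                events=tuple(events),
                person_years=tuple(years),
            )
        )
    bookkeeping = SimulationBookkeeping(
        tables=tuple(tables),
        n_included=int(np.sum(included)),
        n_events=int(np.sum(counted)),
        total_person_years=float(np.sum(np.where(included, stop - start, 0.0))),
    )
    return records, bookkeeping


@dataclass(frozen=True)
class ReplicateSummary:
    """Monte-Carlo summary of repeated estimation at one target age."""

    target_age: int
    truth: float
    q_hat: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    coverage: float
    bias: float
    rmse: float
    mc_se_mean: float

    @property
    def n_replicates(self) -> int:
        return len(self.q_hat)


def simulate_many(
    model: HazardModel,
    config: SimulationConfig,
    n_replicates: int,
    method: str = "nelson_aalen_poisson",
    level: float = 0.95,
    target_age: int = 70,
) -> ReplicateSummary:
    """Estimate Q(target_age) with CI across replicate cohorts.

    Each replicate pools all strata into one table (matching the pooled truth,
    which for multi-stratum models is the uniform mixture mean).  Replicate
    seeds are spawned deterministically from the config seed.
    """
    truth = model.true_q(target_age)
    children = np.random.SeedSequence(config.seed).spawn(n_replicates)
    q_hat = np.empty(n_replicates)
    lo = np.empty(n_replicates)
    hi = np.empty(n_replicates)
    for r in range(n_replicates):
        rep_seed = int(children[r].generate_state(1)[0])
        rep_config = replace(config, seed=rep_seed)
        records, _ = simulate_cohort(model, rep_config)
        (table,) = tabulate(records, group_by=())
        curve = estimate_curve(table, method=method, level=level)
        q_hat[r], lo[r], hi[r] = curve.at(target_age)
    covered = (lo <= truth) & (truth <= hi)
    errors = q_hat - truth
    return ReplicateSummary(
        target_age=target_age,
        truth=truth,
        q_hat=q_hat,
        ci_lo=lo,
        ci_hi=hi,
        coverage=float(np.mean(covered)),
        bias=float(np.mean(errors)),
        rmse=float(np.sqrt(np.mean(errors**2))),
        mc_se_mean=float(np.std(q_hat, ddof=1) / np.sqrt(n_replicates)),
    )
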