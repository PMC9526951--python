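"""End-to-end pipeline and text rendering of stratified incidence tables."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import compare as compare_mod
from .estimate import IncidenceCurve, estimate_curve
from .persontime import summarize_cohort, tabulate
from .records import (
    REPORT_AGES,
    read_cohort,
    write_cohort,
    write_curves,
    write_persontime,
)
from .simulate import HazardModel, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration: exactly one of ``input`` / ``simulation``."""

    outdir: str
    input: Optional[str] = None
    simulation: Optional[dict] = None
    group_by: tuple[str, ...] = ("gene", "sex")
    ci_method: str = "nelson_aalen_poisson"
    ci_level: float = 0.95
    report_ages: tuple[int, ...] = REPORT_AGES
    seed: Optional[int] = None
    reference: Optional[str] = None  # path to a curves CSV, or "builtin"
    strict: bool = True

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulation is None):
            raise ValueError("exactly one of input / simulation must be given")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        known = {
            "outdir",
            "input",
            "simulation",
            "group_by",
            "ci_method",
            "ci_level",
            "report_ages",
            "seed",
            "reference",
            "strict",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        for key in ("group_by", "report_ages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _build_simulated_cohort(spec: dict, seed: Optional[int]):
    """Build a cohort from a simulation spec mapping.

    Expected keys: ``targets`` (mapping ``"GENE,sex"`` or stratum to
    age->cumulative-incidence targets, fractions) or ``hazards`` (stratum to
    nine annual hazards), plus :class:`SimulationConfig` fields.
    """
    spec = dict(spec)
    targets = spec.pop("targets", None)
    hazards = spec.pop("hazards", None)
    if (targets is None) == (hazards is None):
        raise ValueError("simulation spec needs exactly one of targets / hazards")

    def parse_stratum(key) -> tuple[str, str]:
        if isinstance(key, str):
            gene, sex = (tok.strip() for tok in key.split(","))
            return (gene, sex)
        return tuple(key)  # type: ignore[return-value]

    if targets is not None:
        model = HazardModel.from_targets(
            {parse_stratum(k): {int(a): float(q) for a, q in v.items()} for k, v in targets.items()}
        )
    else:
        model = HazardModel({parse_stratum(k): v for k, v in hazards.items()})
    if seed is not None:
        spec.setdefault("seed", seed)
    for key in ("entry_age", "followup", "under25_range"):
        if key in spec:
            spec[key] = tuple(spec[key])
    config = SimulationConfig(**spec)
    records, bookkeeping = simulate_cohort(model, config)
    return records, bookkeeping


@dataclass(frozen=True)
class RunResult:
    outdir: Path
    paths: dict[str, Path]
    summary: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Tabulate, estimate, summarize, render, and optionally compare.

    Writes ``persontime.csv``, ``curves.csv``, ``summary.json``,
    ``table_report.txt`` (and ``cohort.csv`` for simulated input,
    ``comparison.csv`` when a reference is configured) under ``outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.input is not None:
        cohort = read_cohort(config.input, strict=config.strict)
    else:
        cohort, _ = _build_simulated_cohort(config.simulation, config.seed)
        paths["cohort"] = outdir / "cohort.csv"
        write_cohort(cohort, paths["cohort"])

    tables = tabulate(cohort, group_by=config.group_by)
    paths["persontime"] = outdir / "persontime.csv"
    write_persontime(tables, paths["persontime"])

    curves = [
        estimate_curve(
            t,
            method=config.ci_method,
            level=config.ci_level,
            report_ages=config.report_ages,
        )
        for t in tables
    ]
    paths["curves"] = outdir / "curves.csv"
    write_curves(curves, paths["curves"])

    summary_obj = summarize_cohort(cohort)
    summary = {
        "n_included": summary_obj.n_included,
        "total_person_years": summary_obj.total_person_years,
        "mean_followup": summary_obj.mean_followup,
        "n_events": summary_obj.n_events,
        "n_strata": len(tables),
        "ci_method": config.ci_method,
        "ci_level": config.ci_level,
    }
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")

    paths["table_report"] = outdir / "table_report.txt"
    paths["table_report"].write_text(
        render_table1(curves, ages=[a for a in config.report_ages if a > 25]),
        encoding="utf-8",
    )

    if config.reference is not None:
        if config.reference == "builtin":
            reference = compare_mod.load_reference_curves("retrospective")
        else:
            from .records import read_curves

            reference = read_curves(config.reference)
        result = compare_mod.compare_series(curves, reference)
        paths["comparison"] = outdir / "comparison.csv"
        compare_mod.write_comparison(result, paths["comparison"])
        summary["n_disjoint_at_70"] = len(result.disjoint_at_final_age)

    logger.info(
        "pipeline done: %d carriers included, %d events, %d strata",
        summary["n_included"],
        summary["n_events"],
        summary["n_strata"],
    )
    return RunResult(outdir=outdir, paths=paths, summary=summary)


def _fmt_percent(value: float) -> str:
    """Percent with one decimal, half-up; exact zero prints as '0'."""
    if value == 0:
        return "0"
    pct = value * 100.0
    rounded = math.floor(pct * 10 + 0.5) / 10
    return f"{rounded:.1f}"


def format_cell(q: float, lo: float, hi: float) -> str:
    """One table cell: percent point estimate with CI in parentheses."""
    if math.isnan(q):
        return "-"
    if math.isnan(lo) or math.isnan(hi) or (q == 0 and lo == 0 and hi == 0):
        return f"{_fmt_percent(q)} (-)"
    return f"{_fmt_percent(q)} ({_fmt_percent(lo)}-{_fmt_percent(hi)})"


def render_table1(
    curves: Sequence[IncidenceCurve],
    ages: Sequence[int] = (30, 40, 50, 60, 70),
) -> str:
    """Plain-text stratified report: one row per sex/gene/region, columns per age.

    Values are percent cumulative incidences with 95% CIs in parentheses;
    cells without an estimate render as '-'.  Display rounding is half-up at
    one decimal; underlying CSV exports keep full precision.
    """
    header = ["sex", "gene", "region", "method"] + [f"{a}y" for a in ages]
    rows = [header]
    for c in sorted(curves, key=lambda c: (c.sex, c.gene, c.region, c.method)):
        row = [c.sex, c.gene, c.region, c.method]
        for a in ages:
            if a in c.ages:
                row.append(format_cell(*c.at(a)))
            else:
                row.append("-")
        rows.append(row)
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows
    ]
    return "\n".join(lines) + "\n"
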