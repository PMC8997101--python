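"""CSV schemas, stream readers/writers, pipeline configuration and the
end-to-end pipeline.

All streams are UTF-8, comma-separated CSV with a mandatory header row and
ISO-8601 dates (decimal point, not comma).  Readers validate row-by-row
against the declared schema, collect malformed rows with their line numbers
and abort only when the malformed fraction exceeds a configured cap; writers
emit canonical column order and formatting so that identical data produce
byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import benchmarking, kpi as kpi_mod, reliability, validation
from .domain import CULLING_REASONS, RECORDER_TYPES
from .simulate import SimulatedPopulation, SimulationConfig, simulate_population

log = logging.getLogger("clawbench")

#: column -> (kind, required); kinds: str, date, date_opt, int:<lo>:<hi>,
#: int_opt:<lo>:<hi>, enum:<v1>|<v2>..., str_opt
SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "trimming": {
        "herd_id": ("str", True),
        "cow_id": ("str", True),
        "date": ("date", True),
        "lesion_code": ("str", True),
        "zone": ("int:0:10", True),
        "severity": ("int_opt:1:3", True),
        "recorder": ("enum:" + "|".join(RECORDER_TYPES), True),
        "observer_id": ("str", True),
    },
    "locomotion": {
        "herd_id": ("str", True),
        "cow_id": ("str", True),
        "date": ("date", True),
        "score": ("int:1:5", True),
        "observer_id": ("str", True),
    },
    "roster": {
        "herd_id": ("str", True),
        "cow_id": ("str", True),
        "entry_date": ("date", True),
        "exit_date": ("date_opt", True),
        "calving_dates": ("str_opt", True),
        "dryoff_dates": ("str_opt", True),
    },
    "culling": {
        "herd_id": ("str", True),
        "cow_id": ("str", True),
        "date": ("date", True),
        "reason": ("enum:" + "|".join(CULLING_REASONS), True),
    },
    "raters": {
        "observer_id": ("str", True),
        "item_id": ("str", True),
        "rating": ("int:-1000000:1000000", True),
        "reference": ("int:-1000000:1000000", True),
    },
}


class SchemaError(ValueError):
    """Input file does not match the declared schema."""


class MalformedDataError(ValueError):
    """Too many malformed rows to continue."""


def _check_cell(value: str, kind: str) -> tuple[object, Optional[str]]:
    blank = value is None or (isinstance(value, float) and pd.isna(value)) or value == ""
    if kind == "str":
        if blank:
            return None, "required value missing"
        return str(value), None
    if kind == "str_opt":
        return ("" if blank else str(value)), None
    if kind in ("date", "date_opt"):
        if blank:
            return (pd.NaT, None) if kind == "date_opt" else (None, "date missing")
        try:
            return pd.Timestamp(str(value)), None
        except ValueError:
            return None, f"unparsable ISO date {value!r}"
    if kind.startswith("int_opt") and blank:
        return pd.NA, None
    if kind.startswith("int"):
        if blank:
            return None, "integer missing"
        parts = kind.split(":")
        lo, hi = int(parts[1]), int(parts[2])
        try:
            iv = int(str(value))
        except ValueError:
            return None, f"not an integer: {value!r}"
        if not lo <= iv <= hi:
            return None, f"value {iv} outside the {lo}..{hi} scale"
        return iv, None
    if kind.startswith("enum"):
        allowed = kind.split(":", 1)[1].split("|")
        if blank:
            return None, "required value missing"
        if str(value) not in allowed:
            return None, f"{value!r} not one of {allowed}"
        return str(value), None
    raise AssertionError(f"unknown schema kind {kind}")  # pragma: no cover


def read_stream(path, schema: str,
                malformed_cap: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate one record stream.

    Returns (typed records, issues).  ``issues`` has one row per malformed
    cell (line number, column, message); malformed rows are dropped.  A
    missing required column raises :class:`SchemaError` naming the column;
    a malformed fraction above ``malformed_cap`` raises
    :class:`MalformedDataError`.
    """
    spec = SCHEMAS[schema]
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col, (_, required) in spec.items():
        if required and col not in raw.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    issues_rows = []
    bad = np.zeros(len(raw), dtype=bool)
    typed: dict[str, list] = {c: [] for c in spec}
    for i in range(len(raw)):
        row_ok = True
        parsed = {}
        for col, (kind, _) in spec.items():
            value, err = _check_cell(raw.at[i, col] if col in raw.columns else "",
                                     kind)
            if err is not None:
                issues_rows.append({"line": i + 2, "column": col, "message": err})
                row_ok = False
            parsed[col] = value
        if row_ok:
            for col in spec:
                typed[col].append(parsed[col])
        else:
            bad[i] = True
    if len(raw) and bad.mean() > malformed_cap:
        raise MalformedDataError(
            f"{path}: {bad.sum()}/{len(raw)} malformed rows exceeds cap {malformed_cap}")
    frame = pd.DataFrame({c: typed[c] for c in spec})
    for col, (kind, _) in spec.items():
        if kind in ("date", "date_opt"):
            frame[col] = pd.to_datetime(frame[col])
        elif kind.startswith("int_opt"):
            frame[col] = frame[col].astype("Int64")
        elif kind.startswith("int"):
            frame[col] = frame[col].astype("int64") if len(frame) else frame[col]
    issues = pd.DataFrame(issues_rows, columns=["line", "column", "message"])
    if len(issues):
        log.warning("%s: dropped %d malformed row(s)", path, int(bad.sum()))
    return frame, issues


def write_stream(frame: pd.DataFrame, path, schema: str) -> None:
    """Write a stream in canonical form (column order, ISO dates)."""
    spec = SCHEMAS[schema]
    out = frame.copy()
    for col, (kind, _) in spec.items():
        if col not in out.columns:
            out[col] = ""
        if kind in ("date", "date_opt"):
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        elif kind.startswith("int_opt"):
            out[col] = out[col].astype("Int64")
    out[list(spec)].to_csv(path, index=False)


def write_frame(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Canonical CSV writer for derived tables (KPIs, ledgers, benchmarks)."""
    frame.to_csv(path, index=index, float_format="%.10g")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class PipelineConfig(BaseModel):
    """Declarative configuration of the end-to-end run."""

    year: int = 2020
    seed: int = 0
    counting_mode: str = "cow-year"
    kappa_weights: str = "linear"
    kappa_threshold: float = reliability.DEFAULT_GATE_THRESHOLD
    kappa_merge: Optional[str] = None
    farmer_default_severity: int = Field(default=2, ge=1, le=3)
    trained_share_min: float = 0.95
    trim_share_min: float = 0.50
    min_distinct_diagnoses: int = 5
    require_lesion_free: bool = True
    dd_endemic_min_affected: int = 3
    percentile_estimator: str = "linear"  # type-7; fixed, documented
    my_farm: Optional[str] = None
    log_level: str = "INFO"
    simulation: Optional[SimulationConfig] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def validation_config(self, trained_observers=None) -> validation.ValidationConfig:
        return validation.ValidationConfig(
            year=self.year,
            trained_share_min=self.trained_share_min,
            trim_share_min=self.trim_share_min,
            min_distinct_diagnoses=self.min_distinct_diagnoses,
            require_lesion_free=self.require_lesion_free,
            trained_observers=(frozenset(trained_observers)
                               if trained_observers is not None else None),
        )


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    population: SimulatedPopulation
    observer_kappas: Optional[pd.DataFrame]
    trained_observers: Optional[set]
    clean_records: pd.DataFrame
    included_herds: set
    ledger: validation.RejectionLedger
    herd_kpis: pd.DataFrame
    benchmark_tables: dict[str, benchmarking.BenchmarkTable]
    report: Optional[pd.DataFrame] = None
    report_markdown: Optional[str] = None
    artifacts: dict[str, str] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig,
                 population: Optional[SimulatedPopulation] = None,
                 rater_table: Optional[pd.DataFrame] = None,
                 outdir=None) -> PipelineResult:
    """validate -> kpi -> benchmark (-> report), fully deterministic.

    Without an explicit ``population`` the synthetic generator supplies one
    from ``config.simulation`` (seed and year taken from the pipeline config).
    With a ``rater_table``, observers are gated first and the passed set —
    plus the app-trained farmer recorders — forms the trained registry for
    validation; without one, all observers are trusted.
    """
    logging.basicConfig(level=config.log_level)

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                log.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, exc) from exc
        return _Ctx()

    with _stage("simulate"):
        if population is None:
            sim_cfg = config.simulation or SimulationConfig()
            sim_cfg = sim_cfg.model_copy(update={"seed": config.seed,
                                                 "year": config.year})
            population = simulate_population(sim_cfg)

    kappas = None
    registry = None
    with _stage("reliability"):
        if rater_table is not None:
            kappas = reliability.observer_kappas(
                rater_table, merge=config.kappa_merge, weights=config.kappa_weights)
            passed, _failed = reliability.gate_observers(
                dict(zip(kappas["observer_id"], kappas["kappa"])),
                threshold=config.kappa_threshold)
            farmer_obs = set(population.trimming.loc[
                population.trimming["recorder"] == "farmer", "observer_id"])
            registry = passed | farmer_obs

    with _stage("validate"):
        vcfg = config.validation_config(trained_observers=registry)
        clean, included, ledger = validation.validate(
            population.trimming, population.rosters, vcfg)
        if clean.empty:
            log.warning("validation produced an empty record set")

    with _stage("kpi"):
        keep = population.rosters["herd_id"].isin(included)
        rosters = population.rosters[keep]
        loco = population.locomotion[population.locomotion["herd_id"].isin(included)]
        culls = population.culling[population.culling["herd_id"].isin(included)]
        kpis = kpi_mod.compute_herd_kpis(
            clean, loco, rosters, culls, year=config.year,
            mode=config.counting_mode,
            farmer_default_severity=config.farmer_default_severity,
            dd_min_affected=config.dd_endemic_min_affected)

    with _stage("benchmark"):
        tables = benchmarking.build_benchmark_tables(kpis)

    report = report_md = None
    with _stage("report"):
        if config.my_farm is not None:
            report = benchmarking.my_farm_report(config.my_farm, kpis, tables)
            report_md = benchmarking.render_report_markdown(report, config.my_farm)

    result = PipelineResult(population, kappas, registry, clean, included,
                            ledger, kpis, tables, report, report_md)
    if outdir is not None:
        result.artifacts = _persist(result, outdir)
    return result


def _persist(result: PipelineResult, outdir) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _save(name, writer):
        path = os.path.join(outdir, name)
        writer(path)
        paths[name] = path

    _save("clean_records.csv", lambda p: write_stream(result.clean_records, p, "trimming"))
    _save("ledger_records.csv", lambda p: write_frame(result.ledger.records, p))
    _save("ledger_herds.csv", lambda p: write_frame(result.ledger.herds, p))
    _save("herd_kpis.csv", lambda p: write_frame(
        result.herd_kpis.reset_index(), p))
    _save("benchmark.csv", lambda p: write_frame(
        benchmarking.tables_to_frame(result.benchmark_tables), p))
    _save("included_herds.csv", lambda p: write_frame(
        pd.DataFrame({"herd_id": sorted(result.included_herds)}), p))
    _save("summary.json", lambda p: _write_json(result.ledger.summary(), p))
    if result.observer_kappas is not None:
        _save("observer_kappas.csv", lambda p: write_frame(result.observer_kappas, p))
    if result.report is not None:
        _save("my_farm_report.csv", lambda p: write_frame(result.report, p))
        _save("my_farm_report.md", lambda p: _write_text(result.report_markdown, p))
    return paths


def _write_json(payload: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _write_text(text: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(text)
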