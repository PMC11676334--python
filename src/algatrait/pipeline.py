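"""End-to-end orchestration: configuration, input validation, stage
execution and report assembly.

A run is described by a :class:`RunConfig` (stage input paths plus options).
``run_characterization`` executes the requested stages in dependency order,
collects per-stage result tables, and writes them as CSV files next to a
JSON manifest recording the configuration hash and package version — the
same inputs and config always reproduce the same report files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .biodiesel import STANDARDS, check_compliance, evaluate_properties
from .fame import FAMEError, parse_fame_label, read_fame_csv
from .growth import (
    GrowthError,
    build_condition_grid,
    classify_growth,
    find_optimum,
    read_growth_csv,
    read_plate_csv,
)
from .markers import MarkerError, compare_pair, read_fasta_pair
from .quant import (
    QuantError,
    match_peaks_by_rt,
    quantify,
    read_peaks_csv,
    read_standards_csv,
)

logger = logging.getLogger("algatrait")

STAGES = ("biodiesel", "growth", "quant", "markers")


@dataclass
class RunConfig:
    """Paths and options for a characterization run.

    Only stages whose inputs are provided are executed. All thresholds and
    flags carry the library defaults unless overridden.
    """

    output_dir: Path
    fame_csv: Path | None = None
    growth_csv: Path | None = None
    plate_csv: Path | None = None
    plate_duration_days: float = 3.0
    peaks_csv: Path | None = None
    standards_csv: Path | None = None
    extract_mass_mg: float = 10.0
    extract_fraction: float = 1.0
    fasta_pairs: tuple[Path, ...] = ()
    normalize_fame: bool = False
    standards_selection: tuple[str, ...] = ("en14214", "astm")
    growth_threshold_fold: float = 1.2
    plateau_fraction: float = 0.9
    rt_tolerance: float = 0.2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["output_dir"] = Path(raw["output_dir"])
        for key in ("fame_csv", "growth_csv", "plate_csv", "peaks_csv",
                    "standards_csv"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        if raw.get("fasta_pairs"):
            raw["fasta_pairs"] = tuple(Path(p) for p in raw["fasta_pairs"])
        if raw.get("standards_selection"):
            raw["standards_selection"] = tuple(raw["standards_selection"])
        return cls(**raw)

    def requested_stages(self) -> list[str]:
        stages = []
        if self.fame_csv:
            stages.append("biodiesel")
        if self.growth_csv or self.plate_csv:
            stages.append("growth")
        if self.peaks_csv and self.standards_csv:
            stages.append("quant")
        if self.fasta_pairs:
            stages.append("markers")
        return stages

    def config_hash(self) -> str:
        payload = {
            k: str(v) for k, v in sorted(self.__dict__.items())
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StudyReport:
    """Per-stage result tables plus the reproducibility manifest."""

    tables: dict[str, pd.DataFrame]
    manifest: dict
    failed_stages: dict[str, str] = field(default_factory=dict)

    @property
    def succeeded(self) -> bool:
        return not self.failed_stages


@dataclass(frozen=True)
class ValidationFinding:
    """One schema or content problem in an input file."""

    path: str
    message: str


def validate_inputs(config: RunConfig) -> list[ValidationFinding]:
    """Schema-check every configured input file without mutating anything.

    Returns row/column-level findings; unreadable files are listed as
    findings, never raised.
    """
    findings: list[ValidationFinding] = []

    def check(path: Path | None, fn) -> None:
        if path is None:
            return
        try:
            fn(path)
        except Exception as exc:  # reported, not thrown
            findings.append(ValidationFinding(str(path), str(exc)))

    def check_fame(path: Path) -> None:
        df = pd.read_csv(path)
        missing = {"label", "weight_percent"} - set(df.columns)
        if missing:
            raise FAMEError(f"missing column(s) {sorted(missing)}")
        seen: dict[tuple, int] = {}
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            try:
                acid = parse_fame_label(str(row.label))
            except FAMEError as exc:
                findings.append(ValidationFinding(str(path), f"row {row_no}: {exc}"))
                continue
            if acid.key in seen:
                findings.append(
                    ValidationFinding(
                        str(path),
                        f"row {row_no}: duplicate component {acid} "
                        f"(first at row {seen[acid.key]})",
                    )
                )
            seen[acid.key] = row_no
            if not (0 <= float(row.weight_percent) <= 100):
                findings.append(
                    ValidationFinding(
                        str(path),
                        f"row {row_no}: weight percent {row.weight_percent} "
                        "outside [0, 100]",
                    )
                )

    def check_growth(path: Path) -> None:
        df = pd.read_csv(path)
        required = {"condition", "time_d", "value", "measure_kind"}
        missing = required - set(df.columns)
        if missing:
            raise GrowthError(f"missing column(s) {sorted(missing)}")
        for cond, grp in df.groupby("condition"):
            times = grp["time_d"].to_numpy()
            if (times[1:] <= times[:-1]).any():
                findings.append(
                    ValidationFinding(
                        str(path),
                        f"condition {cond!r}: times not strictly increasing",
                    )
                )

    def check_plate(path: Path) -> None:
        read_plate_csv(path)

    def check_peaks(path: Path) -> None:
        read_peaks_csv(path)

    def check_standards(path: Path) -> None:
        read_standards_csv(path)

    check(config.fame_csv, check_fame)
    check(config.growth_csv, check_growth)
    check(config.plate_csv, check_plate)
    check(config.peaks_csv, check_peaks)
    check(config.standards_csv, check_standards)
    for fasta in config.fasta_pairs:
        check(fasta, read_fasta_pair)
    return findings


def _biodiesel_stage(config: RunConfig) -> pd.DataFrame:
    from .fame import normalize_profile

    profile = read_fame_csv(config.fame_csv)
    if config.normalize_fame:
        profile = normalize_profile(profile)
    props = evaluate_properties(profile)
    rows = [dict(section="properties", **props.as_dict())]
    for key in config.standards_selection:
        report = check_compliance(props, STANDARDS[key])
        for crit in report.criteria:
            rows.append(
                {
                    "section": "compliance",
                    "standard": crit.standard,
                    "criterion": crit.criterion,
                    "value": crit.value,
                    "bound": crit.bound,
                    "passed": crit.passed,
                }
            )
    return pd.DataFrame(rows)


def _growth_stage(config: RunConfig) -> pd.DataFrame:
    rows = []
    if config.growth_csv:
        for series in read_growth_csv(config.growth_csv):
            verdict = classify_growth(series, config.growth_threshold_fold)
            rows.append(
                {
                    "section": "series",
                    "condition": series.condition,
                    "classification": verdict,
                }
            )
    if config.plate_csv:
        grid = build_condition_grid(
            read_plate_csv(config.plate_csv), config.plate_duration_days
        )
        opt = find_optimum(grid, config.plateau_fraction)
        rows.append(
            {
                "section": "optimum",
                "temperature_c": opt.temperature,
                "pfd": opt.pfd,
                "mu_max_per_day": opt.mu_max,
                "temperature_range": f"{opt.temperature_range[0]}-{opt.temperature_range[1]}",
                "pfd_range": f"{opt.pfd_range[0]}-{opt.pfd_range[1]}",
            }
        )
    return pd.DataFrame(rows)


def _quant_stage(config: RunConfig) -> pd.DataFrame:
    curves = read_standards_csv(config.standards_csv)
    samples = read_peaks_csv(config.peaks_csv)
    rows = []
    for sample, peaks in samples.items():
        labeled = match_peaks_by_rt(
            peaks, list(curves.values()), config.rt_tolerance
        )
        for peak in labeled:
            if peak.analyte is None:
                rows.append(
                    {
                        "sample": sample,
                        "analyte": None,
                        "rt_min": peak.retention_time,
                        "area": peak.area,
                        "amount_mg_per_g": None,
                        "flag": "unmatched",
                    }
                )
                continue
            result = quantify(
                peak,
                curves[peak.analyte],
                config.extract_mass_mg,
                config.extract_fraction,
            )
            flag = (
                "below_detection"
                if result.below_detection
                else "extrapolated" if result.extrapolated else ""
            )
            rows.append(
                {
                    "sample": sample,
                    "analyte": peak.analyte,
                    "rt_min": peak.retention_time,
                    "area": peak.area,
                    "amount_mg_per_g": result.amount_mg_per_g,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def _markers_stage(config: RunConfig) -> pd.DataFrame:
    rows = []
    for path in config.fasta_pairs:
        pair = read_fasta_pair(path)
        result = compare_pair(pair)
        rows.append(
            {
                "file": str(path),
                "query": pair.query_id,
                "reference": pair.reference_id,
                "substitutions": result.substitutions,
                "gap_columns": result.gap_columns,
                "compared_length": result.compared_length,
                "dissimilarity_percent": result.dissimilarity_rounded,
            }
        )
    return pd.DataFrame(rows)


_STAGE_FNS = {
    "biodiesel": _biodiesel_stage,
    "growth": _growth_stage,
    "quant": _quant_stage,
    "markers": _markers_stage,
}


def run_characterization(config: RunConfig) -> StudyReport:
    """Execute all requested stages; write CSV tables and a JSON manifest.

    A stage error aborts that stage only (logged, recorded in
    ``failed_stages``); the others still run. An empty stage list is a
    successful empty report.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    failed: dict[str, str] = {}
    for stage in config.requested_stages():
        logger.info("[%s] running", stage)
        try:
            table = _STAGE_FNS[stage](config)
        except Exception as exc:
            logger.error("[%s] failed: %s", stage, exc)
            failed[stage] = str(exc)
            continue
        tables[stage] = table
        table.to_csv(out_dir / f"{stage}.csv", index=False)
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages_run": sorted(tables),
        "stages_failed": failed,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return StudyReport(tables=tables, manifest=manifest, failed_stages=failed)
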