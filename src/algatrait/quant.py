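"""External-standard calibration and chromatogram peak quantification.

Analyte amounts are recovered from peak areas by a linear calibration
(area = slope·amount + intercept) fitted to external standards, after
assigning peaks to analytes by retention-time proximity. Amounts are
normalized to mg per g dry weight using the extracted biomass:

    amount (mg/g DW) = ((area − intercept)/slope) / (extract_mass · fraction) · 1000

with extract_mass in mg DW and ``fraction`` the portion of the extract
injected/analyzed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class QuantError(ValueError):
    """Invalid calibration or quantification input."""


@dataclass(frozen=True)
class Peak:
    """A chromatogram peak: retention time (min) and integrated area."""

    retention_time: float
    area: float
    analyte: str | None = None

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise QuantError(
                f"retention time must be > 0 min, got {self.retention_time}"
            )
        if self.area < 0:
            raise QuantError(f"peak area must be >= 0, got {self.area}")


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted external-standard response line for one analyte."""

    analyte: str
    slope: float  # area per mg analyte
    intercept: float  # area
    reference_rt: float  # minutes
    r_squared: float = float("nan")
    residual_sd: float = float("nan")
    amount_range: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise QuantError(f"calibration slope must be > 0, got {self.slope}")

    def area_for(self, amount_mg: float) -> float:
        """Forward model: predicted area for a given analyte amount (mg)."""
        return self.slope * amount_mg + self.intercept

    @property
    def detection_area(self) -> float:
        """Area below which a signal is called below detection.

        intercept + 3·residual SD when the fit has residual statistics;
        the bare intercept otherwise.
        """
        if math.isfinite(self.residual_sd):
            return self.intercept + 3.0 * self.residual_sd
        return self.intercept


@dataclass(frozen=True)
class QuantResult:
    """A quantified analyte amount with quality flags."""

    analyte: str
    amount_mg_per_g: float
    below_detection: bool = False
    extrapolated: bool = False


def fit_calibration(
    standards: Sequence[tuple[float, float]],
    analyte: str,
    reference_rt: float,
    through_origin: bool = False,
) -> CalibrationCurve:
    """Fit area = slope·amount (+ intercept) to (amount mg, area) standards.

    Ordinary least squares by default (>= 2 points with distinct amounts);
    ``through_origin`` forces a zero intercept and accepts a single point.
    """
    if not standards:
        raise QuantError(f"{analyte}: no calibration standards")
    amounts = np.array([s[0] for s in standards], dtype=float)
    areas = np.array([s[1] for s in standards], dtype=float)
    if through_origin:
        denom = float(np.dot(amounts, amounts))
        if denom == 0:
            raise QuantError(f"{analyte}: all standard amounts are zero")
        slope = float(np.dot(amounts, areas)) / denom
        intercept = 0.0
        fitted = slope * amounts
        dof = len(standards) - 1
    else:
        if len(standards) < 2:
            raise QuantError(
                f"{analyte}: need >= 2 standards for a line with intercept"
            )
        if np.ptp(amounts) == 0:
            raise QuantError(
                f"{analyte}: degenerate design, all standard amounts equal"
            )
        fit = stats.linregress(amounts, areas)
        slope, intercept = float(fit.slope), float(fit.intercept)
        fitted = slope * amounts + intercept
        dof = len(standards) - 2
    resid = areas - fitted
    ss_tot = float(np.sum((areas - areas.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    resid_sd = (
        float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else float("nan")
    )
    return CalibrationCurve(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        reference_rt=reference_rt,
        r_squared=r2,
        residual_sd=resid_sd,
        amount_range=(float(amounts.min()), float(amounts.max())),
    )


def match_peaks_by_rt(
    peaks: Sequence[Peak],
    curves: Sequence[CalibrationCurve],
    tolerance: float = 0.2,
) -> list[Peak]:
    """Assign each peak to the nearest reference retention time within tolerance.

    Assignment is one-to-one per chromatogram: each analyte claims its closest
    peak (greedy, smallest RT distance first). Unmatched peaks keep
    ``analyte=None``. Ties between equidistant references break toward the
    lower reference RT; the result order follows the input peaks.
    """
    if tolerance <= 0:
        raise QuantError(f"tolerance must be > 0 min, got {tolerance}")
    # All candidate (distance, ref_rt, analyte, peak index) pairs inside
    # tolerance, best first; lower reference RT wins ties.
    candidates = sorted(
        (abs(p.retention_time - c.reference_rt), c.reference_rt, c.analyte, i)
        for i, p in enumerate(peaks)
        for c in curves
        if abs(p.retention_time - c.reference_rt) <= tolerance
    )
    assigned: dict[int, str] = {}
    used_analytes: set[str] = set()
    for _, _, analyte, i in candidates:
        if i in assigned or analyte in used_analytes:
            continue
        assigned[i] = analyte
        used_analytes.add(analyte)
    return [
        replace(p, analyte=assigned.get(i)) for i, p in enumerate(peaks)
    ]


def quantify(
    peak: Peak,
    curve: CalibrationCurve,
    extract_mass_mg: float,
    extract_fraction: float = 1.0,
) -> QuantResult:
    """Convert a peak area to mg analyte per g dry weight.

    ``extract_mass_mg`` is the dry biomass extracted; ``extract_fraction``
    the portion of the extract represented by the injection. Areas at or
    below the curve's detection area yield amount 0 with
    ``below_detection``; amounts outside the standard range are flagged
    ``extrapolated``.
    """
    if extract_mass_mg <= 0:
        raise QuantError(
            f"extract mass must be > 0 mg, got {extract_mass_mg}"
        )
    if not (0 < extract_fraction <= 1):
        raise QuantError(
            f"extract fraction must be in (0, 1], got {extract_fraction}"
        )
    if peak.area <= curve.detection_area:
        return QuantResult(curve.analyte, 0.0, below_detection=True)
    amount_mg = (peak.area - curve.intercept) / curve.slope
    lo, hi = curve.amount_range
    extrapolated = not (lo <= amount_mg <= hi)
    mg_per_g = amount_mg / (extract_mass_mg * extract_fraction) * 1000.0
    return QuantResult(curve.analyte, mg_per_g, extrapolated=extrapolated)


def read_peaks_csv(path: str | Path) -> dict[str, list[Peak]]:
    """Read peaks grouped by sample from ``sample,rt_min,area`` columns."""
    df = pd.read_csv(path)
    missing = {"sample", "rt_min", "area"} - set(df.columns)
    if missing:
        raise QuantError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, list[Peak]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.sample), []).append(
            Peak(float(r.rt_min), float(r.area))
        )
    return out


def read_standards_csv(
    path: str | Path, through_origin: bool = False
) -> dict[str, CalibrationCurve]:
    """Fit one curve per analyte from ``analyte,amount_mg,area,reference_rt``."""
    df = pd.read_csv(path)
    required = {"analyte", "amount_mg", "area", "reference_rt"}
    missing = required - set(df.columns)
    if missing:
        raise QuantError(f"{path}: missing column(s) {sorted(missing)}")
    curves = {}
    for analyte, grp in df.groupby("analyte", sort=False):
        pts = [(float(r.amount_mg), float(r.area)) for r in grp.itertuples(index=False)]
        ref_rt = float(grp["reference_rt"].iloc[0])
        curves[str(analyte)] = fit_calibration(
            pts, str(analyte), ref_rt, through_origin=through_origin
        )
    return curves
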