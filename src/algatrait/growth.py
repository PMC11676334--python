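"""Growth-rate analysis: specific growth rates, salinity time-series
summaries, temperature × light response grids and optimum detection, and
lipid productivity.

The specific growth rate is the exponential rate constant

    μ = (ln A2 − ln A1) / (T2 − T1)     [per day]

between two density (or OD600) readings. A screening plate — one
(start, end) OD pair per (temperature, photon flux density) cell over a
fixed incubation — becomes a grid of μ values whose argmax locates the
growth optimum, with a plateau mask marking near-optimal conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd


class GrowthError(ValueError):
    """Invalid growth-analysis input."""


MeasureKind = Literal["density", "od600"]


@dataclass(frozen=True)
class GrowthObservation:
    """One timepoint: days since inoculation and a biomass proxy value."""

    time: float  # days
    value: float  # cells/mL or OD600
    measure_kind: MeasureKind = "density"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise GrowthError(f"time must be >= 0, got {self.time}")
        if self.value < 0:
            raise GrowthError(f"value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class GrowthSeries:
    """A density-vs-time record for one culture condition (e.g. a salinity)."""

    condition: str
    observations: tuple[GrowthObservation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        times = [o.time for o in self.observations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise GrowthError(
                f"series {self.condition!r}: times must be strictly increasing"
            )
        kinds = {o.measure_kind for o in self.observations}
        if len(kinds) > 1:
            raise GrowthError(
                f"series {self.condition!r}: mixed measure kinds {kinds}"
            )

    def __len__(self) -> int:
        return len(self.observations)


def specific_growth_rate(a1: float, a2: float, t1: float, t2: float) -> float:
    """μ = (ln a2 − ln a1)/(t2 − t1), per day for times in days.

    Positive for growth, negative for decline, zero iff a2 == a1.
    """
    if a1 <= 0 or a2 <= 0:
        raise GrowthError("densities must be strictly positive")
    if t2 <= t1:
        raise GrowthError(f"need t2 > t1, got t1={t1}, t2={t2}")
    return (math.log(a2) - math.log(a1)) / (t2 - t1)


def fold_change(series: GrowthSeries, at_time: float) -> float:
    """Ratio of the latest value at or before ``at_time`` to the initial value.

    The earliest observation is the baseline (time 0 when present).
    """
    if len(series) == 0:
        raise GrowthError("empty series")
    initial = series.observations[0]
    if initial.value == 0:
        raise GrowthError("initial value is zero; fold change undefined")
    candidates = [o for o in series.observations if o.time <= at_time]
    if not candidates:
        raise GrowthError(
            f"no observation at or before t={at_time} in {series.condition!r}"
        )
    return candidates[-1].value / initial.value


def classify_growth(
    series: GrowthSeries, threshold_fold: float = 1.2
) -> Literal["growth", "no_growth"]:
    """Call growth when final/initial fold change >= threshold (inclusive)."""
    if len(series) < 2:
        raise GrowthError("need at least two observations to classify growth")
    final_time = series.observations[-1].time
    return (
        "growth"
        if fold_change(series, final_time) >= threshold_fold
        else "no_growth"
    )


@dataclass(frozen=True)
class ConditionGrid:
    """Specific growth rates over a temperature × photon-flux-density lattice.

    ``mu[i, j]`` is the rate at ``temperatures[i]``, ``pfds[j]``; missing
    cells are NaN.
    """

    temperatures: tuple[float, ...]  # °C, strictly increasing
    pfds: tuple[float, ...]  # µmol photons m^-2 s^-1, strictly increasing
    mu: np.ndarray  # per day

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures", tuple(self.temperatures))
        object.__setattr__(self, "pfds", tuple(self.pfds))
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        for name, axis in (("temperatures", self.temperatures),
                           ("pfds", self.pfds)):
            if any(b <= a for a, b in zip(axis, axis[1:])):
                raise GrowthError(f"{name} must be strictly increasing")
        if self.mu.shape != (len(self.temperatures), len(self.pfds)):
            raise GrowthError(
                f"mu shape {self.mu.shape} does not match axes "
                f"({len(self.temperatures)}, {len(self.pfds)})"
            )

    def to_frame(self) -> pd.DataFrame:
        """Grid as a DataFrame with temperature rows and PFD columns."""
        return pd.DataFrame(
            self.mu, index=list(self.temperatures), columns=list(self.pfds)
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "temperature_c"
        df.to_csv(path)


@dataclass(frozen=True)
class GrowthOptimum:
    """The grid cell with the highest μ, plus the near-optimal plateau."""

    temperature: float
    pfd: float
    mu_max: float
    plateau_mask: np.ndarray  # boolean, same shape as the grid
    temperature_range: tuple[float, float]  # plateau extent on the T axis
    pfd_range: tuple[float, float]  # plateau extent on the PFD axis


def build_condition_grid(
    plate: Iterable[tuple[float, float, float, float]], duration: float
) -> ConditionGrid:
    """Assemble a μ grid from (temperature, pfd, od_start, od_end) records.

    ``duration`` is the incubation length in days (a 72 h screen is 3.0).
    Cells absent from the plate are NaN; duplicate cells are an error.
    """
    if duration <= 0:
        raise GrowthError(f"duration must be > 0 days, got {duration}")
    records = list(plate)
    if not records:
        raise GrowthError("empty plate")
    seen: set[tuple[float, float]] = set()
    for t, i, _, _ in records:
        if (t, i) in seen:
            raise GrowthError(f"duplicate plate cell at T={t}, PFD={i}")
        seen.add((t, i))
    temps = tuple(sorted({r[0] for r in records}))
    pfds = tuple(sorted({r[1] for r in records}))
    mu = np.full((len(temps), len(pfds)), np.nan)
    t_idx = {t: k for k, t in enumerate(temps)}
    i_idx = {i: k for k, i in enumerate(pfds)}
    for t, i, od0, od1 in records:
        mu[t_idx[t], i_idx[i]] = specific_growth_rate(od0, od1, 0.0, duration)
    return ConditionGrid(temps, pfds, mu)


def find_optimum(
    grid: ConditionGrid, plateau_fraction: float = 0.9
) -> GrowthOptimum:
    """Locate the grid argmax and the plateau of near-optimal cells.

    The plateau holds every finite cell with μ >= plateau_fraction · μ_max.
    Ties at the maximum break toward lower temperature, then lower PFD
    (cheaper cultivation). Reported plateau ranges are the bounding extents
    of the mask on each axis.
    """
    if not (0.0 < plateau_fraction <= 1.0):
        raise GrowthError("plateau_fraction must be in (0, 1]")
    mu = grid.mu
    if not np.isfinite(mu).any():
        raise GrowthError("grid has no finite entries")
    mu_max = np.nanmax(mu)
    # np.argwhere scans row-major: lowest temperature first, then lowest PFD,
    # which is exactly the documented tie-break.
    ti, pi = np.argwhere(mu == mu_max)[0]
    mask = np.isfinite(mu) & (mu >= plateau_fraction * mu_max)
    t_hit = np.array(grid.temperatures)[mask.any(axis=1)]
    p_hit = np.array(grid.pfds)[mask.any(axis=0)]
    return GrowthOptimum(
        temperature=grid.temperatures[ti],
        pfd=grid.pfds[pi],
        mu_max=float(mu_max),
        plateau_mask=mask,
        temperature_range=(float(t_hit.min()), float(t_hit.max())),
        pfd_range=(float(p_hit.min()), float(p_hit.max())),
    )


def lipid_productivity(cl: float, t: float) -> float:
    """Lipid productivity (g L⁻¹ d⁻¹) = lipid concentration CL (g/L) / t (days)."""
    if cl < 0:
        raise GrowthError(f"lipid concentration must be >= 0, got {cl}")
    if t <= 0:
        raise GrowthError(f"cultivation time must be > 0 days, got {t}")
    return cl / t


def read_growth_csv(path: str | Path) -> list[GrowthSeries]:
    """Read series from a CSV with columns ``condition,time_d,value,measure_kind``."""
    df = pd.read_csv(path)
    required = {"condition", "time_d", "value", "measure_kind"}
    missing = required - set(df.columns)
    if missing:
        raise GrowthError(f"{path}: missing column(s) {sorted(missing)}")
    series = []
    for cond, grp in df.groupby("condition", sort=False):
        obs = tuple(
            GrowthObservation(float(r.time_d), float(r.value), str(r.measure_kind))
            for r in grp.itertuples(index=False)
        )
        series.append(GrowthSeries(str(cond), obs))
    return series


def read_plate_csv(path: str | Path) -> list[tuple[float, float, float, float]]:
    """Read plate records from ``temperature_c,pfd,od_start,od_end`` columns."""
    df = pd.read_csv(path)
    required = {"temperature_c", "pfd", "od_start", "od_end"}
    missing = required - set(df.columns)
    if missing:
        raise GrowthError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        (float(r.temperature_c), float(r.pfd), float(r.od_start), float(r.od_end))
        for r in df.itertuples(index=False)
    ]
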