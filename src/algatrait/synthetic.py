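"""Seeded generators emulating every input the analysis pipeline consumes.

Each generator returns both the observable records (what a lab instrument
would produce) and the hidden ground truth behind them, so pipeline stages
can be tested as estimator-vs-truth recovery problems. All randomness flows
through one :class:`numpy.random.Generator` seeded from the config; a fixed
seed reproduces outputs exactly.

Model conventions (generator-side; the analysis stages fit no such model):

* FAME compositions are symmetric-Dirichlet weights scaled to a configured
  total below 100% (published profiles rarely close to 100).
* The temperature × light growth surface is a Gaussian thermal performance
  curve times a Steele photoinhibition light curve:
  μ(T, I) = μ_max · exp(−((T − T_opt)/σ_T)²) · (I/I_opt) · exp(1 − I/I_opt).
* Measurement noise is multiplicative lognormal on densities/ODs and
  additive Gaussian on chromatogram peak areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fame import FattyAcid, FAMEComponent, FAMEProfile, parse_fame_label
from .growth import GrowthObservation, GrowthSeries
from .markers import MarkerAlignmentPair
from .quant import CalibrationCurve, Peak, fit_calibration

# The 11-component composition of the halotolerant Dunaliella isolate at
# 0.5 M NaCl, used as the default generator pool and as the noise-free
# degenerate mode.
REFERENCE_FAME_ROWS: tuple[tuple[str, float], ...] = (
    ("Myristic acid (C14:0)", 0.49),
    ("Palmitic acid (C16:0)", 21.06),
    ("Palmitoleic acid (C16:1 w-7)", 1.63),
    ("Hexadecadienoic acid (C16:2 w-6)", 1.08),
    ("Hexadecatrienoic acid (C16:3 w-3)", 2.75),
    ("Hexadecatetraenoic acid (C16:4 w-3)", 13.23),
    ("Stearic acid (C18:0)", 0.53),
    ("Oleic acid (C18:1 w-9)", 2.77),
    ("Linoleic acid (C18:2 w-6)", 6.81),
    ("gamma-linolenic acid (C18:3 w-6)", 3.84),
    ("alpha-linolenic acid (C18:3 w-3)", 31.55),
)


def reference_fame_profile() -> FAMEProfile:
    """The published 11-component profile as a ready-made FAMEProfile."""
    comps = tuple(
        FAMEComponent(parse_fame_label(lbl), pct)
        for lbl, pct in REFERENCE_FAME_ROWS
    )
    return FAMEProfile(comps, label="D. salina DSTA20, 0.5 M NaCl")


@dataclass(frozen=True)
class FAMEGenConfig:
    """Random compositional FAME profile settings.

    ``total_percent`` defaults to the published profile's 85.74 (the
    remainder being unidentified peaks); ``concentration`` is the symmetric
    Dirichlet parameter (1.0 = uniform over the simplex).
    """

    seed: int = 0
    total_percent: float = 85.74
    concentration: float = 1.0
    pool: tuple[str, ...] = tuple(lbl for lbl, _ in REFERENCE_FAME_ROWS)


def generate_fame_profile(config: FAMEGenConfig = FAMEGenConfig()) -> FAMEProfile:
    """Draw a random profile: Dirichlet weights over the acid pool, scaled
    to ``total_percent``."""
    if len(config.pool) < 1:
        raise ValueError("acid pool must hold at least one identity")
    rng = np.random.default_rng(config.seed)
    weights = rng.dirichlet(np.full(len(config.pool), config.concentration))
    comps = tuple(
        FAMEComponent(parse_fame_label(lbl), float(w * config.total_percent))
        for lbl, w in zip(config.pool, weights)
    )
    return FAMEProfile(comps, label=f"synthetic profile seed={config.seed}")


# 8 temperatures x 12 light levels, emulating a 96-well screening plate over
# the 5-40 °C / 0-350 µmol ranges; both axes contain the published optimum
# (21 °C, 88 µmol photons m^-2 s^-1).
DEFAULT_TEMPERATURES = (5.0, 10.0, 15.0, 18.0, 21.0, 27.0, 34.0, 40.0)
DEFAULT_PFDS = (
    0.0, 15.0, 30.0, 60.0, 88.0, 120.0, 160.0, 200.0, 245.0, 280.0, 315.0, 350.0
)


@dataclass(frozen=True)
class GrowthGridConfig:
    """Temperature × light screening-plate simulation settings.

    The true surface is Gaussian-thermal × Steele-light with maximum
    ``mu_max`` (d⁻¹) at (``t_opt`` °C, ``i_opt`` µmol m⁻² s⁻¹) and thermal
    breadth ``sigma_t`` (°C). ``noise_sigma`` is the lognormal sigma applied
    multiplicatively to the end-point OD.
    """

    seed: int = 0
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    pfds: tuple[float, ...] = DEFAULT_PFDS
    mu_max: float = 0.5
    t_opt: float = 21.0
    sigma_t: float = 8.0
    i_opt: float = 88.0
    od_start: float = 0.05
    duration_days: float = 3.0
    noise_sigma: float = 0.0


def true_growth_surface(
    config: GrowthGridConfig, temperature: float, pfd: float
) -> float:
    """μ(T, I): Gaussian thermal response × Steele photoinhibition curve."""
    thermal = math.exp(-(((temperature - config.t_opt) / config.sigma_t) ** 2))
    rel_i = pfd / config.i_opt
    light = rel_i * math.exp(1.0 - rel_i)
    return config.mu_max * thermal * light


def generate_growth_grid(
    config: GrowthGridConfig = GrowthGridConfig(),
) -> tuple[list[tuple[float, float, float, float]], np.ndarray]:
    """Simulate a screening plate: one (T, PFD, od_start, od_end) record per
    cell, plus the hidden true μ surface (temperature rows × PFD columns).

    ``od_end = od_start · exp(μ·duration) · exp(ε)`` with
    ε ~ Normal(0, noise_sigma).
    """
    rng = np.random.default_rng(config.seed)
    truth = np.array(
        [
            [true_growth_surface(config, t, i) for i in config.pfds]
            for t in config.temperatures
        ]
    )
    records = []
    for ti, t in enumerate(config.temperatures):
        for ii, i in enumerate(config.pfds):
            od_end = config.od_start * math.exp(
                truth[ti, ii] * config.duration_days
            )
            if config.noise_sigma > 0:
                od_end *= math.exp(rng.normal(0.0, config.noise_sigma))
            records.append((t, i, config.od_start, od_end))
    return records, truth


@dataclass(frozen=True)
class GrowthSeriesConfig:
    """Salinity time-course simulation settings.

    ``conditions`` maps a condition label to its true specific growth rate
    (d⁻¹); μ <= 0 conditions emulate no-growth salinities. Defaults emulate
    a 21-day salinity screen where the best condition roughly quintuples by
    day 14 (μ = ln 5 / 14) and growth fails at 0 M NaCl.
    """

    seed: int = 0
    conditions: tuple[tuple[str, float], ...] = (
        ("0.0M", 0.0),
        ("0.1M", 0.04),
        ("0.25M", 0.08),
        ("0.5M", math.log(5.0) / 14.0),
        ("1.0M", 0.09),
        ("1.5M", 0.06),
        ("2.0M", 0.05),
    )
    initial_density: float = 7.08e3  # cells/mL
    duration_days: int = 21
    noise_sigma: float = 0.0


def generate_growth_series(
    config: GrowthSeriesConfig = GrowthSeriesConfig(),
) -> tuple[list[GrowthSeries], dict[str, float]]:
    """Simulate daily-counted exponential trajectories per condition.

    Returns the series plus the hidden true μ per condition.
    """
    rng = np.random.default_rng(config.seed)
    truth = dict(config.conditions)
    series = []
    for label, mu in config.conditions:
        obs = []
        for day in range(config.duration_days + 1):
            value = config.initial_density * math.exp(mu * day)
            if config.noise_sigma > 0 and day > 0:
                value *= math.exp(rng.normal(0.0, config.noise_sigma))
            obs.append(GrowthObservation(float(day), value, "density"))
        series.append(GrowthSeries(label, tuple(obs)))
    return series, truth


@dataclass(frozen=True)
class AnalyteSpec:
    """One analyte's chromatographic behaviour for the simulator."""

    name: str
    reference_rt: float  # minutes
    response_factor: float  # area per mg
    intercept: float = 0.0  # baseline area offset


#: Default carotenoid panel: retention times from the published HPLC runs,
#: response factor for β-carotene from its printed area/amount ratio.
DEFAULT_ANALYTES = (
    AnalyteSpec("lutein", 7.59, 85.0),
    AnalyteSpec("zeaxanthin", 8.45, 75.0),
    AnalyteSpec("beta-carotene", 17.05, 83.0),
)


@dataclass(frozen=True)
class ChromatogramConfig:
    """External-standard + sample chromatogram simulation settings."""

    seed: int = 0
    analytes: tuple[AnalyteSpec, ...] = DEFAULT_ANALYTES
    standard_amounts: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0)  # mg
    amount_range: tuple[float, float] = (0.5, 8.0)  # hidden sample amounts, mg
    area_noise_sd: float = 0.0  # additive, area units
    rt_jitter: float = 0.0  # uniform half-width, minutes


def generate_chromatogram(
    config: ChromatogramConfig = ChromatogramConfig(),
) -> tuple[
    dict[str, list[tuple[float, float]]],
    list[Peak],
    dict[str, float],
]:
    """Simulate calibration standards and one sample chromatogram.

    Returns ``(standards, peaks, hidden_amounts)`` where ``standards`` maps
    analyte -> [(amount mg, area), ...] on the configured response line plus
    noise, ``peaks`` are the sample peaks (RT jittered uniformly within
    ±rt_jitter), and ``hidden_amounts`` are the true mg of each analyte
    encoded in the peak areas.
    """
    rng = np.random.default_rng(config.seed)
    standards: dict[str, list[tuple[float, float]]] = {}
    for spec in config.analytes:
        pts = []
        for amount in config.standard_amounts:
            area = spec.response_factor * amount + spec.intercept
            if config.area_noise_sd > 0:
                area += rng.normal(0.0, config.area_noise_sd)
            pts.append((amount, max(area, 0.0)))
        standards[spec.name] = pts
    peaks = []
    hidden: dict[str, float] = {}
    lo, hi = config.amount_range
    for spec in config.analytes:
        amount = float(rng.uniform(lo, hi))
        hidden[spec.name] = amount
        area = spec.response_factor * amount + spec.intercept
        if config.area_noise_sd > 0:
            area += rng.normal(0.0, config.area_noise_sd)
        rt = spec.reference_rt
        if config.rt_jitter > 0:
            rt += float(rng.uniform(-config.rt_jitter, config.rt_jitter))
        peaks.append(Peak(rt, max(area, 0.0)))
    return standards, peaks, hidden


def calibration_curves(
    standards: dict[str, list[tuple[float, float]]],
    analytes: tuple[AnalyteSpec, ...] = DEFAULT_ANALYTES,
    through_origin: bool = False,
) -> dict[str, CalibrationCurve]:
    """Fit one curve per simulated analyte (convenience wrapper)."""
    rt = {a.name: a.reference_rt for a in analytes}
    return {
        name: fit_calibration(pts, name, rt[name], through_origin=through_origin)
        for name, pts in standards.items()
    }


@dataclass(frozen=True)
class SequencePairConfig:
    """Aligned-pair simulation: a random reference plus an edited copy."""

    seed: int = 0
    length: int = 1460
    substitutions: int = 7
    gap_columns: int = 0
    marker: str = "SSU"


def generate_sequence_pair(
    config: SequencePairConfig = SequencePairConfig(),
) -> tuple[MarkerAlignmentPair, dict[str, int]]:
    """Generate an aligned pair with exactly the configured edit counts.

    The reference is uniform random A/C/G/T; the query carries
    ``substitutions`` base changes and ``gap_columns`` one-sided deletions,
    all at distinct columns. Returns the pair and the true counts.
    """
    k, g, length = config.substitutions, config.gap_columns, config.length
    if length < 1:
        raise ValueError("length must be >= 1")
    if k + g > length:
        raise ValueError(
            f"substitutions + gaps ({k + g}) exceed alignment length {length}"
        )
    rng = np.random.default_rng(config.seed)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=length)
    query = ref.copy()
    edit_cols = rng.choice(length, size=k + g, replace=False)
    for col in edit_cols[:k]:
        others = [b for b in "ACGT" if b != ref[col]]
        query[col] = others[rng.integers(0, 3)]
    for col in edit_cols[k:]:
        query[col] = "-"
    pair = MarkerAlignmentPair(
        query_id=f"synthetic-query-seed{config.seed}",
        reference_id=f"synthetic-ref-seed{config.seed}",
        query_seq="".join(query),
        reference_seq="".join(ref),
        marker=config.marker,
    )
    truth = {
        "substitutions": k,
        "gap_columns": g,
        "compared_length": length,
    }
    return pair, truth
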