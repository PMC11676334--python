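"""Empirical biodiesel fuel descriptors from a FAME composition, and
fuel-standard compliance checks.

The seven descriptors are computed from weight percents ``N_i`` (per
component), double-bond counts ``D_i`` and methyl-ester molecular masses
``M_i`` (g/mol) with the standard empirical equations:

    SV   = Σ 560·N_i / M_i                     (saponification value, mg KOH/g)
    IV   = Σ 254·D_i·N_i / M_i                 (iodine value, g I2/100 g)
    DU   = MUFA + 2·PUFA                       (degree of unsaturation)
    LCSF = 0.1·C16:0 + 0.5·C18:0 + 1·C20:0
           + 1.5·C22:0 + 2·C24:0               (long-chain saturation factor)
    CFPP = 3.1417·LCSF − 16.477                (cold filter plugging point, °C)
    CN   = 46.3 + 5458/SV − 0.225·IV           (cetane number)
    OS   = 117.9295/X + 2.5905                 (oxidative stability, h)

where X is the combined weight percent of the C18:2 and C18:3 components.
All values are computed at full precision; round only for presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fame import ClassTotals, FAMEProfile, class_totals, fame_molecular_mass

# Equation constants, kept in one registry so no value is silently re-rounded.
SV_COEFF = 560.0
IV_COEFF = 254.0
CN_INTERCEPT = 46.3
CN_SV_COEFF = 5458.0
CN_IV_COEFF = 0.225
CFPP_SLOPE = 3.1417
CFPP_INTERCEPT = 16.477
OS_NUMERATOR = 117.9295
OS_ASYMPTOTE = 2.5905
#: LCSF weights keyed by saturated chain length.
LCSF_WEIGHTS = {16: 0.1, 18: 0.5, 20: 1.0, 22: 1.5, 24: 2.0}


class BiodieselError(ValueError):
    """Invalid input to a fuel-property computation."""


def saponification_value(profile: FAMEProfile) -> float:
    """SV = Σ 560·N_i/M_i over profile components (mg KOH/g)."""
    if len(profile) == 0:
        raise BiodieselError("saponification value of an empty profile")
    return sum(
        SV_COEFF * c.weight_percent / fame_molecular_mass(c.acid)
        for c in profile
    )


def iodine_value(profile: FAMEProfile) -> float:
    """IV = Σ 254·D_i·N_i/M_i over profile components (g I2/100 g)."""
    if len(profile) == 0:
        raise BiodieselError("iodine value of an empty profile")
    return sum(
        IV_COEFF * c.acid.double_bonds * c.weight_percent
        / fame_molecular_mass(c.acid)
        for c in profile
    )


def degree_of_unsaturation(totals: ClassTotals) -> float:
    """DU = MUFA + 2·PUFA (weight-percent combination, dimensionless)."""
    return totals.mufa_percent + 2.0 * totals.pufa_percent


def long_chain_saturation_factor(profile: FAMEProfile) -> float:
    """Weighted sum of long saturated chains; unsaturates are ignored."""
    lcsf = 0.0
    for comp in profile:
        if comp.acid.double_bonds == 0:
            weight = LCSF_WEIGHTS.get(comp.acid.carbons)
            if weight is not None:
                lcsf += weight * comp.weight_percent
    return lcsf


def cold_filter_plugging_point(lcsf: float) -> float:
    """CFPP (°C) = 3.1417·LCSF − 16.477."""
    return CFPP_SLOPE * lcsf - CFPP_INTERCEPT


def cetane_number(sv: float, iv: float) -> float:
    """CN = 46.3 + 5458/SV − 0.225·IV. Requires SV > 0."""
    if sv <= 0.0:
        raise BiodieselError(f"saponification value must be > 0, got {sv}")
    if iv < 0.0:
        raise BiodieselError(f"iodine value must be >= 0, got {iv}")
    return CN_INTERCEPT + CN_SV_COEFF / sv - CN_IV_COEFF * iv


def oxidative_stability(profile: FAMEProfile, omega6_only: bool = False) -> float:
    """OS (h) = 117.9295/X + 2.5905, X = combined C18:2 + C18:3 weight percent.

    By default X sums every C18:2 and C18:3 isomer regardless of omega class;
    pass ``omega6_only=True`` to restrict to ω-6 isomers (the literature is
    ambiguous on which convention applies).

    Raises
    ------
    BiodieselError
        If X = 0 — the formula is undefined, report as not computable.
    """
    x = 0.0
    for comp in profile:
        if comp.acid.carbons == 18 and comp.acid.double_bonds in (2, 3):
            if omega6_only and comp.acid.omega_class != "w6":
                continue
            x += comp.weight_percent
    if x <= 0.0:
        raise BiodieselError(
            "oxidative stability not computable: no C18:2/C18:3 content"
        )
    return OS_NUMERATOR / x + OS_ASYMPTOTE


@dataclass(frozen=True)
class BiodieselProperties:
    """The full Table-style fuel descriptor set for one profile."""

    sv: float
    iv: float
    du: float
    mufa_percent: float
    pufa_percent: float
    lcsf: float
    cfpp: float
    cn: float
    os_hours: float | None  # None when no C18:2/C18:3 content (undefined)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sv": self.sv,
            "iv": self.iv,
            "du": self.du,
            "mufa_percent": self.mufa_percent,
            "pufa_percent": self.pufa_percent,
            "lcsf": self.lcsf,
            "cfpp": self.cfpp,
            "cn": self.cn,
            "os_hours": self.os_hours,
        }


def evaluate_properties(
    profile: FAMEProfile, omega6_only_os: bool = False
) -> BiodieselProperties:
    """Compute all fuel descriptors for a profile by delegating to the
    individual property functions; each field is bit-identical to the
    standalone call.

    ``os_hours`` is ``None`` when the profile has no C18:2/C18:3 content
    (the OS correlation is undefined there).
    """
    if len(profile) == 0:
        raise BiodieselError("cannot evaluate properties of an empty profile")
    totals = class_totals(profile)
    sv = saponification_value(profile)
    iv = iodine_value(profile)
    lcsf = long_chain_saturation_factor(profile)
    try:
        os_hours: float | None = oxidative_stability(profile, omega6_only_os)
    except BiodieselError:
        os_hours = None
    return BiodieselProperties(
        sv=sv,
        iv=iv,
        du=degree_of_unsaturation(totals),
        mufa_percent=totals.mufa_percent,
        pufa_percent=totals.pufa_percent,
        lcsf=lcsf,
        cfpp=cold_filter_plugging_point(lcsf),
        cn=cetane_number(sv, iv),
        os_hours=os_hours,
    )


@dataclass(frozen=True)
class StandardLimits:
    """Bounds a fuel standard places on the computed descriptors.

    Absent bounds (None) are simply not checked.
    """

    standard_name: str
    iv_max: float | None = None
    cn_min: float | None = None
    os_min: float | None = None
    cfpp_range: tuple[float, float] | None = None


#: European biodiesel standard: IV <= 120, CN >= 51, OS >= 6 h,
#: CFPP within the climate-class envelope −20…5 °C.
EN14214 = StandardLimits(
    "EN14214", iv_max=120.0, cn_min=51.0, os_min=6.0, cfpp_range=(-20.0, 5.0)
)
#: American biodiesel standard: CN >= 47, OS >= 3 h.
ASTM_D6751 = StandardLimits("ASTM D6751-02", cn_min=47.0, os_min=3.0)

STANDARDS = {"en14214": EN14214, "astm": ASTM_D6751}


@dataclass(frozen=True)
class ComplianceCriterion:
    """One verdict: the value compared, the bound, and pass/fail."""

    standard: str
    criterion: str
    value: float | None
    bound: str
    passed: bool


@dataclass(frozen=True)
class ComplianceReport:
    """All per-criterion verdicts for one property set against one standard."""

    criteria: tuple[ComplianceCriterion, ...]

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.criteria)

    def verdict(self, criterion: str) -> ComplianceCriterion:
        for c in self.criteria:
            if c.criterion == criterion:
                return c
        raise KeyError(criterion)


def check_compliance(
    props: BiodieselProperties, limits: StandardLimits
) -> ComplianceReport:
    """Compare computed descriptors against a standard's bounds.

    IV is compared <= iv_max, CN >= cn_min, OS >= os_min and CFPP within
    cfpp_range; an undefined OS (None) fails any configured OS bound.
    """
    criteria: list[ComplianceCriterion] = []
    name = limits.standard_name
    if limits.iv_max is not None:
        criteria.append(
            ComplianceCriterion(
                name, "iv", props.iv, f"<= {limits.iv_max}",
                props.iv <= limits.iv_max,
            )
        )
    if limits.cn_min is not None:
        criteria.append(
            ComplianceCriterion(
                name, "cn", props.cn, f">= {limits.cn_min}",
                props.cn >= limits.cn_min,
            )
        )
    if limits.os_min is not None:
        passed = props.os_hours is not None and props.os_hours >= limits.os_min
        criteria.append(
            ComplianceCriterion(
                name, "os", props.os_hours, f">= {limits.os_min}", passed
            )
        )
    if limits.cfpp_range is not None:
        lo, hi = limits.cfpp_range
        criteria.append(
            ComplianceCriterion(
                name, "cfpp", props.cfpp, f"within [{lo}, {hi}]",
                lo <= props.cfpp <= hi,
            )
        )
    return ComplianceReport(tuple(criteria))


def flag_inconsistent_row(
    printed: dict[str, float], tol_cn: float = 0.1, tol_cfpp: float = 0.1
) -> dict[str, bool]:
    """Cross-check a published descriptor row against the equations.

    Given printed SV, IV, LCSF, CN and CFPP values, recompute CN from the
    printed SV/IV and CFPP from the printed LCSF and report whether each
    printed value is consistent with the stated equations. Published tables
    occasionally contain values the stated formulas do not reproduce; this
    flags them rather than overwriting either side.
    """
    flags = {}
    if {"sv", "iv", "cn"} <= printed.keys():
        cn = cetane_number(printed["sv"], printed["iv"])
        flags["cn_consistent"] = math.isclose(
            cn, printed["cn"], abs_tol=tol_cn
        )
    if {"lcsf", "cfpp"} <= printed.keys():
        cfpp = cold_filter_plugging_point(printed["lcsf"])
        flags["cfpp_consistent"] = math.isclose(
            cfpp, printed["cfpp"], abs_tol=tol_cfpp
        )
    return flags
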