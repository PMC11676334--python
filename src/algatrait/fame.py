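"""Fatty acid methyl ester (FAME) profiles: data model, label parsing, and
compositional arithmetic.

A FAME profile is the weight-percent composition of the transesterified
fatty acids of a lipid extract, as reported by GC–MS. Each component is
identified by its acyl-chain carbon count ``n``, double-bond count ``d``
(written ``Cn:d``), and optionally an omega (n-minus) position class. The
profile is the sole input to the empirical biodiesel property equations in
:mod:`algatrait.biodiesel`.

Profiles are *not* auto-normalized: published compositions frequently sum to
less than 100% (unidentified peaks), and downstream property values are only
reproducible from the as-printed percents. Use :func:`normalize_profile`
explicitly if a closed composition is wanted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

# Standard atomic masses (g/mol). Single source of truth for molecular-mass
# arithmetic; the methyl ester of a Cn:d acid has formula C(n+1)H(2(n+1)-2d)O2.
ATOMIC_MASS_C = 12.011
ATOMIC_MASS_H = 1.008
ATOMIC_MASS_O = 15.999

#: Canonical omega-class labels. ``parse_fame_label`` folds the dialects
#: "ω-3" / "w3" / "w-3" / "n-3" / "omega-3" onto these.
OMEGA_CLASSES = ("w3", "w6", "w7", "w9", "unspecified")


class FAMEError(ValueError):
    """Malformed or invalid FAME input."""


@dataclass(frozen=True, order=True)
class FattyAcid:
    """A fatty acid identity: chain length, unsaturation, omega class.

    Parameters
    ----------
    carbons : int
        Acyl-chain carbon count, >= 2.
    double_bonds : int
        Number of C=C bonds, 0 <= d <= floor((n - 2) / 2).
    omega_class : str
        One of :data:`OMEGA_CLASSES`; "unspecified" for saturated acids.
    common_name : str
        Optional trivial name, e.g. "Palmitic acid". Not part of identity.
    """

    carbons: int
    double_bonds: int
    omega_class: str = "unspecified"
    common_name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise FAMEError(f"carbon count must be >= 2, got {self.carbons}")
        if self.double_bonds < 0:
            raise FAMEError("double-bond count must be >= 0")
        if self.double_bonds > (self.carbons - 2) // 2:
            raise FAMEError(
                f"C{self.carbons}:{self.double_bonds} is impossible: at most "
                f"{(self.carbons - 2) // 2} methylene-interrupted double bonds "
                f"fit on a {self.carbons}-carbon chain"
            )
        if self.omega_class not in OMEGA_CLASSES:
            raise FAMEError(f"unknown omega class {self.omega_class!r}")
        if self.double_bonds == 0 and self.omega_class != "unspecified":
            raise FAMEError("saturated acids carry no omega class")

    @property
    def key(self) -> tuple[int, int, str]:
        """Identity triple used for duplicate detection."""
        return (self.carbons, self.double_bonds, self.omega_class)

    def __str__(self) -> str:
        return format_fame_label(self)


@dataclass(frozen=True)
class FAMEComponent:
    """One profile entry: a fatty acid and its weight percent of total FAs."""

    acid: FattyAcid
    weight_percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight_percent <= 100.0):
            raise FAMEError(
                f"weight percent must be in [0, 100], got {self.weight_percent}"
            )


@dataclass(frozen=True)
class FAMEProfile:
    """An ordered FAME composition for one strain/condition.

    Weight percents need not sum to 100 (unidentified peaks are simply
    absent); the sum may not exceed 100. Duplicate (n, d, omega) identities
    are rejected — they indicate a transcription error, not data.
    """

    components: tuple[FAMEComponent, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        seen: set[tuple[int, int, str]] = set()
        for comp in self.components:
            if comp.acid.key in seen:
                raise FAMEError(f"duplicate component {comp.acid}")
            seen.add(comp.acid.key)
        if self.total_percent > 100.0 + 1e-6:
            raise FAMEError(
                f"profile sums to {self.total_percent:.4f}% > 100%"
            )

    @property
    def total_percent(self) -> float:
        return sum(c.weight_percent for c in self.components)

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def percent_of(self, carbons: int, double_bonds: int) -> float:
        """Summed weight percent of all components with the given (n, d)."""
        return sum(
            c.weight_percent
            for c in self.components
            if c.acid.carbons == carbons and c.acid.double_bonds == double_bonds
        )


@dataclass(frozen=True)
class ClassTotals:
    """Saturation-class weight-percent totals of a profile."""

    sfa_percent: float
    mufa_percent: float
    pufa_percent: float

    @property
    def total(self) -> float:
        return self.sfa_percent + self.mufa_percent + self.pufa_percent


_LABEL_RE = re.compile(r"C\s*_?(\d+)_?\s*:\s*_?(\d+)_?", re.IGNORECASE)
_OMEGA_RE = re.compile(
    r"(?:ω|w|n|omega)\s*-?\s*(\d+)", re.IGNORECASE | re.UNICODE
)


def parse_fame_label(label: str) -> FattyAcid:
    """Parse a fatty-acid label like ``"α-linolenic acid (C18:3 ω-3)"``.

    Accepts the shorthand dialects "ω-3", "w-3", "w3", "n-3" and "omega-3"
    for the omega class; any text before the ``Cn:d`` token becomes the
    common name.

    Raises
    ------
    FAMEError
        If no ``Cn:d`` token is present or the (n, d) pair is chemically
        impossible.
    """
    m = _LABEL_RE.search(label)
    if m is None:
        raise FAMEError(f"no Cn:d token found in label {label!r}")
    carbons, double_bonds = int(m.group(1)), int(m.group(2))
    common_name = label[: m.start()].strip(" \t(").strip()
    tail = label[m.end():]
    omega = "unspecified"
    om = _OMEGA_RE.search(tail)
    if om is not None:
        omega = f"w{om.group(1)}"
        if omega not in OMEGA_CLASSES:
            raise FAMEError(f"unsupported omega class in {label!r}")
    if double_bonds == 0:
        omega = "unspecified"
    return FattyAcid(carbons, double_bonds, omega, common_name)


def format_fame_label(acid: FattyAcid) -> str:
    """Canonical label ``C<n>:<d>[ w<k>]``; inverse of :func:`parse_fame_label`."""
    base = f"C{acid.carbons}:{acid.double_bonds}"
    if acid.omega_class != "unspecified":
        base += f" {acid.omega_class}"
    return base


def fame_molecular_mass(acid: FattyAcid) -> float:
    """Molecular mass (g/mol) of the fatty acid *methyl ester*.

    The methyl ester of a Cn:d acid has elemental formula
    C(n+1) H(2(n+1)-2d) O2; each double bond removes two hydrogens.
    """
    n, d = acid.carbons, acid.double_bonds
    n_c = n + 1
    n_h = 2 * (n + 1) - 2 * d
    return ATOMIC_MASS_C * n_c + ATOMIC_MASS_H * n_h + 2 * ATOMIC_MASS_O


def class_totals(profile: FAMEProfile) -> ClassTotals:
    """Sum weight percents into SFA (d=0), MUFA (d=1), PUFA (d>=2) classes."""
    sfa = mufa = pufa = 0.0
    for comp in profile:
        d = comp.acid.double_bonds
        if d == 0:
            sfa += comp.weight_percent
        elif d == 1:
            mufa += comp.weight_percent
        else:
            pufa += comp.weight_percent
    return ClassTotals(sfa, mufa, pufa)


def normalize_profile(profile: FAMEProfile) -> FAMEProfile:
    """Rescale weight percents to a 100% total. Identities preserved.

    Raises
    ------
    FAMEError
        If the profile total is zero.
    """
    total = profile.total_percent
    if total <= 0.0:
        raise FAMEError("cannot normalize a zero-total profile")
    scale = 100.0 / total
    comps = tuple(
        replace(c, weight_percent=c.weight_percent * scale) for c in profile
    )
    return FAMEProfile(comps, label=profile.label)


def read_fame_csv(path: str | Path, label: str = "") -> FAMEProfile:
    """Read a FAME composition CSV with columns ``label,weight_percent``."""
    df = pd.read_csv(path)
    missing = {"label", "weight_percent"} - set(df.columns)
    if missing:
        raise FAMEError(f"{path}: missing column(s) {sorted(missing)}")
    comps = tuple(
        FAMEComponent(parse_fame_label(str(row.label)), float(row.weight_percent))
        for row in df.itertuples(index=False)
    )
    return FAMEProfile(comps, label=label or str(path))


def write_fame_csv(profile: FAMEProfile, path: str | Path) -> None:
    """Write a profile using canonical ``C<n>:<d>[ w<k>]`` labels."""
    df = pd.DataFrame(
        {
            "label": [format_fame_label(c.acid) for c in profile],
            "weight_percent": [c.weight_percent for c in profile],
        }
    )
    df.to_csv(path, index=False)
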