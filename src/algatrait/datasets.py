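"""Packaged published-value fixtures.

Three small CSVs ship with the package, transcribed from the published
characterization of the halotolerant *Dunaliella salina* isolate:

* the 11-component FAME composition at 0.5 M NaCl,
* the biodiesel descriptor table for that strain alongside reference crops
  and microalgae,
* the pairwise marker-divergence table (substitution counts and percent
  dissimilarities against deposited strains).

These are printed values, distinct from the random fixtures produced by
:mod:`algatrait.synthetic`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fame import FAMEProfile, read_fame_csv


def _data_path(name: str):
    return resources.files("algatrait.data").joinpath(name)


def load_reference_fame_profile() -> FAMEProfile:
    """The published 11-component FAME profile (total 85.74%)."""
    with resources.as_file(_data_path("fame_dsta20_0p5M.csv")) as p:
        return read_fame_csv(p, label="D. salina DSTA20, 0.5 M NaCl")


def load_biodiesel_reference_table() -> pd.DataFrame:
    """Published fuel descriptors per source (strains, crops)."""
    with resources.as_file(_data_path("biodiesel_reference.csv")) as p:
        return pd.read_csv(p, index_col="source")


def load_marker_divergence_table() -> pd.DataFrame:
    """Published pairwise marker divergences (SSU rDNA and rbcL)."""
    with resources.as_file(_data_path("marker_divergence.csv")) as p:
        return pd.read_csv(p)
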