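# Methods

## Scope and model

The package implements the computational layer of a microalgal strain
characterization: empirical biodiesel descriptors from a FAME weight-percent
composition, exponential growth-rate analysis over condition lattices,
linear external-standard calibration for chromatographic quantification, and
column-wise divergence of pre-aligned marker genes. Everything upstream of
these tables — spectral deconvolution, peak detection, sequence alignment,
phylogenetics — is out of scope: the pipeline consumes identified peak
tables, OD/count series and aligned pairs.

## FAME compositions and the descriptor equations

A profile is an ordered list of (Cn:d, omega class, weight percent) entries.
Profiles are **not** auto-normalized: published compositions commonly sum to
less than 100% (unidentified peaks), and the descriptor equations are linear
in the as-printed percents, so rescaling would change every value. The
packaged reference composition sums to 85.74%; the remaining 14.26% is
unattributed and deliberately left so. `normalize_profile` exists for the
cases where a closed composition is wanted, and is never applied implicitly.

Molecular masses are of the **methyl ester**, not the free acid:
C(n+1)H(2(n+1)−2d)O₂ with C = 12.011, H = 1.008, O = 15.999 (constants
defined once in `fame.py`). Each double bond removes two hydrogens
(−2.016 g/mol). The descriptor equations and their constants (560, 254,
46.3, 5458, 0.225, 3.1417, −16.477, 117.9295, 2.5905, and the LCSF chain
weights 0.1/0.5/1/1.5/2) live in a single registry in `biodiesel.py`;
values are held at full precision and rounded only for presentation.

The OS term X sums **all** C18:2 and C18:3 isomers regardless of omega
class by default; the underlying correlation is ambiguous on this point, so
an ω-6-only switch is provided. OS is undefined (reported as not
computable, `None`) when X = 0 rather than returned as infinity.

Duplicate (n, d, ω) rows in an input file are an error, not a silent merge —
in transcription-heavy workflows a duplicate row almost always indicates a
mistake. Omega-class dialects (ω-3, w-3, w3, n-3, omega-3) are folded to a
canonical `w<k>` form at parse time.

**Known inconsistency handling.** Published descriptor tables occasionally
contain entries the stated equations do not reproduce. The package never
forces such values: `flag_inconsistent_row` recomputes CN from a row's
printed SV/IV and CFPP from its printed LCSF and reports
consistent/inconsistent per row. In the packaged reference table, the study
strain's printed CN (35.04) and OS (8.7) are inconsistent with the
equations applied to its own printed SV/IV/composition (which give ≈40.1
and ≈5.39), while a second strain's row reproduces exactly (CN 34.29,
CFPP −7.08) — evidence the equations themselves are implemented correctly.
Compliance checks can therefore be run either on computed descriptors or on
a printed property set supplied directly.

## Growth analysis

μ is always reported per day; a 72 h screen is entered as duration 3.0.
OD600 is accepted as a biomass proxy with no calibration. The growth /
no-growth call uses an inclusive final-fold-change threshold, default 1.2 —
low enough that any sustained doubling is growth, high enough that
measurement jitter on a flat series is not; it is configurable.

`find_optimum` is deliberately grid-based (argmax plus a plateau mask of
cells within a fraction — default 0.9 — of μ_max) rather than a fitted
response surface: screening lattices are coarse and a mechanistic
thermal×light fit would add assumptions the data cannot check. Ties at the
maximum break toward lower temperature, then lower photon flux density, on
a cost-of-cultivation rationale. Missing plate cells are NaN and ignored.

## Calibration quantification

Calibration is ordinary least squares with intercept by default (≥2
distinct-amount standards); a through-origin single-factor mode accepts one
point. The detection limit is intercept + 3·residual SD when the fit has
residual statistics, else the bare intercept. Peak→analyte matching is
greedy nearest-retention-time within a tolerance (default 0.2 min, wider
than typical run-to-run RT drift of ~0.1 min), one-to-one per chromatogram,
ties toward the lower reference RT. Biomass normalization (extract mass,
analyzed fraction) is an explicit per-sample input; amounts are reported in
mg per g dry weight, with extrapolation beyond the standard range flagged
rather than refused.

## Marker divergence

Inputs are pre-aligned equal-length pairs over A/C/G/T/N/-. A column is a
substitution when both bases are unambiguous, non-gap and unequal; a gap
column when exactly one sequence has a gap; N columns are never mismatches
but count toward the compared length, as do all columns (terminal gaps are
not trimmed). Dissimilarity = 100·(substitutions + gap columns)/length,
kept at full precision with a half-up one-decimal rounding for display —
the convention that renders 2/1460 as 0.1% and 7/1460 as 0.5%.

## Synthetic data generators

The generators exist so every stage can be tested as estimator-vs-truth
recovery; each returns the hidden truth beside the observables and is
deterministic given its seed (one `numpy.random.Generator` per call).

- **FAME profiles**: symmetric-Dirichlet weights over a configurable acid
  pool, scaled to a configured total (default 85.74%, matching the packaged
  reference composition). The degenerate mode — the reference composition
  itself — reproduces the published descriptor row.
- **Growth surface**: μ(T, I) = μ_max·exp(−((T−T_opt)/σ_T)²)·(I/I_opt)·
  exp(1−I/I_opt) — a Gaussian thermal performance curve times a Steele
  photoinhibition light curve. This is a generator-side convention only;
  the analysis stage fits nothing. Defaults: μ_max = 0.5 d⁻¹ (a realistic
  short-term optimum for a halotolerant chlorophyte), T_opt = 21 °C,
  I_opt = 88 µmol m⁻² s⁻¹ (the published optimum), σ_T = 8 °C (growth
  spanning roughly 8–34 °C). The default plate is 8 temperatures × 12 light
  levels over 5–40 °C and 0–350 µmol m⁻² s⁻¹ with both optima on-lattice.
  End-point ODs get multiplicative lognormal noise.
- **Salinity series**: exponential trajectories with daily sampling over 21
  days from 7.08×10³ cells/mL; the best condition uses μ = ln 5/14 d⁻¹ (a
  fivefold day-14 increase) and the zero-salinity condition μ = 0.
- **Chromatograms**: standard points on a configured response line
  (response factors ~75–85 area/mg; the β-carotene factor matches the
  published area/amount ratio 205.1/2.47 ≈ 83) with additive Gaussian area
  noise, plus sample peaks encoding hidden amounts, RTs jittered uniformly.
- **Sequence pairs**: uniform random A/C/G/T reference with exactly k
  substitutions and g one-sided gap columns injected at distinct positions.

What the generators do **not** emulate: lag/stationary growth phases,
plate-edge effects, baseline drift and co-eluting peaks, compositional
covariance between fatty acids, and alignment uncertainty. Passing recovery
tests therefore demonstrate the correctness of the estimators under the
stated noise models, not robustness to real-instrument artifacts.

## Problem sizes and numerical choices

The stochastic suites run 1,000 random compositions for SV/IV linearity,
200 noisy screening plates for optimum recovery (lognormal σ = 0.05,
success = argmax within one grid step on each axis, required rate ≥95%),
200 seeded calibration re-fits (additive area noise σ = 2 units, slopes
required within 5% of truth) and 1,000 random pairs against a per-column
brute-force divergence oracle. All complete in a few seconds; these sizes
give comfortable statistical margins for the stated tolerances.

Floating-point equality is asserted via absolute/relative tolerances stated
per test; published values are checked at their printed precision (two
decimals for descriptors, one decimal for dissimilarity percents, ±0.5 for
SV/IV where atomic-mass rounding propagates). Internal arithmetic is double
precision throughout; no value is re-rounded between stages.

## Orchestration

`RunConfig` (YAML-loadable) points at per-stage input CSVs/FASTAs;
`validate_inputs` schema-checks every file and returns row-level findings
without raising; `run_characterization` executes the requested stages in
order, isolates stage failures (one failed stage never aborts the others),
and writes per-stage CSVs plus a JSON manifest with a config hash so
identical inputs yield byte-identical reports. CSV (UTF-8, "." decimal) is
the interchange format everywhere; the `analysis/` drivers are the
command-line surface.
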