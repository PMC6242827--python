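# Methods

## Problem and scope

Coarse-mode (≈1–10 µm) particles containing sodium salts are routinely
observed over the Amazon basin and traditionally attributed to marine
aerosol. The alternative hypothesis this package supports is that
locally emitted fungal spores — carbonaceous particles that carry
sodium-bearing salts — supply a large share of that sodium, especially
in the wet season when precipitation scavenges long-range marine
transport. The package implements four analysis stages (single-particle
classification, per-spore sodium quantification, hygroscopic growth
factors, sodium budget apportionment) plus a synthetic-data generator
that emulates every input, so the whole pipeline runs and is testable
without instrument data or a chemistry-transport model.

## Particle classification

Input is one row per particle: elemental composition as atomic
fractions (the native output of quantified EDX), projected area,
morphology label, and sampling metadata. Atomic fractions are converted
to weight fractions via w_i = a_i·M_i / Σ a_j·M_j using IUPAC standard
atomic weights for C, N, O, Na, Mg, Al, Si, P, S, Cl, K, Fe. Copper is
excluded before normalisation: particles sit on Cu mesh grids and any
Cu signal is substrate background; particles on the grid edge (where
that background dominates) are dropped entirely.

Classification is a first-match decision list (all thresholds are
weight fractions, editable via a YAML `RuleSet`):

1. **na_rich** — Na ≥ 3 wt% (the EDX detection limit) and Na is the
   largest fraction among non-CNO elements;
2. **mixed_bio_dust** — biological composition (C+N+O ≥ 50 wt% and
   P ≥ 0.5 wt%) with a crustal admixture (Al+Fe ≥ 1 wt%);
3. **dust** — Al+Si+Fe ≥ 10 wt%, where Si counts only when corroborated
   by ≥1 wt% Al or Fe (bare Si is indistinguishable from substrate);
4. **sulfate** — S ≥ 5 wt%;
5. **carbonaceous** — C+O ≥ 90 wt%;
6. **other** — everything else, so the scheme is total.

The **fungal-spore flag** is deliberately separate from the composition
class: spore morphology (spherical, rod-like, spheroidal), 1–6 µm
area-equivalent diameter, and biological composition. A
sodium-containing spore typically *also* classifies `na_rich`; the two
labels are cross-tabulated rather than forced disjoint, because the
population of interest — "sodium salt particles" — includes
sodium-bearing spores by design. Quoted ± values on number fractions
are binomial standard errors √(p(1−p)/n); whether the original ±2%
figures used exactly this estimator is not documented, so the choice is
stated here. Morphology is an input label; automated shape recognition
from images is out of scope.

Diameters are geometric area-equivalent diameters d = 2√(A/π), not
aerodynamic; the impactor stage window is metadata, not recomputed.

## Per-spore sodium

Spores average 51 wt% carbon (range 42–66%) with a carbon-to-sodium
mass ratio of 4:1, giving a sodium dry-mass fraction of
0.51/4 = 0.1275. The budget uses the rounded constant 0.13; both values
are retained and an internal test asserts their consistency. Spore mass
assumes a sphere of unit density: m[pg] = (π/6)·d[µm]³, so a 4 µm
emission-size spore weighs 33.51 pg and carries ≈4.27 pg Na. When
per-particle Na weight fractions are available they take precedence
over the population constant. The size trend (smaller spores carrying
proportionally more Na) is summarised by binned means plus a Spearman
rank correlation, with the sign reported only when p ≤ 0.05.

## Hygroscopic growth factors

ESEM hydration pairs are segmented independently (Otsu threshold,
largest connected component; the particle is brighter than the
background). The **area growth factor** is the wet/dry ratio of
area-equivalent diameters; the squared value (the raw area ratio) is
reported alongside, since "area growth factor" is defined as a diameter
ratio. STXM transmission maps are converted to optical density
OD = −ln(I/I₀); at the oxygen absorption edge integrated OD is
proportional to oxygen (hence water+organic) mass, so the **mass growth
factor** is the wet/dry ratio of OD integrated over the particle mask.
The mask is the union of dry and wet masks so water condensed beyond
the dry boundary is counted; background pixels (including negative-OD
noise) never enter either integral. I₀ defaults to the median intensity
of a 5-pixel particle-free border when not supplied. Pixels with
nonpositive intensity are invalid (NaN) and excluded.

Sub-pixel effects are ignored; accuracy budgets are expressed in
pixel-quantization units (e.g. a 50-px dry disk recovers a configured
factor of 2.4 to within 2 pixel widths on the diameter, ≈0.4%).

## Sodium budget

For spore and sea-salt mass concentrations C_s and C_ss, the per-step
spore share of sodium is

    f = p·w_s·C_s / (p·w_s·C_s + w_ss·C_ss)

with w_s = 0.13 (Na fraction of sodium-rich spores), w_ss = 0.30 (sea
salt), and p = 0.70 the assumed sodium-rich spore fraction (0.30 and
0.50 as sensitivity cases). Seasonal summaries average **per-step
fractions**; the alternative (fraction of season-mean masses) differs
on heterogeneous series by Jensen's inequality and is exposed as a
separate diagnostic. Uncertainty bounds rescale every step — spores
÷10 with sea salt ×2 (low), spores ×10 with sea salt ÷2 (high) — and
re-average; because the rescaled fraction dominates pointwise, the
bracket low ≤ mean ≤ high is exact, not statistical. The factor-10
spore bound reflects the order-of-magnitude spread of spore-emission
estimates; a factor-2 mode is available via `spore_factor=2`.

Night is the half-open window [18:00, 06:00) — the caption convention
gives endpoints but not boundary assignment, so 18:00 itself counts as
night. The ≥50%-of-days statistic averages sub-daily fractions to daily
means first. Wet season is January–June (dry July–December),
configurable. Steps with zero total sodium are undefined (NaN, warned)
and excluded from means.

## Synthetic-data generator

The generator defines the study conditions for all tests; its defaults
are fixed calibration choices, documented here because the source
measurements publish summary fractions but not distributional
parameters.

**Particle tables.** Each class has a composition profile (per-element
weight-fraction mean and spread; draws truncated at zero, renormalised
to 1, stored as atomic fractions — the inverse of the classifier's
conversion), a morphology distribution, and a lognormal size
distribution. Profiles are calibrated so the shipped mixtures, pushed
through the default ruleset, recover the configured fractions within
binomial sampling error; they are calibration artefacts, not measured
compositions. Two deliberate features: the sodium-salt (`na_rich`)
profile has Na clearly above Cl so it robustly satisfies the
Na-dominance rule, while the fungal-spore profile has Cl above Na
(NaCl is 61 wt% Cl), so roughly half of spores exceed the 3 wt% sodium
detection limit — matching the observed 22–60% range of
sodium-containing spores — without flipping their composition class.
The default coarse-mode mixture is 48% na_rich / 25% dust / 19%
fungal spore / 5% sulfate / 3% carbonaceous; the below-canopy mixture
raises the spore fraction to 60%. Grid-edge flags are Bernoulli(0.07),
inside the reported 5–10% exclusion range.

**Imagery.** Hydration pairs are filled analytic shapes (disk, 1.4:1
ellipse, capsule) at 0.8 intensity on a 0.2 background with optional
Gaussian noise; the wet shape scales every linear dimension by the
configured diameter growth factor, so the projected-area ratio is its
square by construction. STXM pairs carry hemispherical OD profiles with
the wet amplitude normalised so the pixel-summed OD ratio equals the
configured mass ratio exactly; intensities obey I = I₀·e^(−OD)
pixelwise. These fixtures exercise threshold-and-measure operators;
they do not emulate detector artefacts, drift, charging, or partial
volume effects, so passing tests demonstrate correctness of the
measurement operators, not robustness to real instrument pathology.

**Concentration series.** Daily spore and sea-salt concentrations are
lognormal (defaults: spore median 1.0 µg m⁻³, GSD 2.0; sea salt median
0.30 µg m⁻³, GSD 2.5 — chosen so typical wet-season days sit near the
f = 0.5 boundary and the threshold statistic is informative). The wet
season multiplies the sea-salt median by 0.4 and daily Bernoulli(0.25)
scavenging events multiply sea salt by 0.2, emulating wet removal of
marine aerosol without any transport physics. Hourly output applies a
square-wave diurnal cycle to spores with night/day ratio 2 (nighttime
spore enhancement is reported but no model amplitude is printed; 2 is
a fixed calibration choice) while preserving the daily mean. Grid
series derive cell seeds as seed+i, with an optional per-cell sea-salt
multiplier field. A fixed seed reproduces every generator output byte
for byte (`numpy.random.default_rng`).

The generator does **not** emulate aerosol microphysics, emission
parameterisations, sea-salt source functions, or meteorology; seasonal
sodium percentages computed on synthetic series are therefore
illustrative, and the published seasonal values are not reproduction
targets. The budget machinery is validated structurally instead: exact
bound bracketing on every series, strict monotonicity in p, exact
hand-computed single-step values, and the direction of the day/night
contrast.

## Numerical choices and problem sizes

Classification fixtures use n = 2000 particles (binomial SE ≈ 1.1% at
p = 0.5, so 3-SE recovery bands are ±3.3%). Growth-factor acceptance
uses 25-px dry disks (43k-pixel frames) and 18-px STXM domes; the noise
robustness property runs 50 seeds at noise SD 0.02. Budget series use
60–200 days daily or 60 days hourly. The full suite runs in a few
seconds on one CPU. Ties in segmentation (equal-area components) fall
to the first-labelled component; Otsu thresholding requires a
non-uniform frame and segmentation fails loudly on uniform input.

## Known limitations

- Composition profiles and all series parameters are calibration
  choices; recovered fractions validate the pipeline's statistics, not
  the field measurements.
- The classifier consumes already-quantified atomic fractions; EDX
  spectrum deconvolution and ZAF correction are out of scope.
- No κ-Köhler activation, deliquescence detection, or RH ramp
  kinetics — endpoint growth factors only.
- Sodium speciation (NaCl vs organic sodium salts) is not modelled.
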