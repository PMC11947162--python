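# Methods

This note documents the models implemented in `ferroprop`, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the numerical choices that matter when reproducing results.

## Monolayer geometry

Cells are hard discs packed into a square field by random sequential
adsorption (RSA): uniform centre proposals, truncated-normal diameters,
rejection when a proposed disc would overhang the field or approach an
existing centre closer than (1 − tol)·(rᵢ + rⱼ). RSA is simple,
reproducible, respects non-overlap, and naturally caps at the densities
used in confluency experiments. The overlap tolerance (default 0.1)
mimics the slight interdigitation of real adherent cells and keeps
packing fast at 50 % area coverage; the attempt budget scales with the
expected cell count and a `PackingError` reports the achieved fraction
when a target is unreachable (RSA jams near 0.55 for discs).

Defaults: field 500 µm, target confluency 0.5, diameters 23 ± 2 µm (HeLa
scale), transfected fraction 0.3, 10 illuminated cells. Coordinates are in
µm with y increasing downward (image convention); all distances are
Euclidean and centroid-to-centroid.

The contact graph joins cells with centroid distance ≤ κ·(dᵢ + dⱼ)/2.
κ = 1.2 by default: nominal tangency (κ = 1) plus the packing tolerance
and membrane reach. At the default density this yields a mean contact
degree near 2.

## Propagation model

Discrete time with Δt = 2 min (a plausible imaging cadence; the
chain-binomial estimator assumes the same clock). At t = 0 every
illuminated transfected cell receives an oxidation onset of 0 and a death
(blebbing) time drawn from a normal(17, 2) truncated to [13, 20] min —
the single-cell timing of optogenetically induced ferroptosis. At each
step, a cell with k contact neighbours that died *in that step* converts
with probability 1 − (1 − p_eff)ᵏ where

    p_eff = p_spread · iron_factor · fer1(t) · [contacts_enabled]

with fer1(t) = fer1_efficacy for t ≥ fer1_time and 1 before. Converted
cells acquire ox_onset = conversion time + lognormal(ln 30, 0.4) min and
blebbing = ox_onset + normal(60, 15) min truncated at 0; DRAQ7 positivity
follows blebbing by a fixed lag (default 4 min, configurable) since the
dye requires membrane permeabilisation. The onset/death delay
distributions are modelling choices, not measured values: they place
bystander death on the hours scale while activated cells die within
minutes, preserving the observed ordering (oxidation precedes death,
bystanders trail their inducers).

Only ferroptotic deaths (opto or propagated) are infectious, and only
during the step in which they occur. The background hazard (default
1e-5 / min) is a memoryless per-minute death probability applied to
alive, unconverted cells; background deaths are *not* infectious and do
not show an oxidation onset, which keeps background-only runs spatially
random — the null the spatial statistics are calibrated against. Two
simplifications relative to a fully general process: the hazard is not
applied to already-converted, not-yet-dead cells (at the default hazard
this is negligible and it avoids overwriting scheduled death times), and
dead cells are never resurrected or removed from the field.

The optional bilayer bridge exposes non-contact cells within
`bilayer_range` of a newly dead cell with probability
p_eff · (1 − d/R), a linear distance decay — the functional form is a
model choice; only the existence of accelerated long-range spread is
anchored in observation. p_spread defaults to 0.4, which at mean degree 2
produces partial, cluster-forming spread rather than field-wide
percolation over the default 12 h observation.

Determinism: every operation is a pure function of (inputs, seed). The
exposure step draws one uniform per exposed cell in index order even when
p_eff = 0, so modifier-null runs (contacts disabled, iron 0, Fer-1 at
full efficacy) consume the same random stream as p_spread = 0 and produce
bitwise-identical event tables.

## Virtual microscope

Each cell renders as an isotropic Gaussian blob of σ = diameter/4
(convolved in quadrature with the PSF σ). Four channels: a transfection
marker (constant for transfected cells), DRAQ7 (steps on at frames ≥
draq7_time), and BODIPY green/red, which exchange linearly over 20 min
after the oxidation onset with green + red conserved per cell. Additive
Gaussian pixel noise (default sd 3 at gains of 100–150) and constant
channel offsets complete the image model. The ground-truth label map
paints the true disc footprints.

Not emulated: cell migration and division, photobleaching, uneven
illumination, out-of-focus light, segmentation-relevant texture within
cells, and DRAQ7 intensity heterogeneity. Passing round-trip tests
therefore demonstrates the *pipeline's* correctness on geometry- and
noise-realistic data, not robustness to every real-microscopy artefact.

## Quantification

Segmentation: Gaussian smoothing (σ = 2 px), Otsu threshold, connected
components, watershed splitting at distance-transform maxima (peaks
separated by at least one plausible cell radius), then an area filter
(default 80–2000 µm²). A guard rejects masks whose foreground/background
contrast is below 3 background SDs, so noise-only frames yield an empty
label map rather than segmented noise. Labels are static from a reference
frame (no tracking): adherent cells over short windows; a documented
limitation.

Timecourses: per cell/channel/frame, the *mean* intensity over label
pixels (intensity per pixel — the cell-size correction) minus a
background estimate: "local" (default) is the median of a 3-px dilation
annulus excluding all labelled pixels, falling back to the global
background median with a logged warning when an annulus is empty;
corrected values clip at 0.

Population split: time-averaged marker intensity over pre-activation
frames against a threshold; "auto" uses the Otsu split and refuses
distributions whose class separation is under twice the summed class SDs
(a unimodality guard that asks for an explicit threshold instead of
guessing).

Death calling: first frame at which corrected DRAQ7 stays ≥ threshold for
`persistence` (default 2) consecutive frames, else censored at the last
frame. The default threshold is 5 pre-activation background-pixel SDs of
the DRAQ7 channel (`estimate_death_threshold`): per-pixel noise is the
right yardstick — per-cell trace noise is far smaller, and a trace-derived
5-SD threshold sits so close to the noise floor that chance
double-crossings occur; the pixel-based value lies well above chance and
well below a genuine dye step.

Oxidation ratio: G/(G + R), the oxidised fraction, bounded in [0, 1];
undefined where G + R = 0 (returned as NaN with a warning, never silently
zeroed). An alternative (R + G)/G reading is exposed via
`formula="total_over_green"` for comparability with conventions that
report the reciprocal-style quantity; the bounded form is the default and
is what the ratio tests assert.

## Spatial statistics

Hopkins: per replicate, m uniform locations (u, distance to nearest
event) and m sampled events (w, distance to nearest *other* event);
H = Σuᵈ/(Σuᵈ + Σwᵈ) with d = 2, m = max(5, 0.1 n), 100 replicates, and
mean ± sd reported rather than a single draw. The sampling window is the
bounding box of the *full* cell population, not the dead-cell hull —
the field of view defines the sampling frame, and a dead-cell hull would
bias H upward. Coincident events give H = 1 exactly; H is invariant under
uniform rescaling of pattern and window.

Nearest-neighbour distances are raw vector lengths without edge
correction (boundary bias: distances of near-edge points are biased
upward in sparse patterns); ties resolve to the lowest index, which
affects neighbour identity only, never the distance. The permutation null
holds the monolayer geometry fixed, resamples which cells died uniformly
within each population, and uses the add-one rule
p = (1 + #{null ≤ observed}) / (reps + 1), one-sided for
shorter-than-random distances.

`estimate_cell_diameter` reports the mean and sd of equivalent-circle
diameters 2·√(area/π).

## Kinetics

%positive curves use initial population counts as fixed denominators
(value(t) = 100 · cumulative deaths ≤ t / n₀), sampled at the acquisition
cadence; step interpolation precedes trapezoidal integration. %AUC divides
the trapezoidal area by the maximal possible area (100 % over the span),
× 100 — a saturated curve scores exactly 100, and the statistic is linear
in the curve and invariant to affine rescaling of the time axis. A
count-per-confluency mode divides positive-object counts by a confluency
trace and is reported in arbitrary units. Censoring is at last
observation; no survival modelling — summaries report uncensored moments
plus an explicit censored count and never impute. Group comparison is
one-way ANOVA with Tukey HSD; identical constant groups are flagged
degenerate (F undefined) rather than reported as 0/0.

## Lipidomics

Normalised ratio = peak area / matched internal-standard area, divided by
protein content (µg) for the oxidized-phospholipid workflow;
fatty-acid panels omit the protein step. The standard map (PC species to
the PC standard, PE to PE, fatty acids to deuterated palmitate) is
supplied by the caller since instrument tables do not pin it down. Fold
change = illuminated / replicate-paired control per replicate, averaged
arithmetically across replicates (geometric mean available). Replicate
pairing, rather than a pooled control mean, is adopted; fold changes are
invariant to any per-replicate global scaling applied to both conditions,
and the noiseless simulated table round-trips exactly.

## Spread-probability inference

Death times are binned to the Δt grid; a cell is susceptible until its
oxidation onset (or death/censoring). Each step in which a susceptible
cell has k newly dead ferroptotic contact neighbours is one Bernoulli
trial with success probability 1 − (1 − p)ᵏ; the likelihood is maximised
by bounded golden-section search with a grid profile cross-check (the two
agree to 1e-3 on simulated data, and the profile is unimodal).

Three estimator decisions matter:

1. **Response = oxidation onset, not death.** Attribution through death
   would confound p with the onset-to-death delay.
2. **Attribution to the last exposure at or before the onset.** The
   conversion step itself is unobserved (the onset trails it by the
   delay); attributing success to the final exposure and counting earlier
   ones as failures keeps the sequential chain-binomial form. Pooling a
   cell's exposures into one trial (success probability 1 − (1 − p)^K) is
   *misspecified*: conversion stops the exposure process, so K is
   outcome-dependent, and the pooled estimator degrades with epidemic
   size. The residual cost of the sequential rule is a small downward
   bias from exposures accrued during the onset delay (measured ≈ 0.03 at
   p = 0.6 under default delays).
3. **Only onset-bearing deaths are infectious.** Deaths without a
   preceding oxidation onset (background toxicity) do not spread
   ferroptosis and are excluded as infectors — observable in real data,
   where only ferroptotic corpses show prior C11-BODIPY oxidation.
   Counting them produces spurious failure trials and a bias that does
   not vanish with field size.

Estimation assumes complete observation of onsets; right-censored cells
contribute failure trials up to censoring. Boundary data give exact
boundary MLEs (no conversions → 0, all single-neighbour exposures convert
→ 1). The estimator is a formalisation at the artifact level: published
propagation experiments demonstrate spread but do not estimate a
transmission probability, so there is no field value to compare p̂
against — only generator truth.

The composite `propagation_test` calls "propagating" when the
permutation p-value < α (default 0.05) *and* Hopkins H_mean > 0.5,
"random" when p ≥ α, else "inconclusive"; both thresholds are
configurable.

## GUV transfer model

Donor oxidised fraction: dx_d/dt = k_act(1 − x_d); acceptor:
dx_a/dt = contact · k₀ · [Fe] · x_d · (1 − x_a). Measured ratios map
through r = baseline + (1 − baseline)·x. Integrated numerically (LSODA,
rtol 1e-10) and validated against the closed forms
x_d = 1 − e^(−k_act t) and x_a = 1 − exp(−c(t − (1 − e^(−k_act t))/k_act)),
to which the donor agrees within 3e-12 at dt = 0.01. Defaults
(k_act = 0.08 /min, k₀ = 0.5 /(min·mM), [Fe] = 0.5 mM, baseline 0.2,
60 min horizon) put donor oxidation on the tens-of-minutes scale with
acceptor transfer strictly conditional on contact and iron.

## Problem sizes and numerical choices

Test-suite and acceptance-script runs use deliberately modest problem
sizes chosen to exercise every code path at statistical power: 500 µm
fields (~310 cells) for spatial/kinetics replicates, 600 µm (~440 cells,
20 seeds) for parameter recovery, 210 µm fields (~55 cells, 240 min at
6 min/frame) for full imaging round trips, 500 Hopkins replicates for
calibration, and 200-seed Monte-Carlo checks for distributional claims.
Tolerances asserted in tests derive from the oracles (closed forms,
brute-force enumerations, Monte-Carlo bands), not from tuning.

Degenerate inputs are defined behaviour throughout: empty segmentations
return empty label maps; all-censored groups return flagged summaries;
coincident Hopkins patterns return exactly 1; zero-variance ANOVA is
flagged; zero-denominator ratios are NaN with a warning.

## Known limitations

- No cell motility, division, or death-independent detachment; static
  segmentation labels.
- The onset/death delay distributions are plausible placeholders; all
  downstream defaults are exposed for recalibration against real data.
- Fer-1 in the model only blocks *new* conversions; whether it rescues
  already-oxidised, not-yet-dead cells is unresolved, and the model makes
  the conservative choice.
- Hopkins values depend on the window convention and (m, d); regular
  monolayer geometry pushes H below 0.5 even for "random" death because
  deaths are constrained to cell positions.
- No edge correction in distance statistics; near-boundary distances are
  biased upward in sparse patterns.
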