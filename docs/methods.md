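# Methods

## The assay being modelled

A parallel-plate microchannel is coated with a mesothelial monolayer and
perfused with a suspension of fluorescent tumour spheroids (nominally
1500 mL⁻¹, 70–100 μm diameter after strainer gating) in a 0.9 cP binding
buffer.  Fields of view are recorded for 30 s at 1 frame s⁻¹ under imposed
wall shear in the ascitic range, 0.03–0.15 dyn cm⁻².  Each transiting
spheroid is scored as tethering, rolling, firmly adherent or
non-interacting, and the percentage of each class is the class count
divided by the total number of spheroids that crossed the field during the
recording.  Categorical outcomes are compared between conditions with
Pearson's chi-square on pooled counts; rolling-velocity distributions with
a one-tailed unpaired Student's t test; effect sizes are reported as median
fold changes.

## Hydrodynamics

For a rectangular channel with width ≫ height, plane Poiseuille flow gives
the wall shear stress τ = 6μQ/(wh²).  The package computes this relation
and its inverse exactly (round-trip relative error < 1e-12) with interface
units matching laboratory practice (dyn cm⁻², cP, μm, μL min⁻¹).  A free
spheroid near the wall translates at

    u_h = k_wall · (τ/μ) · (d/2),

the undisturbed fluid velocity at its centre height scaled by a wall drag
correction; k_wall defaults to 0.5676, the classical translation factor
for a sphere in near-wall linear shear, and k_wall = 1 recovers the
undisturbed velocity.  At τ = 0.05 dyn cm⁻², μ = 0.9 cP, d = 85 μm this
gives u_h ≈ 134 μm s⁻¹ — a spheroid crosses a 3.3 mm field in ~25 s, which
is what makes the 30 s, 1 fps protocol informative.

Channel cross-section and field of view are not published for the original
chip; the defaults (w = 1000 μm, h = 150 μm, field 3300 × 2500 μm) are a
plausible PDMS scale and are configurable everywhere.  The height exceeds
the 100 μm spheroid gate because a spheroid must fit the gap.

## The synthetic cohort generator

No raw videos or kinetic rates are published for this assay, so the
generator's kinetics are a modelling construct, calibrated once (see
"Calibration") and then frozen.  Each spheroid evolves by a discrete-time
Markov chain (Δt = 1 s, matching the observation process) over
free / tethered / rolling / adherent:

* free → tethered at `k_on`;
* tethered → adherent at `k_arrest`, → free at `k_release`
  (a transient tether — the "tethering" phenotype), → rolling at
  `k_off(τ)` (the first bond fails under load but motion continues on
  successive bonds);
* rolling → adherent at `k_arrest`, → free at `k_off(τ)`;
* adherent is absorbing during recording.

Rates become per-frame probabilities 1 − exp(−rate·Δt), with competing
exits attributed in proportion to their rates.  The bond off-rate follows
the standard two-pathway catch-slip law, with wall shear as the force
proxy:

    k_off(τ) = a·exp(−τ/f_c) + b·exp(τ/f_s).

Positions advance at u_h when free, ρ·u_h when rolling (ρ the rolling
speed fraction), and are stationary with 1 μm Gaussian jitter when
tethered or adherent.  Spheroids enter at the upstream edge at uniformly
random frames (Poisson arrivals per field), exit when no longer fully in
view, and are treated as rigid bodies: entries that would interpenetrate a
near-simultaneous arrival are resampled, and a mover passing over a parked
spheroid cannot initiate a tether there (the parked body occludes the
substrate).  Diameters are normal (85 ± 7 μm) truncated to the 70–100 μm
gate — a strainer-gated population has little mass exactly at the gate
edges.

The printed suspension density (1500 mL⁻¹) combined with the default
chamber gives well under one spheroid per field per recording
(`expected_arrivals_per_field`), far sparser than the per-condition sample
sizes this assay reports; the study presets therefore override arrivals
with an explicit mean (12 per field) chosen to reproduce realistic field
occupancies of ≤ 10 simultaneous spheroids.

Firm (post-arrest) bonds get their own, much more shear-resistant
catch-slip parameters, used by the detachment-ramp simulation: survival
per ramp step is exp(−k_off_firm(τ)·hold).  Under the defaults (a = 0.05,
f_c = 0.5, b = 0.001, f_s = 0.6; 10 s holds) about three quarters of
adherent spheroids survive 1 dyn cm⁻² but none survive a ramp to
4 dyn cm⁻².  EDTA mode models calcium chelation as k_on = 0 with all
off-rates multiplied by 50, which empties the adherent pool at or below
1 dyn cm⁻².

### The exact chain oracle

`analytic_outcome_probabilities` computes latent-outcome probabilities of
the generative chain exactly, by dynamic programming over (state, frames
spent free, frames spent rolling) — position is a deterministic function
of those counts — marginalised over entry frames and the diameter
distribution.  Besides the latent end-state distribution it reports the
**operational adhesion probability**: the probability that the final
observed interval is stationary, which is the event the assay's
"stationary for more than one frame, through the end of recording" rule
actually measures (a tether that straddles the end of the recording is
observationally arrest).  This oracle validates the simulator (chi-square
goodness of fit of transition frequencies) and anchors the calibration.

### Calibration (done once, then frozen)

Free parameters were set so that (i) the operational adhesion probability
over the shear grid {0.03, 0.04, 0.05, 0.07, 0.1, 0.15} dyn cm⁻² peaks at
0.05 with a comfortable margin (+9 percentage points over the best
neighbour for the high-avidity condition), (ii) bonds at the optimum live
~4 s so that rolling is actually observable at 1 fps, and (iii) the two
conditions' operational adhesion probabilities at 0.05 are 0.40 and 0.17
(≈ 2.3-fold), with the low-avidity condition also rolling faster
(ρ = 0.25 vs 0.15).  The frozen values are a = 16100 s⁻¹, f_c = 0.004,
b = 0.00155 s⁻¹, f_s = 0.012 dyn cm⁻² (k_off(0.05) = 0.16 s⁻¹),
k_arrest = 0.08 s⁻¹, k_release = 0.40 s⁻¹, and k_on = 0.1967 s⁻¹ (M-CSC)
or 0.0551 s⁻¹ (NM-CSC).  These numbers are calibration artifacts of this
package, not measurements.

### Image rendering

Fields render as 16-bit stacks at 4 μm px⁻¹: each spheroid is a soft-edged
disc (half-maximum width equal to its diameter, 1.5 px edge), composed
with the pointwise maximum (opaque bodies do not add), over a flat
background of 100 counts with Poisson noise; plateau intensity 2000
counts.  TIFF metadata records pixel size and frame interval.

## Detection and tracking

Detection: median background subtraction, Otsu threshold (with a
robust-noise guard so blank frames yield nothing), distance-transform
watershed to split touching spheroids, and per component a diameter from
the area above half the plateau intensity — nearly threshold-independent
for soft-edged discs — plus an intensity-weighted centroid over that
half-maximum core, which a touching neighbour's skirt cannot drag.  The
per-frame size gate is the 70–100 μm collection gate widened by 5 μm so
boundary objects do not flicker; the exact gate is re-applied per track on
the median diameter (`apply_track_gate`).

Linking is greedy nearest-neighbour with a flow-aware asymmetric gate
(downstream reach 1.5·u_h·Δt, upstream and lateral one diameter) and a
cost equal to the distance from the detection to the nearest of three
predicted positions — stay (arrest), constant velocity, one hydrodynamic
step — so a mover overtaking an arrested spheroid, or a fresh track with
no velocity estimate yet, resolves correctly.  One missed detection is
tolerated (memory = 1 frame).  On rendered benchmarks (≤ 10
spheroids/field) this recovers ≥ 95% of true links with ≤ 2% identity
switches.

## Classification

Per-interval speeds are Euclidean displacements over elapsed (gap-aware)
time.  The reference velocity u_ref is either analytic (u_h at the
cohort's median diameter) or empirical (90th percentile of all interval
speeds); below five tracks the empirical mode falls back to analytic.
Classes are assigned with precedence adhesion > rolling > tethering >
free, making the three phenotypes a partition:

* **adhesion** — ≥ 2 consecutive observed frames with per-frame
  displacement < ε = 5 μm, persisting to the end of the track (an
  "anywhere-arrest" variant exists);
* **rolling** — a contiguous run of intervals all below c·u_ref whose
  summed path exceeds one median diameter; the rolling velocity is
  path/time over the best such run;
* **tethering** — a sub-threshold (or arrested) interval followed by a
  return to ≥ c·u_ref;
* **free** — otherwise; single-detection tracks are flagged and counted
  in the denominator by default (configurable).

c defaults to 0.5 (the leukocyte-rolling convention); c = 1 expresses the
literal "below the hydrodynamic velocity" reading, which at 1 fps
misclassifies noisy free spheroids.  ε = 5 μm is ~6% of a diameter and
five times the simulator's positional jitter.  Cohort percentages pool
counts across fields before dividing, never averaging percentages.

A brute-force reference classifier (exhaustive window scans) agrees with
the production implementation on 100% of 1,000 randomized tracks; this
equivalence is asserted in the test suite.

## Statistics

Pearson chi-square without continuity correction (Yates optional), with a
warning when any expected count is below 5; classical pooled-variance
Student's t with the one-tailed alternative stated explicitly (Welch
optional); median fold changes with Katz log-scale confidence intervals
for proportion ratios; stars at p < 0.05 / 0.01 / 0.001 with strict
inequalities.  No multiple-testing adjustment is applied by default
(per-comparison reporting); a Holm helper exists.  Both engines match
independent implementations to 1e-10 and the chi-square test's null
rejection rate calibrates to 5% ± 1.5% over 2,000 simulated null
replicates.

## Problem sizes

Default validation runs use cohorts of roughly 300–700 spheroids per
condition (30–100 fields at ~12 arrivals each), 8 rendered fields for the
imaging round trip, 1,000 random tracks for the classifier-oracle check
and 2,000 replicates for the null calibration; all are configurable.

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis assumes —
free near-wall convection, stochastic capture with a catch-bond optimum,
two-condition contrasts, Poisson noise on rendered discs — so passing
tests demonstrate that the pipeline recovers known ground truth under
that structure.  Real assay data differ in ways the generator does not
emulate: mesothelial autofluorescence and uneven illumination, spheroid
deformation and disaggregation, out-of-focus drift, lateral collisions
and margination, bond-level force heterogeneity.  Performance on real
videos therefore needs its own validation; the interchange CSV schema is
designed to make that drop-in.

## Known limitations

* The latent chain is memoryless per spheroid; cooperative or
  history-dependent adhesion is out of scope.
* Substrate occlusion is the only spheroid–spheroid interaction; movers
  do not deflect around parked spheroids, so brief projected overlaps
  still occur and are handled by the tracker, not the physics.
* The detachment ramp models rupture of already-firm bonds only; it does
  not re-simulate trajectories under ramped flow.
* EDTA mode is a rate multiplier, not a chemistry model.
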