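# Methods

This note records the models, numerical choices, and known limitations
behind `depotflow`, in the package's own terms.

## Two-compartment transport model

**Geometry and physics.** A well of neat ethanol (height `h_E = 1.5` cm,
diffusivity `D_E = 1e-5` cm²/s) sits below a tumor slab (height `h_T`,
measured per sample with a micrometer; diffusivity `D_T`, unknown),
separated by a membrane fully permeable to ethanol. Both compartments obey
the 1-D diffusion equation. Boundary and interface conditions:

* bottom (`x = 0`): zero flux;
* interface (`x = h_E`): flux continuity and the partition jump
  `c_T = Phi_ET * c_E`, with `Phi_ET = 1` by default (the membrane does not
  discriminate small molecules);
* top surface (`x = h_E + h_T`): Robin condition `-D_T dc/dx = K_EV c`,
  modelling first-order evaporative loss with `K_EV` a surface mass-transfer
  coefficient (cm/s). Initial state: relative concentration 1 in the
  ethanol well, 0 in the tumor.

The observable is the relative concentration at the top surface — what the
confocal Raman probe measures. With `K_EV = 0` mass conservation fixes the
plateau at `Phi_ET * h_E / (h_E + Phi_ET * h_T)` (0.75 for `h_T = 0.5` cm),
which serves as an analytic anchor in the tests.

**Where the loss term acts.** The literature description of `K_EV` as a
"first-order loss" is compatible with two readings. The default places it
in the surface boundary condition (units cm/s); `kev_mode="volumetric"`
instead applies a sink `-K_EV c` (units 1/s) throughout the tumor. Both are
implemented; fit reports record which was used. Neither is asserted to be
the original authors' choice.

**Numerics.** Finite volumes on the partition-weighted variable
`a = c / Phi(x)` (continuous across the interface), so the capacity is
`Phi` in the tumor and the conductivity `D * Phi`; harmonic face
conductances handle the coefficient jump without special-casing. Faces are
sine-graded toward the interface in the ethanol well and cosine-graded
toward both the interface and the top surface in the tumor, because the
early-time front at the interface and the Robin observation point are where
resolution pays. Time stepping is backward Euler on geometric dt-doubling
blocks (default ~400 steps over the horizon): unconditionally stable for
the stiff contrast `D_E / D_T ≈ 2–10`, first-order accurate with steps
graded like the solution's early-time scale, and the banded Cholesky factor
is reused within each constant-dt block. Backward-Euler finite volumes
conserve mass to solver roundoff when `K_EV = 0` (observed drift ~1e-12
relative; the test budget is 1e-6). Default resolution is 60 cells per
compartment; halving the step changes the surface curve by well under 0.5%
of its scale. Output times are interpolated from the dense step grid.

**Verification against a closed form.** For early times, the two-medium
semi-infinite contact solution applies: at depth `z` into the tumor,
`c = B erfc(z / (2 sqrt(D_T t)))` with
`B = Phi sqrt(D_E) / (sqrt(D_E) + Phi sqrt(D_T))`. The solver is compared
to this oracle at interior depths while the penetration depth
`2 sqrt(D_T t)` is under `h_T / 3` (so neither far boundary is felt);
agreement is ~0.3%, tested at 2%. An optional single image-reflection term
extends the oracle to the insulated top surface.

**Inverse problem.** `(D_T, K_EV)` are estimated by bounded nonlinear least
squares (`scipy.optimize.least_squares`, gradient tolerance 1e-10) on the
unweighted SSE of the relative-concentration residuals, with `D_T`
optimized in log10 space (it ranges over decades) and default bounds
`D_T ∈ [1e-8, 1e-4]` cm²/s, `K_EV ∈ [0, 1e-2]`. Multi-start (default 5
starts: one mid-bounds, the rest log-uniform, seeded) guards against local
minima; the best local optimum by SSE is returned with per-start
diagnostics. 95% half-widths come from the Gauss–Newton curvature via the
delta method and should be read as local, not profile, intervals.

**Identifiability and schedules.** The fit needs observations spanning the
concentration rise: for `h_T = 0.5` cm and `D_T ≈ 2e-6` cm²/s the rise
unfolds over ~1e5 s, so synthetic acquisition schedules are built by
`rise_schedule`, which extends the horizon until the surface curve reaches
~90% of the conservative plateau or has visibly peaked (with evaporation
the curve decays after its maximum and never attains that plateau). A
series that is flat at zero raises a non-identifiability error rather than
returning a boundary estimate.

## Raman unmixing

Each measured spectrum is decomposed against two pure-component references
by non-negative least squares; the relative ethanol concentration is the
weight fraction `w_e / (w_e + w_t)`. Non-negativity is a physical
constraint and coincides with the unconstrained normal-equations solution
whenever that solution is feasible — the tests check both routes. The
alternative normalization (ethanol weight alone against a pure-ethanol
calibration) is available via `normalization="ethanol_weight"`, since which
convention the original analysis used is not recorded. No baseline
correction or cosmic-ray removal is applied: the synthetic spectra contain
neither, and adding preprocessing stages would change what the round-trip
tests demonstrate. Series values are clipped to [0, 1] for downstream
fitting, with raw values retained (`c_raw`); partition coefficients above 1
can legitimately push the raw surface concentration past 1.

## Morphometrics

Masks come from two threshold rules: absolute intensity (inclusive `>=`,
matching a "this value or higher" selection, used for radiant-efficiency
images) and channel saturation (`> 0.8 ×` the dtype's full scale, used for
RGB micrographs). Compactness is `4 pi A / P^2` with `A` the whole-pixel
count (scaled to mm² when a scale is present) and `P` a sub-pixel
marching-squares contour length measured on the mask after light Gaussian
smoothing (`sigma = 1.5` px). The smoothing matters: contouring the raw
binary mask traces the staircase mid-crack path and inflates a disk's
perimeter by ~6%, putting a perfect circle near 0.90 instead of 1. With
smoothing, a rasterized disk of radius ≥ 50 px scores 0.997–1.00 and a
large square converges to `pi/4` from above, the two analytic anchors. The
estimator is recorded in each result's provenance string.

By default all supra-threshold components are pooled (leakage lobes reduce
compactness through added perimeter and components); `largest_only=True`
restricts to the largest 8-connected component. Holes contribute perimeter,
since blanching and leakage create genuine signal voids. Spherical
retention volume assumes the section passes through the center of a
spherically distributed injection: `r1 = sqrt(A/pi)`,
`V1 = (4/3) pi r1^3`; this overestimates aspherical depots and is reported
as a ratio to the injected volume (1 µL = 1 mm³).

## Volumetrics

Necrotic volume is the rectangle-rule sum `V = sum A(x_i) dx` exactly as
the assay defines it (`dx = 2` mm sectioning by default); a trapezoid
variant exists but is never the default, so reported volumes match the
printed convention. Spacing must be uniform to 1% — missing sections are
rejected, not interpolated, because serial coverage is assumed complete.
The rectangle rule's error against an analytic sphere is O(dx) and the
tests verify it shrinks monotonically on nested grids.

## Cohort statistics

* Caliper volume `V = W^2 L / 2`; width/length are swapped with a logged
  note if recorded in the wrong order.
* Surrogate survival: first crossing of 1500 mm³ (configurable; 2000 mm³ is
  the humane endpoint), linearly interpolated in volume between bracketing
  measurement days. A first measurement already above threshold events on
  that day. Animals dying earlier are censored at death by default — the
  humane endpoint is recorded as an adverse event, not a tumor event —
  with `death_is_event=True` as the alternative.
* Kaplan–Meier and log-rank via `lifelines`; both are validated against
  hand-computed product-limit tables and the textbook O−E/V statistic to
  1e-10, and the log-rank type-I error on null synthetic cohorts (equal
  growth rates, n = 10/arm, 500 replicates) is checked to sit in
  [0.03, 0.08] at nominal 0.05.
* Adverse events: Pearson chi-squared on 2×2 tables, df = 1, no continuity
  correction by default (flag available).
* Group comparisons: Welch ANOVA (honoring the unequal-variance design)
  with the classical F as an option, then Tukey HSD on untransformed means
  via the studentized-range distribution.
* Grubbs two-sided single-outlier test, implemented directly (no installed
  package provides it): `G = max|x - mean|/s` against
  `((n-1)/sqrt(n)) sqrt(t^2/(n-2+t^2))` at `alpha/(2n)`.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* each analysis stage
assumes, not the instruments:

* Reference spectra are sums of Gaussian peaks at interleaved seeded
  centers — smooth, non-negative, well-conditioned — not literature ethanol
  Raman bands. Only the linear-mixture structure matters to NNLS unmixing;
  fluorescence background, cosmic rays, and detector noise shape are not
  modelled, so passing round-trips demonstrate correctness of the unmixing
  and fitting machinery, not robustness to raw instrument artifacts.
* Injection images are a bright disk plus optional rectangular finger
  lobes over a noisy sub-threshold background; real IVIS images add animal
  autofluorescence and pose variation that are out of scope.
* Section profiles are exact spherical caps `A = pi (r^2 - x^2)` with
  optional Gaussian area noise; the default offset 0 places one section
  through the center, since section registration is not recorded in the
  assay description.
* Cohorts grow exponentially, `V(t) = v0 exp(k t)` with lognormal
  measurement noise (default CV 10–15%), measured Mon/Wed/Fri — the
  simplest monotone model producing the observed survival-curve structure.
  Default `v0 = 50` mm³ matches the treatment-day tumor size; growth rates
  around 0.14/day bring untreated tumors to 1500 mm³ in ~3.5 weeks,
  consistent with the study's monitoring window. Real tumors regress,
  plateau, and ulcerate; none of that is modelled.
* Adverse events are independent Bernoulli draws per group.

Group-level diffusion cohorts for the EC-ethanol vs neat-ethanol contrast
draw per-sample true `D_T` from normal distributions at the published group
means and SDs (3.3 ± 1.5 ×10⁻⁶ vs 5.9 ± 1.2 ×10⁻⁶ cm²/s, n = 7 and 6),
truncated to [5e-7, 9.9e-5] cm²/s to stay physically plausible and inside
the fit bounds, then simulate and refit each sample's assay before testing
the fitted groups.

## Problem sizes and determinism

Defaults were chosen so a full analysis is interactive on one CPU: 60 cells
per compartment and ~400 implicit steps per forward solve (a few
milliseconds), 2–5 optimizer starts per fit (a fit takes ~1–4 s), 20-seed
recovery studies, 500-replicate calibration runs, and 5-replicate group
contrasts. Every stochastic component takes an explicit integer seed and
uses `numpy.random.default_rng`; identical arguments and seed give
bit-identical outputs.

## Known limitations

* The transport model is 1-D planar; radial depot geometry, convection,
  pressure-driven flow, and EC gelation kinetics are out of scope.
* `D_T` and `K_EV` can trade off when observations stop before the curve's
  plateau or peak; the curvature-based intervals do not capture that
  jointly. The `time_to_half_plateau` diagnostic helps flag poorly
  designed schedules.
* Compactness depends on the perimeter estimator at the few-percent level;
  comparisons should use a single estimator throughout (the provenance
  string makes this auditable).
* The surrogate-survival interpolation is linear in volume between
  measurements; for exponential growth this biases crossing times slightly
  late (well under one measurement interval at the default schedule).
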