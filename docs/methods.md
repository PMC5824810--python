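# Methods

This note records the models implemented in `memscaffold`, the parameter
choices behind their defaults, the synthetic-data conventions, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Scaffold geometry

A curved scaffold is treated as a circular arc of contour length
*L* = 110 nm. Two radii coexist: the TEM-measured radius of curvature
(46 nm for the half-circle design H, 84 nm for the quarter-circle Q) and
the arc-derived radius *L*/θ from the curvature angle (131° and 73°,
giving 48.1 and 86.3 nm). The two disagree by 3–5%, presumably because a
folded origami relaxes slightly relative to its designed arc.
`ScaffoldDesign` stores both and keys every reported quantity (curvature
*C* = 1/*R*, predicted tube diameter 2*R*) off the measured radius; the
arc convention θ/*L* is exposed separately because some printed
curvature figures (11.6 /µm for Q) follow it rather than 1/*R*TEM
(11.9 /µm). We do not guess which convention a given external number
used; both are available and the discrepancy is documented here.

Reporting rounds tube diameters to the nearest 10 nm and coverage to the
nearest percent, matching how such figures are conventionally quoted
(2·84 = 168 → "~170 nm"; σ·A at 50 and 90 /µm² → 9% and 16%).

Units: all lengths are nm internally; curvature crosses to 1/µm and
densities to 1/µm² only at explicit boundaries (`NM_PER_UM`).

## ADE bending energetics

The area-difference-elasticity energy of a uniform-curvature patch is

    E = kappa * [ (A/2)(C1 + C2 - C0)^2
                  + (alpha/2) (pi / (A D^2)) (dA - dA0)^2 ]   (kBT)

Defaults: κ = 23.1 kBT (DOPC), α = κ̄/κ = 3/π, C₀ = 0 (symmetric
bilayer), D = 4 nm, ΔA₀ = 0. For a patch of area A bent into a cylinder
of radius R we take C₁ = 1/R, C₂ = 0 and the geometric leaflet area
difference ΔA = D·A/R (leaflet midplanes separated by the bilayer
thickness). With α = 3/π the tube energy then collapses to the closed
form 2κA/R², in which D cancels — a property the tests assert directly.
An independent quadrature oracle (element-by-element summation over a
discretised cylinder, with ΔA accumulated numerically as D·Σc·dA)
agrees with the closed form to 1e-6 relative.

Energies stay in kBT throughout; joule conversion uses kB·T at a
configurable temperature (default 298.15 K). For the three reference
patches the closed form gives 11.79 kBT (A = 1800 nm², R = 84 nm),
39.30 kBT (1800 nm², 46 nm) and 8.78 kBT (23 nm², 11 nm). Quoted
literature values for these cases (~11, ~38, 9 kBT) are rounded and were
presumably computed with slightly different rounding of κ, A or R; our
tests accept a 10% window (5% for the small patch) around them.

Adhesion free energy uses the 1 M standard state: ΔG = ln(Kd/1 M) kBT,
so Kd = 0.68 nM gives −21.1 kBT and 2.0 nM gives −20.0 kBT. The
cost-benefit rule declares tubulation permitted iff |ΔG| ≥ E_bend;
equality counts as permitted (an arbitrary but fixed and tested
tie-break). A flat design has zero tube bending cost but also templates
no tube, so the pipeline reports its decision as undefined rather than
trivially permitted.

## Langmuir isotherm fitting

Ordinary least squares on raw per-vesicle intensities against
I = Imax/(1 + Kd/C), parameterised in (log Kd, log Imax) so positivity
is structural. Initialisation is deterministic: Imax from the 95th
percentile of intensities, Kd from the concentration whose intensity is
nearest half of that. Standard errors come from the Jacobian-based
covariance of the log-parameters, mapped by the delta method
(sd(p) = p·sd(log p)). No weighting is applied by default; a
per-concentration-mean mode (`pooled=False`) is available since it is
not generally knowable whether an external fit pooled vesicles or
averaged per concentration. Independent titration repeats are fit
separately and summarised as mean ± s.d. of Kd. Fits require at least
two distinct concentrations and warn below a 4-fold range.

## FCS densities

The one-component 2D diffusion model G(τ) = (1/N)/(1 + τ/τD) is fit
unweighted over the (log-spaced) lag grid in (log N, log τD), initialised
from the amplitude at the shortest lag and the lag nearest half
amplitude. Curves that do not decay toward half amplitude within the
grid are rejected as having unidentifiable τD. Triplet/photophysics
terms are deliberately omitted: the bare one-component model is the one
being studied, and membrane-bound scaffolds are slow enough that the
triplet regime is well below the fitted lags.

Detection-volume calibration follows τD = r0²/(4D): a reference dye of
known D (414 µm²/s for Alexa488 at 25 °C) fixes the waist r0
(207 ± 7 nm). Carrying D to the working temperature uses Stokes–Einstein
scaling D₂ = D₁(T₂/T₁)(η₁/η₂) with the standard empirical Vogel-type
water-viscosity correlation η = 2.414e-2·10^(247.8/(T−140)) mPa·s,
accurate to ~0.3% between the supported 15–40 °C (0.8906 mPa·s at
25 °C); 25 → 27.5 °C raises D by ~6.7% to ≈442 µm²/s.

Surface density is σ = N/(πr0²); the reduced density ρ = σL² uses the
configured scaffold length (110 nm default, never hard-coded). ρ > 0.2
marks crowding: such estimates carry `valid=False`, are excluded from
the intensity calibration (which needs ≥ 3 valid pairs and reports how
many it dropped), and densities there are instead predicted from the
calibration line σ = slope·I + intercept (clipped at zero). ρ = 0.2
exactly is treated as valid, matching the strict-inequality direction of
the crowding rule.

## Morphology statistics

Vesicle outcomes use a closed, case-normalised vocabulary (spherical,
outward_tubules, inward_tubules, evagination_invagination, flaccid,
burst); burst vesicles count in condition totals. Fractions carry Wilson
score intervals (default 95%) — preferable to Wald at the n of tens
typical of GUV counting.

The tubulation density threshold is the smallest density whose
interpolated tubulated fraction reaches a target. The
(density, fraction) response is first passed through isotonic regression
(non-decreasing least-squares fit; a no-op on monotone data) so
experimental dips cannot create spurious crossings, then the crossing is
located by linear interpolation between the bracketing points. Tube
diameters are summarised as mean ± s.d. (ddof = 1) with the ratio to the
geometric prediction 2R.

## Synthetic data

The generator defines the conditions under which the package is
validated; none of the noise structures are measured properties of the
real system, and they are declared here as conventions:

- **Binding**: intensity = Langmuir(C; Kd, Imax) × lognormal noise with
  unit mean and CV 0.2; defaults Kd = 0.68 nM, Imax = 1000 a.u., 8
  concentrations spanning 0.01–50 nM, 15 vesicles each.
- **FCS**: exact model values on an 11-points-per-decade grid over 4
  decades from 0.1 ms, plus additive Gaussian noise (sd 0.002) on G;
  defaults N = 12, τD = 20 ms.
- **Morphology**: a Hill link P(tubules | σ) = 1/(1 + (σ50/σ)^h) with
  σ50 = 62 /µm² and h = 4, placing P(90) ≈ 0.82 (so ~90 /µm² tubulates
  >80% of vesicles while 50 /µm² initiates it in ~30%); non-tubulated
  vesicles split 0.8/0.1/0.1 among spherical/flaccid/burst.
- **Tube sections**: Normal(220, 70) nm, n = 35, floored at zero.

All draws flow from one integer seed through numpy's PCG64 generator, so
fixed seeds give byte-identical tables. Recovery tolerances were
calibrated by Monte-Carlo before being frozen into the tests: at these
defaults, Kd is recovered within ±25% and N within ±10% in well over 95%
of 200 seeded replicates. What passing shows: the fitters are unbiased
and correctly scaled under these noise models at these sizes. What it
does not show: robustness to the unmodelled features of real data —
vesicle-to-vesicle gain variation, photobleaching, membrane undulation
contributions to G, misclassification of morphologies.

## Pipeline

`run_pipeline` composes the stages exactly as the quantities combine:
fitted Kd → ΔG; design radius and footprint → bending cost; their
comparison → decision; FCS dilution series → densities and the intensity
calibration (the simulated series spans relative particle numbers
0.04–1.5 so both regimes are populated); morphology table → fractions
and thresholds. The JSON report embeds the resolved-config hash, seed
and package version; re-running with the same inputs is byte-identical.
Problem sizes in the default run (120 vesicles per titration, 8 FCS
curves of 45 points, 360 morphology calls) were chosen as a realistic
single-session dataset that keeps a full run under a second.

## Known limitations

- Patches are independent: no scaffold–scaffold coupling, no vesicle
  shape minimisation, no spontaneous-curvature phase behaviour.
- Equilibrium only; no binding kinetics.
- The crowding boundary 0.2 is taken as given, not re-derived.
- Image analysis (intensity extraction, morphology classification) is
  upstream and out of scope; the package consumes its output tables.
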