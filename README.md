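# memscaffold

Quantitative analysis of how curved, BAR-domain-mimicking DNA-origami
nanoscaffolds bind and tubulate giant unilamellar vesicles (GUVs).

Experiments of this kind produce three kinds of table — per-vesicle
fluorescence intensity vs bulk scaffold concentration (a binding
titration), FCS autocorrelation curves of membrane-bound scaffolds, and
per-vesicle morphology calls — and interpret them through a small set of
models. This package implements that full analysis chain as a tested
library, for membrane biophysicists who want to run each stage on their
own tables or probe the method itself on synthetic data with known ground
truth.

## The models

- **Scaffold geometry.** A curved scaffold is a circular arc of contour
  length *L* = 110 nm with measured radius *R*; its curvature is
  *C* = 1/*R* and it templates a membrane tube of diameter 2*R*. At
  surface density σ, scaffolds of footprint *A* cover the membrane
  fraction σ·*A*.
- **Langmuir binding isotherm.** Membrane-bound intensity vs bulk
  concentration: *I* = *I*max / (1 + *K*d/*C*bulk), fit by least squares
  in log-parameter space; *K*d is the concentration at half coverage.
- **FCS surface density.** For 2D diffusion through a Gaussian spot of
  waist *r*₀, *G*(τ) = (1/*N*)/(1 + τ/τD). Fitted *N* gives the absolute
  density σ = *N*/(π*r*₀²); the reduced density ρ = σ*L*² flags the
  crowding regime (ρ > 0.2), where densities come instead from a linear
  intensity calibration anchored in the valid regime.
- **ADE bending energetics.** The area-difference-elasticity energy
  ε = κ[(1/2)∫d*A*(C₁+C₂−C₀)² + (α/2)(π/(*A D*²))(Δ*A*−Δ*A*₀)²]
  with κ = 23.1 kBT (DOPC) and α = 3/π reduces, for a tube, to
  2κ*A*/*R*². Adhesion contributes ΔG = ln(*K*d/1 M) kBT per scaffold,
  and tubulation is predicted iff |ΔG| ≥ ε_bend.
- **Morphology statistics.** Per-condition fractions of vesicle outcomes
  with Wilson confidence intervals, isotonic-smoothed interpolation of the
  density threshold for tubulation, and tube-diameter summaries against
  the geometric prediction.

Because no raw tables are publicly deposited for this system, the
`simulate` module generates all three table types with known ground truth
and study-like defaults; every fitter is validated by parameter recovery
on that generator.

## Worked example

`python examples/bending_vs_adhesion.py`:

```
Q3 (R = 84 nm, Kd = 0.68 nM): bending 11.8 kBT vs adhesion -21.1 kBT -> tubulation permitted (margin +9.3 kBT)
H3 (R = 46 nm, Kd = 2.0 nM): bending 39.3 kBT vs adhesion -20.0 kBT -> not permitted (margin -19.3 kBT)
amphiphysin (R = 11 nm, A = 23 nm^2): bending cost 8.8 kBT
```

The moderately curved quarter-circle design gains 21.1 kBT of adhesion
free energy per bound scaffold — more than the 11.8 kBT it costs to bend
its 1800 nm² membrane footprint into the 168 nm tube it templates — so it
can tubulate. The highly curved half-circle design binds slightly more
weakly (−20.0 kBT) but would have to pay 39.3 kBT, so it cannot; a BAR
domain itself (small footprint, tight radius) sits at ~9 kBT.

The other scripts in `examples/` walk through each capability: geometry
(`scaffold_geometry.py`), titration fitting (`binding_fit.py`), FCS
densities (`fcs_density.py`), morphology thresholds
(`morphology_thresholds.py`) and the end-to-end run
(`full_pipeline.py`). The same stages are available from the shell:

```
memscaffold simulate --seed 1 --out simdata
memscaffold run-all --input simdata --out report.json
memscaffold fit-binding --input simdata/binding.csv --condition Q3
```

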