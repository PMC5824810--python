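"""Arc geometry of the three scaffold designs: curvature, predicted tube
diameter and membrane coverage.

A curved scaffold is a 110 nm arc; its TEM-measured radius sets the
curvature C = 1/R and the diameter 2R of the membrane tube it templates.
At a given surface density sigma, bound scaffolds of footprint A cover the
fraction sigma*A of the membrane.
"""

from memscaffold import coverage_fraction, predicted_tube_diameter
from memscaffold.geometry import DEFAULT_DESIGNS, FlatDesignError

for name, design in DEFAULT_DESIGNS.items():
    line = (
        f"design {name}: curvature {design.curvature_per_um:5.1f} /um "
        f"(arc convention {design.arc_curvature_per_um:5.1f} /um)"
    )
    try:
        line += f", predicted tube {predicted_tube_diameter(design, round_to_nm=10):.0f} nm"
    except FlatDesignError:
        line += ", no tube predicted (flat)"
    print(line)

for sigma in (50.0, 90.0):
    pct = 100 * coverage_fraction(sigma, 1800.0)
    print(f"at {sigma:.0f} scaffolds/um^2 the membrane is {pct:.0f}% covered")

# The two curvature conventions (1/R_TEM vs theta/L) differ by ~3%; the
# coverage window 9-16% corresponds to the density range over which
# tubulation switches on.
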