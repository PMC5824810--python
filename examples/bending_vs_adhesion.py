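"""The energetic cost-benefit rule for tubulation.

Bending a flat membrane patch the size of a scaffold footprint
(A = 1800 nm^2) into the tube the scaffold templates costs 2*kappa*A/R^2
(ADE model, kappa = 23.1 kBT for DOPC).  The adhesion free energy of one
bound scaffold, dG = ln(Kd/1M) kBT, is what can pay for it: tubulation is
predicted only when |dG| >= E_bend.
"""

from memscaffold import (
    MembraneMechanics,
    adhesion_free_energy,
    cost_benefit,
    tube_bending_energy,
)

mech = MembraneMechanics()
cases = [
    ("Q3 (R = 84 nm, Kd = 0.68 nM)", 1800.0, 84.0, 0.68e-9),
    ("H3 (R = 46 nm, Kd = 2.0 nM)", 1800.0, 46.0, 2.0e-9),
    ("amphiphysin (R = 11 nm, A = 23 nm^2)", 23.0, 11.0, None),
]

for label, area, radius, kd in cases:
    bend = tube_bending_energy(area, radius, mech)
    if kd is None:
        print(f"{label}: bending cost {bend:.1f} kBT")
        continue
    adhesion = adhesion_free_energy(kd)
    verdict = cost_benefit(adhesion, bend)
    print(
        f"{label}: bending {bend:.1f} kBT vs adhesion {adhesion.delta_g_kbt:.1f} kBT"
        f" -> {'tubulation permitted' if verdict.permitted else 'not permitted'}"
        f" (margin {verdict.margin_kbt:+.1f} kBT)"
    )

# The moderately curved design's adhesion (-21.1 kBT) exceeds its 11.8 kBT
# bending cost, so it can tubulate; the highly curved design's 39.3 kBT
# cost overwhelms its -20 kBT adhesion, so it cannot.
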