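"""Per-vesicle morphology statistics and the tubulation density threshold.

Vesicle outcomes are drawn from a Hill-type link between scaffold surface
density and tubulation probability (midpoint 62 /um^2, slope 4); the
threshold extractor then reads back the density at which 50% and 80% of
vesicles tubulate.
"""

from memscaffold import morphology_fractions, threshold_density
from memscaffold.simulate import MorphologySimConfig, gen_morphology_dataset

cfg = MorphologySimConfig()
densities = [10.0, 30.0, 50.0, 70.0, 90.0, 120.0]
points = []
observations = []
for i, dens in enumerate(densities):
    obs = gen_morphology_dataset([dens] * 60, cfg, seed=100 + i,
                                 condition=f"sigma={dens:.0f}")
    observations.extend(obs)
    frac = sum(o.morphology == "outward_tubules" for o in obs) / len(obs)
    points.append((dens, frac))
    print(f"sigma = {dens:5.0f} /um^2: {100 * frac:4.0f}% tubulated (n = {len(obs)})")

for target in (0.5, 0.8):
    th = threshold_density(points, target)
    print(f"density for {100 * target:.0f}% tubulation: {th:.0f} /um^2")

table = morphology_fractions(observations).table
row = table[(table.condition == "sigma=90") & (table.morphology == "outward_tubules")]
print("at 90 /um^2, Wilson 95% CI on the tubulated fraction:",
      f"[{row.ci_low.iloc[0]:.2f}, {row.ci_high.iloc[0]:.2f}]")

# The 50% threshold lands near the generator midpoint (62 /um^2) and the
# 80% threshold near 90 /um^2 -- the density at which almost all vesicles
# present tubules.
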