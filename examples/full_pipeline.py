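"""One end-to-end run: simulate all tables, fit every stage, decide.

Equivalent to `memscaffold run-all` from the shell.  The report holds, per
scaffold design, the fitted Kd, the adhesion free energy, the ADE bending
cost and the tubulation decision, plus the FCS density calibration and the
morphology thresholds.
"""

from memscaffold import run_pipeline

report = run_pipeline({"simulation": {"seed": 1}})

for name, entry in report.conditions.items():
    decision = entry["decision"]
    verdict = ("no tube predicted (flat)" if decision is None
               else "tubulation permitted" if decision["permitted"]
               else "not permitted")
    print(
        f"{name}: Kd = {entry['binding']['kd_nM']:.2f} nM, "
        f"dG = {entry['delta_g_kbt']:.1f} kBT, "
        f"bend = {entry['bending_kbt']:.1f} kBT -> {verdict}"
    )

cal = report.fcs["calibration"]
print(f"intensity->density calibration: slope {cal['slope']:.3f} /um^2 per a.u., "
      f"R^2 = {cal['r_squared']:.3f} ({cal['n_excluded']} crowded curves excluded)")
th = report.morphology["threshold_density_per_um2"]
print(f"80% tubulation threshold: {th['0.8']:.0f} particles/um^2")
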