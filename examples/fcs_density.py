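"""From an FCS autocorrelation curve to an absolute surface density.

Membrane-bound particles diffusing through a calibrated confocal spot
(waist r0 = 207 nm) give G(tau) = (1/N)/(1 + tau/tau_D).  Fitting N and
dividing by the spot area pi*r0^2 yields the surface density sigma; the
reduced density rho = sigma*L^2 (L = 110 nm scaffold length) flags
crowding (rho > 0.2), where densities must come from an intensity
calibration instead.
"""

from memscaffold import DetectionVolume, fit_fcs, surface_density, waist_from_reference
from memscaffold.fcs import diffusion_time, temperature_correct_d
from memscaffold.simulate import FCSSimConfig, gen_fcs_curve

# Spot calibration: a reference dye of known D gives tau_D, hence r0.
d_ref = temperature_correct_d(414.0, 298.15, 300.65)  # dye D at the objective
tau_ref = diffusion_time(207.0, d_ref)
print(f"dye D corrected 414 -> {d_ref:.0f} um^2/s; "
      f"r0 = {waist_from_reference(tau_ref, d_ref):.0f} nm")

curve = gen_fcs_curve(FCSSimConfig(), seed=7)  # true N = 12, tau_D = 20 ms
fit = fit_fcs(curve)
dens = surface_density(fit, DetectionVolume(r0_nm=207.0), scaffold_length_nm=110.0)

print(f"fitted N = {fit.n_particles:.2f}, tau_D = {1e3 * fit.tau_d_s:.1f} ms")
print(f"sigma = {dens.sigma_per_um2:.0f} particles/um^2, rho = {dens.rho:.2f}, "
      f"valid = {dens.valid}")

# ~12 particles in a 207 nm spot is ~90/um^2 -- already rho > 0.2, i.e. in
# the crowded regime where the one-component model is only indicative.
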