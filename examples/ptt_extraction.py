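"""Extract single-mode PTT parameters from SAOS + LAOS observables.

The melt is characterized by a relaxation time (from the G'-G'' crossover),
a zero-shear viscosity (from the low-frequency limit of G''/omega) and a
PTT damping coefficient eps (from the third elastic harmonic ratio of a
large-amplitude cycle). Here the "measurements" are generated by the PTT
model itself with the packaged oil-free reference parameters, so the
extraction chain can be checked against known truth.
"""

import spc_rheoflow as sr
from spc_rheoflow import io, synthetic

truth = io.ptt_for_sample("SPC_0")
print(f"generating truth: eta0 = {truth.eta0_ref:g} Pa.s, "
      f"lambda = {truth.lambda_ref:g} s, eps = {truth.epsilon:g}")

sweep = sr.make_saos_sweep(sr.SweepSpec(
    model_kind="maxwell", omega_grid=synthetic.default_omega_grid(0.01, 100, 50),
    eta0=truth.eta0_ref, lam=truth.lambda_ref))
cycle = sr.ptt_laos_cycle(truth, gamma0=2.0, omega=1.0)
measures = sr.nonlinear_measures(
    sr.chebyshev_from_fourier(sr.decompose(cycle)))
print(f"measured e3/e1 at gamma0 = 2: {measures.e3_over_e1:+.5f}")

params = sr.extract_ptt(sweep, measures, gamma0_ref=2.0)
print(f"extracted: eta0 = {params.eta0_ref:.1f} Pa.s, "
      f"lambda = {params.lambda_ref:.4f} s, eps = {params.epsilon:.4f}")
tau, N1, eta = sr.ptt_steady_shear(params, gamma_dot=10.0)
print(f"viscometric check at 10 1/s: shear stress {tau:.0f} Pa, "
      f"N1 {N1:.0f} Pa, viscosity {eta:.0f} Pa.s "
      f"(shear-thinned from {params.eta0_ref:.0f})")
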