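"""Constitutive models for the melt: generalized-Newtonian and exponential PTT.

Model A (SAOS-informed) is a temperature-dependent power law,

    eta(gamma_dot, T) = K(T) * gamma_dot**(n(T) - 1)
    K(T) = K0 * exp[(Ea_k/R) * (1/T - 1/T_ref)]
    n(T) = n0 + alpha_n * (T - T_ref)

Model B (LAOS-informed) is the single-mode exponential Phan-Thien--Tanner
equation with no solvent contribution,

    f(tau) * tau + lambda(T) * tau^(upper-convected) = 2 eta0(T) D
    f(tau) = exp[(eps * lambda / eta0) * tr(tau)]

with Arrhenius shifts on eta0 and lambda. In steady simple shear the PTT
reduces (tau_yy = tau_zz = 0, tr tau = tau_xx) to the scalar equation

    u * exp(2u) = 2 eps lambda^2 gamma_dot^2,   u = eps*lambda*tau_xx/eta0

whose solution gives tau_xy = eta0*gamma_dot*exp(-u) and N1 = tau_xx; the
exact inverse gamma_dot(tau_xy) follows from u = 2 eps lambda^2 tau_xy^2 /
eta0^2, which the flow solver exploits.

Parameter extraction for Model B follows the SAOS/LAOS recipe: lambda from
the G'-G'' crossover frequency (lambda = 1/omega_c), eta0 from the
low-frequency limit of G''/omega, and eps by root-finding on the third
elastic harmonic ratio e3/e1 of a simulated LAOS cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import laos, saos
from .laos import OscillatoryCycle, NonlinearMeasures
from .saos import FrequencySweep

R_GAS = 8.314  # J/(mol K)

GAMMA_DOT_FLOOR = 1e-4  # 1/s; regularizes the power law at zero shear


@dataclass
class PowerLawTemperatureModel:
    """Apparent-viscosity law for Model A.

    K0 in Pa·s^n at T_ref (K); Ea_k in J/mol; alpha_n in 1/K. The evaluated
    exponent n(T) is clamped to (0, 2).
    """

    K0: float
    Ea_k: float
    n0: float
    alpha_n: float
    T_ref: float

    def __post_init__(self) -> None:
        if self.K0 <= 0:
            raise ValueError("K0 must be positive")
        if self.T_ref <= 0:
            raise ValueError("T_ref must be positive (kelvin)")

    def K(self, T: float | np.ndarray) -> float | np.ndarray:
        return self.K0 * np.exp((self.Ea_k / R_GAS) * (1.0 / T - 1.0 / self.T_ref))

    def n(self, T: float | np.ndarray) -> float | np.ndarray:
        return np.clip(self.n0 + self.alpha_n * (T - self.T_ref), 1e-6, 2.0)


@dataclass
class PTTParams:
    """Single-mode exponential PTT parameters (Model B).

    eta0_ref (Pa·s) and lambda_ref (s) at T_ref (K); eps dimensionless;
    E_eta, E_lambda in J/mol (Arrhenius activation energies).
    """

    eta0_ref: float
    lambda_ref: float
    epsilon: float
    E_eta: float = 0.0
    E_lambda: float = 0.0
    T_ref: float = 373.15

    def __post_init__(self) -> None:
        if self.eta0_ref <= 0 or self.lambda_ref <= 0:
            raise ValueError("eta0_ref and lambda_ref must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    def eta0(self, T: float | np.ndarray) -> float | np.ndarray:
        return self.eta0_ref * np.exp(
            (self.E_eta / R_GAS) * (1.0 / T - 1.0 / self.T_ref))

    def lam(self, T: float | np.ndarray) -> float | np.ndarray:
        return self.lambda_ref * np.exp(
            (self.E_lambda / R_GAS) * (1.0 / T - 1.0 / self.T_ref))


@dataclass
class MaterialProperties:
    """Bulk thermophysical properties: rho, cp(T) and k(T) polynomials.

    Polynomial coefficients are highest-order-first (numpy.polyval) with T
    in degC, matching the packaged table convention.
    """

    rho: float                    # kg/m^3
    cp_poly: list[float]          # J/(kg K), T in degC
    k_poly: list[float]           # W/(m K), T in degC

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        Tchk = np.linspace(10.0, 100.0, 10)
        if np.any(self.cp(Tchk) <= 0) or np.any(self.k(Tchk) <= 0):
            raise ValueError("cp(T) and k(T) must stay positive over 10-100 degC")

    def cp(self, T_degC: float | np.ndarray) -> float | np.ndarray:
        return np.polyval(self.cp_poly, T_degC)

    def k(self, T_degC: float | np.ndarray) -> float | np.ndarray:
        return np.polyval(self.k_poly, T_degC)


def apparent_viscosity(model: PowerLawTemperatureModel,
                       gamma_dot: float | np.ndarray,
                       T: float | np.ndarray) -> float | np.ndarray:
    """Model A apparent viscosity K(T)*gamma_dot^(n(T)-1), regularized below
    GAMMA_DOT_FLOOR to avoid the zero-shear singularity for n < 1."""
    if np.any(np.asarray(T) <= 0):
        raise ValueError("temperature must be positive kelvin")
    gd = np.maximum(np.asarray(gamma_dot, dtype=float), GAMMA_DOT_FLOOR)
    out = model.K(T) * gd ** (model.n(T) - 1.0)
    return float(out) if np.ndim(gamma_dot) == 0 and np.ndim(T) == 0 else out


def _ptt_trace_equation_solve(c: float, newton_tol: float = 1e-12,
                              max_iter: int = 100) -> float:
    """Solve u*exp(2u) = c (c >= 0) for u >= 0 by damped Newton."""
    if c <= 0.0:
        return 0.0
    # log-space initial guess: for large c, 2u ~ ln c - ln u
    u = min(c, 0.5 * np.log1p(c))
    u = max(u, 1e-12)
    for _ in range(max_iter):
        g = u * np.exp(2.0 * u) - c
        dg = (1.0 + 2.0 * u) * np.exp(2.0 * u)
        step = g / dg
        u_new = u - step
        # damping: keep iterate positive
        while u_new <= 0.0:
            step *= 0.5
            u_new = u - step
        if abs(u_new - u) <= newton_tol * max(1.0, abs(u_new)):
            return u_new
        u = u_new
    raise RuntimeError(f"PTT trace equation did not converge; last residual "
                       f"{u * np.exp(2 * u) - c:.3e}")


def ptt_steady_shear(params: PTTParams, gamma_dot: float,
                     T: float | None = None) -> tuple[float, float, float]:
    """Steady simple-shear viscometric functions of the exponential PTT.

    Returns (shear_stress Pa, N1 Pa, viscosity Pa·s) at the temperature-
    shifted eta0(T), lambda(T) (T in kelvin; None means reference state).
    """
    if gamma_dot < 0:
        raise ValueError("gamma_dot must be >= 0")
    eta0 = params.eta0_ref if T is None else float(params.eta0(T))
    lam = params.lambda_ref if T is None else float(params.lam(T))
    if gamma_dot == 0.0:
        return 0.0, 0.0, eta0
    c = 2.0 * params.epsilon * (lam * gamma_dot) ** 2
    u = _ptt_trace_equation_solve(c)
    f = np.exp(u)
    tau_xy = eta0 * gamma_dot / f
    N1 = 0.0 if params.epsilon == 0.0 else u * eta0 / (params.epsilon * lam)
    if params.epsilon == 0.0:
        N1 = 2.0 * eta0 * lam * gamma_dot**2  # UCM limit
    return float(tau_xy), float(N1), float(tau_xy / gamma_dot)


def ptt_shear_rate_from_stress(params: PTTParams, tau_xy: float | np.ndarray,
                               T: float | None = None) -> float | np.ndarray:
    """Exact inverse viscometric map gamma_dot(tau_xy) for the exponential PTT.

    From tau_xy = eta0*gamma_dot*e^-u and u*e^2u = 2 eps lam^2 gamma_dot^2
    it follows that u = 2*eps*lam^2*tau_xy^2/eta0^2 explicitly, hence
    gamma_dot = (tau_xy/eta0)*exp(u).
    """
    eta0 = params.eta0_ref if T is None else params.eta0(T)
    lam = params.lambda_ref if T is None else params.lam(T)
    tau = np.asarray(tau_xy, dtype=float)
    u = 2.0 * params.epsilon * (lam * tau) ** 2 / np.asarray(eta0) ** 2
    gd = (tau / eta0) * np.exp(u)
    return float(gd) if np.ndim(tau_xy) == 0 else gd


def ptt_laos_cycle(params: PTTParams, gamma0: float, omega: float,
                   T: float | None = None, samples_per_cycle: int = 256,
                   max_cycles: int = 50, rms_tol: float = 1e-6
                   ) -> OscillatoryCycle:
    """Integrate the PTT tensor ODE under gamma(t) = gamma0*sin(omega t)
    to the periodic steady state and return the final cycle.

    The shear-flow reduction keeps (tau_xx, tau_xy); tau_yy and tau_zz stay
    zero from a stress-free start. Periodicity is declared when the
    cycle-to-cycle RMS stress change drops below rms_tol (relative to the
    cycle RMS).
    """
    eta0 = params.eta0_ref if T is None else float(params.eta0(T))
    lam = params.lambda_ref if T is None else float(params.lam(T))
    eps = params.epsilon
    period = 2.0 * np.pi / omega
    t_eval = np.linspace(0.0, period, samples_per_cycle + 1)

    def rhs(t, y):
        tau_xx, tau_xy = y
        gd = gamma0 * omega * np.cos(omega * t)
        f = np.exp(eps * lam * tau_xx / eta0)
        return [(2.0 * lam * gd * tau_xy - f * tau_xx) / lam,
                (eta0 * gd - f * tau_xy) / lam]

    state = [0.0, 0.0]
    prev = None
    for cycle_idx in range(max_cycles):
        sol = solve_ivp(rhs, (0.0, period), state, t_eval=t_eval,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"PTT cycle integration failed: {sol.message}")
        stress = sol.y[1]
        state = [sol.y[0][-1], sol.y[1][-1]]
        if prev is not None:
            scale = np.sqrt(np.mean(stress**2))
            change = np.sqrt(np.mean((stress - prev) ** 2))
            if scale == 0.0 or change <= rms_tol * scale:
                break
        prev = stress
    else:
        raise RuntimeError(
            f"no periodic steady state within {max_cycles} cycles "
            f"(last relative RMS change {change / scale:.2e})")

    t = t_eval[:-1]
    return OscillatoryCycle(
        time=t,
        strain=gamma0 * np.sin(omega * t),
        strain_rate=gamma0 * omega * np.cos(omega * t),
        stress=stress[:-1],
        gamma0=gamma0, omega=omega,
        meta={"model": "ptt", "eta0": eta0, "lambda": lam, "epsilon": eps,
              "cycles_to_periodic": cycle_idx + 1},
    )


def maxwell_moduli(eta0: float, lam: float, omega: float | np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form single-mode Maxwell G'(omega), G''(omega)."""
    lw = lam * np.asarray(omega, dtype=float)
    Gp = eta0 * lam * np.asarray(omega) ** 2 / (1.0 + lw**2)
    Gpp = eta0 * np.asarray(omega) / (1.0 + lw**2)
    return Gp, Gpp


def _laos_e3_over_e1(params: PTTParams, gamma0: float, omega: float) -> float:
    cyc = ptt_laos_cycle(params, gamma0, omega)
    spec = laos.decompose(cyc, max_order=9)
    cheb = laos.chebyshev_from_fourier(spec)
    return cheb.e3_over_e1


def extract_ptt(sweep: FrequencySweep,
                laos_measures: NonlinearMeasures | float | None = None,
                gamma0_ref: float = 2.0, omega_ref: float = 1.0,
                eps_tol: float = 1e-4, T_ref: float = 373.15) -> PTTParams:
    """Extract (lambda, eta0, eps) from SAOS + LAOS outputs.

    lambda = 1/omega_c from the G'-G'' crossover; eta0 = lim G''/omega,
    estimated by an unweighted linear fit of G'' against omega over the
    lowest decade of the sweep (the Maxwell-consistent reading of the
    low-frequency plateau recipe eta0 = G'0 * lambda — both coincide for
    single-mode data, and the slope estimator is noise-robust; the
    G'0*lambda reading is reported in the returned params' ``notes``
    attribute for comparison). eps is found by bisection+secant (brentq)
    in [0, 1] so a simulated LAOS cycle at (gamma0_ref, omega_ref)
    reproduces the measured e3/e1.

    laos_measures may be a NonlinearMeasures, a bare e3/e1 float, or None
    (eps = 0, linear material).
    """
    omega_c = saos.find_crossover(sweep)
    if omega_c is None:
        raise ValueError("no G'-G'' crossover in sweep; lambda is undefined")
    lam = 1.0 / omega_c

    # eta0 from the low-frequency behaviour of G'': least-squares fit of
    # G'' against the single-mode basis omega/(1 + (lam*omega)^2) over the
    # lowest decade. The basis reduces to plain omega as omega -> 0, so the
    # fitted coefficient is the zero-shear slope lim G''/omega, while the
    # Maxwell-consistent curvature keeps the estimate unbiased when the
    # lowest decade already bends away from linearity.
    w = sweep.omega
    mask = w <= w[0] * 10.0
    if mask.sum() < 2:
        mask = np.zeros_like(w, bool)
        mask[:2] = True
    basis = w[mask] / (1.0 + (lam * w[mask]) ** 2)
    eta0 = float(np.sum(basis * sweep.G_dprime[mask]) / np.sum(basis**2))
    # alternative reading: plateau of G'*(1 + 1/(lam*w)^2) at low omega
    eta0_alt = float(np.mean(
        sweep.G_prime[mask] * (1.0 + 1.0 / (lam * w[mask]) ** 2))) * lam

    target = laos_measures.e3_over_e1 \
        if isinstance(laos_measures, NonlinearMeasures) else laos_measures
    if target is None or target == 0.0:
        eps = 0.0
    else:
        def objective(eps_try: float) -> float:
            if eps_try == 0.0:
                return -target
            p = PTTParams(eta0_ref=eta0, lambda_ref=lam, epsilon=eps_try,
                          T_ref=T_ref)
            return _laos_e3_over_e1(p, gamma0_ref, omega_ref) - target

        # e3/e1 is not monotone in eps (intracycle softening at small eps
        # turning to stiffening at large), so scan a log-dense grid for the
        # first sign change and refine there — the smallest root is the
        # physically relevant weak-nonlinearity one. A measured ratio can
        # also sit at the curve's extremum (tangent case): fall back to
        # bounded minimization of the mismatch and accept a near-touch.
        grid = np.concatenate(([0.0], np.logspace(-3, 0, 25)))
        vals = {g: objective(float(g)) for g in grid}
        eps = None
        for lo_g, hi_g in zip(grid[:-1], grid[1:]):
            f_lo, f_hi = vals[lo_g], vals[hi_g]
            if f_lo == 0.0:
                eps = float(lo_g)
                break
            if f_lo * f_hi < 0:
                eps = float(brentq(objective, float(lo_g), float(hi_g),
                                   xtol=eps_tol))
                break
        if eps is None:
            from scipy.optimize import minimize_scalar
            best = min(grid, key=lambda g: abs(vals[g]))
            i = int(np.flatnonzero(grid == best)[0])
            lo_g = float(grid[max(i - 1, 0)])
            hi_g = float(grid[min(i + 1, grid.size - 1)])
            res = minimize_scalar(lambda e: abs(objective(float(e))),
                                  bounds=(lo_g, hi_g), method="bounded",
                                  options={"xatol": eps_tol})
            mismatch_tol = max(0.1 * abs(target), 1e-4)
            if abs(res.fun) > mismatch_tol:
                raise ValueError(
                    f"measured e3/e1 = {target:.4g} is outside the "
                    f"attainable range for eps in [0, 1] at gamma0 = "
                    f"{gamma0_ref} (closest approach {res.fun:.2g})")
            eps = float(res.x)

    params = PTTParams(eta0_ref=eta0, lambda_ref=lam, epsilon=eps,
                       T_ref=T_ref)
    params.notes = {"eta0_from_Gpp_slope": eta0,
                    "eta0_from_Gp_plateau_times_lambda": eta0_alt,
                    "omega_crossover": omega_c}
    return params
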