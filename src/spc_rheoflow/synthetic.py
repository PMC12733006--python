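"""Synthetic rheometer and duct-flow inputs with known ground truth.

Everything downstream of the rheometer is testable without measured data:
this module fabricates (a) LAOS stress waveforms with prescribed odd
Chebyshev content plus additive Gaussian noise, (b) power-law and
single-mode Maxwell frequency sweeps with multiplicative lognormal noise,
(c) strain sweeps with a linear-viscoelastic plateau and a smooth modulus
decay whose 5%-drop critical strain is known analytically, and (d) a
Newtonian rectangular-duct flow case with the exact series pressure drop
attached as reference.

Defaults emulate the instrument protocol of the study conditions: 8 cycles
of 256 samples per cycle for waveforms (integer-cycle windows, no spectral
leakage), frequency sweeps over 0.1-100 rad/s, amplitude sweeps over
0.1-1000% at 1 rad/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.polynomial import chebyshev as _cheb

from .laos import OscillatoryCycle
from .saos import FrequencySweep, StrainSweep, StrainUnit


@dataclass
class WaveformSpec:
    """Ground-truth recipe for one LAOS waveform.

    e_coeffs / v_coeffs map odd order -> elastic (Pa) / viscous (Pa·s)
    Chebyshev coefficient. noise_sd is the additive stress noise (Pa).
    """

    gamma0: float
    omega: float
    e_coeffs: dict[int, float]
    v_coeffs: dict[int, float]
    n_cycles: int = 8
    samples_per_cycle: int = 256
    noise_sd: float = 0.0
    seed: int = 0
    unit: StrainUnit = "fraction"

    def __post_init__(self) -> None:
        for name, coeffs in (("e_coeffs", self.e_coeffs),
                             ("v_coeffs", self.v_coeffs)):
            for order in coeffs:
                if order % 2 == 0 or order < 1:
                    raise ValueError(
                        f"{name} contains even/invalid order {order}; only "
                        "odd orders are physical for a strain-symmetric material")
        if self.gamma0 <= 0 or self.omega <= 0:
            raise ValueError("gamma0 and omega must be positive")
        if self.n_cycles < 1 or self.samples_per_cycle < 64:
            raise ValueError("need n_cycles >= 1 and samples_per_cycle >= 64")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SweepSpec:
    """Recipe for a synthetic frequency sweep.

    model_kind "power_law" uses G' = K'*w**n', G'' = K''*w**n''; supply
    (K, n) for G' and optionally (K2, n2) for G'' (defaults mirror G').
    model_kind "maxwell" uses the single-mode element
    G' = eta0*lam*w^2/(1+lam^2 w^2), G'' = eta0*w/(1+lam^2 w^2).
    noise_rel is the sigma of multiplicative lognormal noise on both moduli.
    """

    model_kind: Literal["power_law", "maxwell"]
    omega_grid: np.ndarray
    K: float | None = None
    n: float | None = None
    K2: float | None = None
    n2: float | None = None
    eta0: float | None = None
    lam: float | None = None
    noise_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.omega_grid = np.asarray(self.omega_grid, dtype=float)
        if self.omega_grid.size == 0:
            raise ValueError("omega_grid is empty")
        if np.any(self.omega_grid <= 0) or \
                np.any(np.diff(self.omega_grid) <= 0):
            raise ValueError("omega_grid must be positive and increasing")
        if self.model_kind == "power_law":
            if self.K is None or self.n is None:
                raise ValueError("power_law sweep requires K and n")
            if self.eta0 is not None or self.lam is not None:
                raise ValueError("power_law sweep takes no Maxwell fields")
        elif self.model_kind == "maxwell":
            if self.eta0 is None or self.lam is None:
                raise ValueError("maxwell sweep requires eta0 and lam")
            if self.K is not None or self.n is not None:
                raise ValueError("maxwell sweep takes no power-law fields")
        else:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")


def default_omega_grid(lo: float = 0.1, hi: float = 100.0,
                       n: int = 50) -> np.ndarray:
    """Log-spaced frequency grid mirroring the instrument sweep range."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def make_laos_waveform(spec: WaveformSpec) -> OscillatoryCycle:
    """Construct the stress waveform implied by a Chebyshev coefficient set.

    strain(t) = gamma0*sin(omega t); stress is the Chebyshev synthesis
    gamma0*sum e_n T_n(gamma/gamma0) + gamma0*omega*sum v_n T_n(rate/(gamma0*omega))
    plus N(0, noise_sd) noise. The generating coefficients are recorded in
    cycle.meta for round-trip checks.
    """
    N = spec.n_cycles * spec.samples_per_cycle
    period = 2.0 * np.pi / spec.omega
    t = np.arange(N) * (spec.n_cycles * period / N)
    x = np.sin(spec.omega * t)                 # gamma/gamma0
    y = np.cos(spec.omega * t)                 # rate/(gamma0*omega)

    max_order = max([1, *spec.e_coeffs, *spec.v_coeffs])
    e_full = np.zeros(max_order + 1)
    v_full = np.zeros(max_order + 1)
    for order, val in spec.e_coeffs.items():
        e_full[order] = val
    for order, val in spec.v_coeffs.items():
        v_full[order] = val

    stress = (spec.gamma0 * _cheb.chebval(x, e_full)
              + spec.gamma0 * spec.omega * _cheb.chebval(y, v_full))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        stress = stress + rng.normal(0.0, spec.noise_sd, size=N)

    return OscillatoryCycle(
        time=t,
        strain=spec.gamma0 * x,
        strain_rate=spec.gamma0 * spec.omega * y,
        stress=stress,
        gamma0=spec.gamma0,
        omega=spec.omega,
        unit=spec.unit,
        meta={"e_coeffs": dict(spec.e_coeffs), "v_coeffs": dict(spec.v_coeffs),
              "noise_sd": spec.noise_sd, "seed": spec.seed},
    )


def make_saos_sweep(spec: SweepSpec, temperature: float = np.nan,
                    state_label=None) -> FrequencySweep:
    """Synthesize a frequency sweep from a power-law or Maxwell model."""
    w = spec.omega_grid
    if spec.model_kind == "power_law":
        K2 = spec.K if spec.K2 is None else spec.K2
        n2 = spec.n if spec.n2 is None else spec.n2
        Gp = spec.K * w ** spec.n
        Gpp = K2 * w ** n2
    else:
        lw = spec.lam * w
        Gp = spec.eta0 * spec.lam * w**2 / (1.0 + lw**2)
        Gpp = spec.eta0 * w / (1.0 + lw**2)
    if spec.noise_rel > 0:
        rng = np.random.default_rng(spec.seed)
        Gp = Gp * rng.lognormal(0.0, spec.noise_rel, size=w.size)
        Gpp = Gpp * rng.lognormal(0.0, spec.noise_rel, size=w.size)
    return FrequencySweep(omega=w, G_prime=Gp, G_dprime=Gpp,
                          temperature=temperature, state_label=state_label)


def make_strain_sweep(plateau_G: float, decay_onset: float,
                      decay_rate: float,
                      grid: np.ndarray | None = None,
                      damping: float = 3.5,
                      unit: StrainUnit = "percent") -> StrainSweep:
    """Amplitude sweep with an LVR plateau and exponential modulus decay.

    G'(gamma) = plateau_G for gamma <= decay_onset and
    plateau_G * exp(-decay_rate * (gamma/decay_onset - 1)) above, so G' is
    continuous and non-increasing. The 5%-drop critical strain is known in
    closed form, gamma_cr = decay_onset * (1 - ln(0.95)/decay_rate), and is
    stored on the sweep as ground truth; decay_rate = 0 gives a flat sweep
    with no critical strain (true_gamma_cr = None). G'' is set to
    G'/damping, so damping < 1 yields a viscous-dominated (paste-like) sweep.
    """
    if grid is None:
        grid = np.logspace(-1, 3, 60)  # 0.1-1000%
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("strain grid must be strictly increasing")
    ratio = np.maximum(grid / decay_onset, 1.0)
    Gp = plateau_G * np.exp(-decay_rate * (ratio - 1.0))
    if decay_rate > 0:
        true_gamma_cr = decay_onset * (1.0 - np.log(0.95) / decay_rate)
    else:
        true_gamma_cr = None
    return StrainSweep(gamma=grid, G_prime=Gp, G_dprime=Gp / damping,
                       unit=unit, true_gamma_cr=true_gamma_cr)


# ---------------------------------------------------------------------------
# Newtonian rectangular-duct reference


def duct_series_pressure_drop(mu: float, Q: float, width: float,
                              height: float, length: float,
                              n_terms: int = 50) -> float:
    """Exact laminar pressure drop of a Newtonian rectangular duct.

    Uses the standard aspect-ratio series for flow in a duct of cross
    section width x height (2b x 2a with a <= b):

        Q = (4 b a^3 / (3 mu)) G [1 - (192 a)/(pi^5 b) sum_odd tanh(n pi b / 2a)/n^5]

    solved for G = -dp/dz; returns G*length in Pa.
    """
    if mu <= 0 or Q <= 0:
        raise ValueError("viscosity and flow rate must be positive")
    a = min(width, height) / 2.0
    b = max(width, height) / 2.0
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    series = np.sum(np.tanh(n * np.pi * b / (2.0 * a)) / n**5)
    phi = 1.0 - (192.0 * a / (np.pi**5 * b)) * series
    G = 3.0 * mu * Q / (4.0 * b * a**3 * phi)
    return G * length


def duct_shape_factor(width: float, height: float, n_terms: int = 50) -> float:
    """Ratio of slab-model flow to true rectangular-duct flow at equal dp/dz.

    Equals the bracketed series factor; the slab (infinite-width) pressure
    gradient divided by this factor gives the rectangular-duct gradient.
    """
    a = min(width, height) / 2.0
    b = max(width, height) / 2.0
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    series = np.sum(np.tanh(n * np.pi * b / (2.0 * a)) / n**5)
    return 1.0 - (192.0 * a / (np.pi**5 * b)) * series


def make_newtonian_die_case(viscosity: float, Q: float,
                            width: float = 0.020, height: float = 0.010,
                            length: float = 0.500):
    """Isothermal Newtonian die case with the analytic duct-series ΔP attached.

    Returns a DieCase (see die_flow) with constant properties, all wall
    zones at the inlet temperature, and ``case.reference_dp`` holding the
    exact rectangular-duct pressure drop.
    """
    from .constitutive import MaterialProperties, PowerLawTemperatureModel
    from .dieflow import DieCase

    model = PowerLawTemperatureModel(K0=viscosity, Ea_k=0.0, n0=1.0,
                                     alpha_n=0.0, T_ref=293.15)
    material = MaterialProperties(rho=1000.0, cp_poly=[4000.0],
                                  k_poly=[0.5])
    case = DieCase(
        width=width, height=height, length=length,
        zone_bounds=(0.100 * length / 0.5, 0.350 * length / 0.5),
        zone_wall_T=(20.0, 20.0, 20.0),
        inlet_T=20.0, inlet_Q=Q,
        material=material, model=model,
        include_dissipation=False,
    )
    case.reference_dp = duct_series_pressure_drop(
        viscosity, Q, width, height, length)
    return case
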