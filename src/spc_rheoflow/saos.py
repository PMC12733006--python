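"""Linear-regime (SAOS) analysis.

Power-law fits of the dynamic moduli, loss-tangent (damping factor)
evaluation, G'-G'' crossover detection, critical-strain identification from
strain sweeps, and cohesive energy density.

The frequency dependence of the moduli in the linear regime is modelled as

    G'(omega)  = K' * omega**n'
    G''(omega) = K'' * omega**n''

with consistency coefficients K (Pa·s^n) and dimensionless exponents n.
The critical strain gamma_cr is the strain at which G' has dropped 5% below
its linear-viscoelastic plateau; the cohesive energy density

    E_c = 1/2 * gamma_cr**2 * G'_cr

measures the elastic energy per unit volume stored at the edge of the
linear regime.

Unit convention for strain: every strain-carrying record is flagged
``"fraction"`` or ``"percent"``. E_c as printed in the packaged tables uses
the percent number directly (gamma_cr = 0.23 means 0.23%); this dimensional
shortcut is the table convention and is the default here, with
``percent_convention=False`` giving the SI-consistent value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

StrainUnit = Literal["fraction", "percent"]
StateLabel = Literal["paste", "molten", "weak_gel"]

_PCT = 100.0


def to_fraction(value: np.ndarray | float, unit: StrainUnit) -> np.ndarray | float:
    """Convert a strain value or array to dimensionless fraction."""
    if unit == "fraction":
        return value
    if unit == "percent":
        return np.asarray(value) / _PCT if np.ndim(value) else value / _PCT
    raise ValueError(f"unknown strain unit {unit!r}")


def to_percent(value: np.ndarray | float, unit: StrainUnit) -> np.ndarray | float:
    """Convert a strain value or array to percent."""
    if unit == "percent":
        return value
    if unit == "fraction":
        return np.asarray(value) * _PCT if np.ndim(value) else value * _PCT
    raise ValueError(f"unknown strain unit {unit!r}")


@dataclass
class FrequencySweep:
    """G'(omega), G''(omega) table from an oscillatory frequency sweep."""

    omega: np.ndarray          # rad/s, strictly increasing
    G_prime: np.ndarray        # Pa
    G_dprime: np.ndarray       # Pa
    temperature: float = np.nan  # degC, metadata only
    state_label: StateLabel | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.G_prime = np.asarray(self.G_prime, dtype=float)
        self.G_dprime = np.asarray(self.G_dprime, dtype=float)
        n = self.omega.size
        if n < 3 or self.G_prime.size != n or self.G_dprime.size != n:
            raise ValueError("sweep needs >= 3 points with equal-length arrays")
        if not np.all(np.diff(self.omega) > 0):
            raise ValueError("omega must be strictly increasing")
        if np.any(self.omega <= 0):
            raise ValueError("omega must be positive")
        if np.any(self.G_prime <= 0) or np.any(self.G_dprime <= 0):
            raise ValueError("moduli must be positive")


@dataclass
class StrainSweep:
    """G'(gamma), G''(gamma) table from an oscillatory amplitude sweep."""

    gamma: np.ndarray          # strain, unit per `unit`
    G_prime: np.ndarray        # Pa
    G_dprime: np.ndarray       # Pa
    unit: StrainUnit = "percent"
    temperature: float = np.nan
    state_label: StateLabel | None = None
    # generator-attached ground truth (percent/fraction per `unit`), if any
    true_gamma_cr: float | None = None

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.G_prime = np.asarray(self.G_prime, dtype=float)
        self.G_dprime = np.asarray(self.G_dprime, dtype=float)
        n = self.gamma.size
        if n < 3 or self.G_prime.size != n or self.G_dprime.size != n:
            raise ValueError("sweep needs >= 3 points with equal-length arrays")
        if not np.all(np.diff(self.gamma) > 0):
            raise ValueError("gamma must be strictly increasing")


@dataclass
class PowerLawFit:
    """K * omega**n fit of one dynamic modulus."""

    K: float                   # Pa·s^n
    n: float                   # dimensionless
    r_squared: float
    target: Literal["G_prime", "G_dprime"]

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")

    def __call__(self, omega: np.ndarray | float) -> np.ndarray | float:
        return self.K * np.asarray(omega, dtype=float) ** self.n


@dataclass
class CriticalStrainResult:
    """Critical strain, modulus there, plateau and cohesive energy density."""

    gamma_cr: float            # in `unit`
    G_cr: float                # Pa
    cohesive_energy: float     # J/m^3 (table percent convention by default)
    plateau_G: float           # Pa
    unit: StrainUnit = "percent"


def fit_power_law(
    sweep: FrequencySweep,
    target: Literal["G_prime", "G_dprime"] = "G_prime",
) -> PowerLawFit:
    """Least-squares power-law fit of log(modulus) on log(omega).

    Returns K (exponentiated intercept, Pa·s^n) and n (slope).
    """
    modulus = getattr(sweep, target)
    logw = np.log(sweep.omega)
    logg = np.log(modulus)
    slope, intercept = np.polyfit(logw, logg, 1)
    pred = slope * logw + intercept
    ss_res = float(np.sum((logg - pred) ** 2))
    ss_tot = float(np.sum((logg - logg.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return PowerLawFit(K=float(np.exp(intercept)), n=float(slope),
                       r_squared=r2, target=target)


def damping_factor(fit_prime: PowerLawFit, fit_dprime: PowerLawFit,
                   omega: float) -> float:
    """Loss tangent G''/G' at `omega` from the two power-law fits."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    return float(fit_dprime(omega) / fit_prime(omega))


def find_crossover(sweep: FrequencySweep | StrainSweep) -> float | None:
    """First G' = G'' crossover, by log-log linear interpolation.

    For a FrequencySweep the returned abscissa is omega (rad/s); for a
    StrainSweep it is strain in the sweep's own unit. Returns None when
    G' - G'' never changes sign over the sweep (the "nil" case of
    viscous-dominated pastes).
    """
    x = sweep.omega if isinstance(sweep, FrequencySweep) else sweep.gamma
    if np.any(x <= 0):
        raise ValueError("crossover interpolation requires positive abscissa")
    d = np.log(sweep.G_prime) - np.log(sweep.G_dprime)
    exact = np.flatnonzero(d == 0.0)
    if exact.size:
        return float(x[exact[0]])
    sign_change = np.flatnonzero(d[:-1] * d[1:] < 0.0)
    if not sign_change.size:
        return None
    i = int(sign_change[0])
    lx0, lx1 = np.log(x[i]), np.log(x[i + 1])
    frac = d[i] / (d[i] - d[i + 1])
    return float(np.exp(lx0 + frac * (lx1 - lx0)))


def _plateau(sweep: StrainSweep, rel_tol: float = 0.01,
             min_points: int = 3) -> tuple[float, int]:
    """Initial-window plateau estimate of G'.

    The plateau window is the longest initial run over which G' stays
    within `rel_tol` of its starting value; the plateau is the median of
    G' over that window (robust both to a smooth decay tail entering the
    window and to isolated noisy points — a point-to-point criterion would
    let a slow decay creep arbitrarily far into the window). Requires at
    least `min_points` points.
    """
    g = sweep.G_prime
    within = np.abs(g - g[0]) <= rel_tol * g[0]
    end = int(np.argmin(within)) if not within.all() else g.size
    if end < min_points:
        raise ValueError(
            f"no linear-viscoelastic plateau: only {end} initial points stay "
            f"within {rel_tol:.0%} of the first (need >= {min_points})")
    return float(np.median(g[:end])), end


def find_critical_strain(sweep: StrainSweep,
                         drop_fraction: float = 0.05) -> CriticalStrainResult:
    """Strain at which G' drops `drop_fraction` below its LVR plateau.

    The plateau is the median of G' over the initial window where G'
    stays within 1% of its first point. gamma_cr is found by interpolation
    (linear in log-strain vs linear G') at G' = (1 - drop_fraction)*plateau,
    and G_cr is G' interpolated at gamma_cr. The cohesive energy density is
    evaluated in the table percent convention.
    """
    plateau, _ = _plateau(sweep)
    threshold = (1.0 - drop_fraction) * plateau
    g = sweep.G_prime
    below = np.flatnonzero(g < threshold)
    if not below.size:
        raise ValueError("threshold never crossed: G' stays within "
                         f"{drop_fraction:.0%} of the plateau")
    j = int(below[0])
    if j == 0:
        raise ValueError("G' starts below threshold; no plateau to drop from")
    lg0, lg1 = np.log(sweep.gamma[j - 1]), np.log(sweep.gamma[j])
    frac = (g[j - 1] - threshold) / (g[j - 1] - g[j])
    gamma_cr = float(np.exp(lg0 + frac * (lg1 - lg0)))
    G_cr = threshold  # by the interpolation convention G'(gamma_cr) = threshold
    gamma_pct = float(to_percent(gamma_cr, sweep.unit))
    return CriticalStrainResult(
        gamma_cr=gamma_cr,
        G_cr=float(G_cr),
        cohesive_energy=cohesive_energy_density(gamma_pct, float(G_cr)),
        plateau_G=plateau,
        unit=sweep.unit,
    )


def cohesive_energy_density(gamma_cr: float, G_cr: float,
                            percent_convention: bool = True) -> float:
    """Cohesive energy density E_c = 1/2 * gamma_cr^2 * G'_cr.

    With ``percent_convention=True`` (default) gamma_cr is the percent
    number exactly as printed in the characterization tables (0.23 means
    0.23%); this reproduces the tabulated E_c values. Set it to False to
    pass gamma_cr as a dimensionless fraction and obtain the SI-consistent
    value (a factor 1e4 smaller for the same physical strain).
    """
    if gamma_cr < 0 or G_cr < 0:
        raise ValueError("gamma_cr and G_cr must be non-negative")
    return 0.5 * gamma_cr**2 * G_cr
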