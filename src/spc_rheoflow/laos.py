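"""Nonlinear-regime (LAOS) analysis.

Decomposition of strain-controlled oscillatory stress waveforms into odd
Fourier harmonics and the equivalent Chebyshev representation, plus the
derived intracycle measures and Lissajous-Bowditch loops.

With strain gamma(t) = gamma0*sin(omega*t), the periodic stress of an
odd-symmetric viscoelastic material decomposes as

    sigma(t) = gamma0 * sum_n_odd [ G'_n sin(n omega t) + G''_n cos(n omega t) ]

and equivalently, in terms of Chebyshev polynomials of the first kind T_n
of normalized strain x = gamma/gamma0 and normalized rate
y = gamma_dot/(gamma0*omega),

    sigma = gamma0 * sum_n_odd e_n T_n(x)  +  gamma0*omega * sum_n_odd v_n T_n(y)

with e_n = G'_n * (-1)^((n-1)/2) and v_n = G''_n / omega. The third-order
ratios e3/e1 and v3/v1 quantify intracycle strain-stiffening (e3/e1 > 0) or
softening, and shear-thickening (v3/v1 > 0) or thinning. The minimum-strain
and large-strain moduli and their viscous analogues,

    G'_M = e1 - 3 e3 + 5 e5 - 7 e7 + ...   (tangent modulus at gamma = 0)
    G'_L = e1 + e3 + e5 + e7 + ...         (secant modulus at gamma = +/-gamma0)
    eta'_M = v1 - 3 v3 + 5 v5 - ...        eta'_L = v1 + v3 + v5 + ...

give the stiffening ratio S = (G'_L - G'_M)/G'_L and thickening ratio
T = (eta'_L - eta'_M)/eta'_L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import chebyshev as _cheb

from .saos import StateLabel, StrainUnit

__all__ = [
    "OscillatoryCycle", "HarmonicSpectrum", "ChebyshevSet",
    "NonlinearMeasures", "LissajousLoop",
    "decompose", "chebyshev_from_fourier", "nonlinear_measures", "lissajous",
]


@dataclass
class OscillatoryCycle:
    """Sampled strain/stress waveform over an integer number of cycles."""

    time: np.ndarray           # s, uniform
    strain: np.ndarray         # in `unit`
    strain_rate: np.ndarray    # 1/s
    stress: np.ndarray         # Pa
    gamma0: float              # amplitude, in `unit`
    omega: float               # rad/s
    unit: StrainUnit = "fraction"
    temperature: float = np.nan
    state_label: StateLabel | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("time", "strain", "strain_rate", "stress"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        if any(getattr(self, a).size != n
               for a in ("strain", "strain_rate", "stress")):
            raise ValueError("channel arrays must share one length")
        dt = np.diff(self.time)
        if n < 8 or not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise ValueError("sampling must be uniform (rtol 1e-6)")
        peak = np.max(np.abs(self.strain))
        if not np.isclose(peak, self.gamma0, rtol=0.01):
            raise ValueError(
                f"max|strain| = {peak:.4g} deviates > 1% from gamma0 = "
                f"{self.gamma0:.4g}")

    @property
    def n_cycles(self) -> int:
        dt = self.time[1] - self.time[0]
        span = self.time[-1] - self.time[0] + dt  # endpoint-exclusive window
        cycles = span * self.omega / (2.0 * np.pi)
        rounded = round(cycles)
        if rounded < 1 or abs(cycles - rounded) > 1e-6 * max(1.0, rounded):
            raise ValueError(f"window covers {cycles:.8f} cycles; an integer "
                             "number of full cycles is required")
        return int(rounded)


@dataclass
class HarmonicSpectrum:
    """Odd-harmonic Fourier moduli of one decomposed waveform."""

    orders: np.ndarray         # odd, ascending
    G_prime_n: np.ndarray      # Pa, in-phase with strain
    G_dprime_n: np.ndarray     # Pa, in-phase with strain rate
    residual_rms: float        # Pa, RMS of stress not captured by retained odd harmonics
    even_rms: float = 0.0      # Pa, RMS power at even harmonics (data-quality diagnostic)
    gamma0: float = np.nan
    omega: float = np.nan

    def __post_init__(self) -> None:
        self.orders = np.asarray(self.orders, dtype=int)
        self.G_prime_n = np.asarray(self.G_prime_n, dtype=float)
        self.G_dprime_n = np.asarray(self.G_dprime_n, dtype=float)
        if np.any(self.orders % 2 == 0):
            raise ValueError("orders must be odd")
        if np.any(np.diff(self.orders) <= 0):
            raise ValueError("orders must be ascending")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")


@dataclass
class ChebyshevSet:
    """Elastic (e_n, Pa) and viscous (v_n, Pa·s) Chebyshev coefficients."""

    orders: np.ndarray
    e: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.orders = np.asarray(self.orders, dtype=int)
        self.e = np.asarray(self.e, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (np.all(np.isfinite(self.e)) and np.all(np.isfinite(self.v))):
            raise ValueError("coefficients must be finite")

    def coeff(self, which: str, order: int) -> float:
        arr = self.e if which == "e" else self.v
        idx = np.flatnonzero(self.orders == order)
        return float(arr[idx[0]]) if idx.size else 0.0

    @property
    def e3_over_e1(self) -> float:
        return self.coeff("e", 3) / self.coeff("e", 1)

    @property
    def v3_over_v1(self) -> float:
        return self.coeff("v", 3) / self.coeff("v", 1)


@dataclass
class NonlinearMeasures:
    """Intracycle moduli/viscosities and the stiffening/thickening ratios."""

    G_prime_M: float           # Pa, tangent modulus at zero strain
    G_prime_L: float           # Pa, secant modulus at peak strain
    eta_prime_M: float         # Pa·s
    eta_prime_L: float         # Pa·s
    S: float                   # stiffening ratio; NaN when G'_L == 0
    T_ratio: float             # thickening ratio; NaN when eta'_L == 0
    e3_over_e1: float
    v3_over_v1: float


@dataclass
class LissajousLoop:
    """Normalized elastic and viscous Lissajous-Bowditch curves (one cycle)."""

    normalized_strain: np.ndarray
    normalized_rate: np.ndarray
    normalized_stress: np.ndarray
    enclosed_area_elastic: float   # Pa, shoelace area of stress vs strain
    enclosed_area_viscous: float   # Pa, shoelace area of stress vs rate/omega


def _fourier_harmonics(cycle: OscillatoryCycle, max_order: int):
    """Raw FFT harmonics of strain and stress over the integer-cycle window.

    Returns (phi, gamma0_fit, a, b, even_power, total_power) where
    sigma(t) ~= sum_n a_n sin(n*theta') + b_n cos(n*theta') in the
    strain-referenced phase theta' = omega*t + phi.
    """
    n_cycles = cycle.n_cycles
    N = cycle.time.size
    X = np.fft.rfft(cycle.stress)
    S = np.fft.rfft(cycle.strain)

    # strain phase and amplitude from the fundamental
    k1 = n_cycles
    a1s = -2.0 * S[k1].imag / N
    b1s = 2.0 * S[k1].real / N
    phi = float(np.arctan2(b1s, a1s))
    gamma0_fit = float(np.hypot(a1s, b1s))

    max_harm = (N // 2) // n_cycles
    orders = np.arange(1, min(max_order, max_harm) + 1)
    a = np.zeros(orders.size)
    b = np.zeros(orders.size)
    for i, n in enumerate(orders):
        k = n * n_cycles
        an = -2.0 * X[k].imag / N
        bn = 2.0 * X[k].real / N
        # rotate into the strain-referenced phase
        c, s = np.cos(n * phi), np.sin(n * phi)
        a[i] = an * c + bn * s
        b[i] = bn * c - an * s
    even = orders[orders % 2 == 0]
    even_power = 0.5 * float(np.sum(a[even - 1] ** 2 + b[even - 1] ** 2))
    return phi, gamma0_fit, orders, a, b, even_power


def decompose(cycle: OscillatoryCycle, max_order: int = 9,
              zero_tol: float = 1e-6) -> HarmonicSpectrum:
    """Odd-harmonic Fourier decomposition of a stress waveform.

    The strain channel is fit to gamma0*sin(omega*t + phi) and every stress
    harmonic is rotated by -n*phi, so the result is independent of where in
    the cycle sampling started. Harmonics whose magnitude falls below
    ``zero_tol`` times the first-harmonic magnitude are reported as zero
    (noise-floor truncation). Even-harmonic power is excluded from the
    moduli and reported via ``even_rms`` as a data-quality diagnostic.
    """
    phi, gamma0_fit, orders, a, b, even_power = _fourier_harmonics(
        cycle, max_order)
    g0 = gamma0_fit
    odd = orders[orders % 2 == 1]
    Gp = a[odd - 1] / g0
    Gpp = b[odd - 1] / g0

    mag = np.hypot(Gp, Gpp)
    if mag[0] > 0:
        small = mag < zero_tol * mag[0]
        Gp = np.where(small, 0.0, Gp)
        Gpp = np.where(small, 0.0, Gpp)

    # residual: stress minus reconstruction from retained odd harmonics
    theta = cycle.omega * cycle.time + phi
    recon = np.zeros_like(cycle.stress)
    for n, gp, gpp in zip(odd, Gp, Gpp):
        recon += g0 * (gp * np.sin(n * theta) + gpp * np.cos(n * theta))
    residual_rms = float(np.sqrt(np.mean((cycle.stress - recon) ** 2)))
    even_rms = float(np.sqrt(even_power))

    return HarmonicSpectrum(orders=odd, G_prime_n=Gp, G_dprime_n=Gpp,
                            residual_rms=residual_rms, even_rms=even_rms,
                            gamma0=g0, omega=cycle.omega)


def chebyshev_from_fourier(spectrum: HarmonicSpectrum,
                           omega: float | None = None) -> ChebyshevSet:
    """Convert odd Fourier moduli to Chebyshev coefficients.

    e_n = G'_n * (-1)^((n-1)/2)  (from T_n(sin t) = (-1)^((n-1)/2) sin(n t))
    v_n = G''_n / omega          (from T_n(cos t) = cos(n t))
    """
    w = spectrum.omega if omega is None else omega
    if not np.isfinite(w) or w <= 0:
        raise ValueError("omega must be positive")
    n = spectrum.orders
    if np.any(n % 2 == 0):
        raise ValueError("only odd orders convert to Chebyshev coefficients")
    sign = (-1.0) ** ((n - 1) // 2)
    return ChebyshevSet(orders=n, e=sign * spectrum.G_prime_n,
                        v=spectrum.G_dprime_n / w)


def nonlinear_measures(cheb: ChebyshevSet) -> NonlinearMeasures:
    """Intracycle measures G'_M, G'_L, eta'_M, eta'_L, S and T.

    Evaluated from the retained finite coefficient set:
    the M (minimum-strain / tangent) sums weight order n by
    n*(-1)^((n-1)/2), the L (large-strain / secant) sums are plain sums.
    Ratios are NaN (not an error) when their denominator vanishes.
    """
    n = cheb.orders.astype(float)
    sign = (-1.0) ** ((cheb.orders - 1) // 2)
    GpM = float(np.sum(sign * n * cheb.e))
    GpL = float(np.sum(cheb.e))
    etaM = float(np.sum(sign * n * cheb.v))
    etaL = float(np.sum(cheb.v))
    S = (GpL - GpM) / GpL if GpL != 0.0 else float("nan")
    T = (etaL - etaM) / etaL if etaL != 0.0 else float("nan")
    e1 = cheb.coeff("e", 1)
    v1 = cheb.coeff("v", 1)
    return NonlinearMeasures(
        G_prime_M=GpM, G_prime_L=GpL, eta_prime_M=etaM, eta_prime_L=etaL,
        S=S, T_ratio=T,
        e3_over_e1=cheb.coeff("e", 3) / e1 if e1 else float("nan"),
        v3_over_v1=cheb.coeff("v", 3) / v1 if v1 else float("nan"),
    )


def slope_measures(cheb: ChebyshevSet, npts: int = 20001
                   ) -> tuple[float, float, float, float]:
    """Slope/secant-based G'_M, G'_L, eta'_M, eta'_L from the reconstructed
    decomposed loop (numerical derivative of the elastic stress contribution
    at gamma=0 and secant at gamma=+/-gamma0; viscous analogue on the rate
    projection). Used as a cross-check of the series forms; a discrepancy
    beyond ~1% indicates an under-resolved harmonic set.
    """
    x = np.linspace(-1.0, 1.0, npts)
    e_full = np.zeros(int(cheb.orders.max()) + 1)
    v_full = np.zeros_like(e_full)
    e_full[cheb.orders] = cheb.e
    v_full[cheb.orders] = cheb.v
    sig_e = _cheb.chebval(x, e_full)     # elastic stress / gamma0
    sig_v = _cheb.chebval(x, v_full)     # viscous stress / (gamma0*omega)
    h = x[1] - x[0]
    mid = npts // 2
    GpM = (sig_e[mid + 1] - sig_e[mid - 1]) / (2 * h)
    GpL = sig_e[-1] / 1.0
    etaM = (sig_v[mid + 1] - sig_v[mid - 1]) / (2 * h)
    etaL = sig_v[-1] / 1.0
    return float(GpM), float(GpL), float(etaM), float(etaL)


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    """Signed enclosed area of a closed polygon (shoelace rule)."""
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def lissajous(cycle: OscillatoryCycle) -> LissajousLoop:
    """Normalized Lissajous-Bowditch loops over the final cycle.

    Strain is normalized by gamma0, strain rate by gamma0*omega, stress by
    its own peak. ``enclosed_area_elastic`` is the shoelace area of the
    *unnormalized* stress-strain loop (equal to the energy dissipated per
    cycle per unit volume, pi*gamma0^2*G''_1 for a decomposable material);
    ``enclosed_area_viscous`` is the area of stress vs strain-rate/omega
    (the recoverable-energy analogue).
    """
    n_cycles = cycle.n_cycles
    per = cycle.time.size // n_cycles
    sl = slice(cycle.time.size - per, cycle.time.size)
    gam = cycle.strain[sl]
    rate = cycle.strain_rate[sl]
    sig = cycle.stress[sl]
    g0 = cycle.gamma0
    peak = np.max(np.abs(sig))
    area_e = abs(_shoelace(gam, sig))
    area_v = abs(_shoelace(rate / cycle.omega, sig))
    return LissajousLoop(
        normalized_strain=gam / g0,
        normalized_rate=rate / (g0 * cycle.omega),
        normalized_stress=sig / peak if peak > 0 else sig,
        enclosed_area_elastic=area_e,
        enclosed_area_viscous=area_v,
    )
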