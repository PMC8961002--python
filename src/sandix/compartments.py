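"""Elementary non-exchanging compartment signals.

Isotropic Gaussian decay, the powder-averaged stick, and the apparent
diffusivity of water restricted in a sphere in the Gaussian phase
approximation (GPA), both in the narrow-pulse limit and for finite
gradient pulses (Murday-Cotts/Balinov form).  Sphere expressions are
built on the eigenvalue spectrum of the Neumann problem in a ball,
whose dimensionless roots alpha_m solve J_{3/2}(alpha) =
alpha * J_{5/2}(alpha).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, jv

__all__ = [
    "SphereSpectrum",
    "sphere_spectrum",
    "gaussian_signal",
    "stick_powder_signal",
    "sphere_diffusivity_narrow_pulse",
    "sphere_diffusivity_gpa",
]


@dataclass(frozen=True)
class SphereSpectrum:
    """First M dimensionless sphere eigenvalue roots alpha_m."""

    roots: np.ndarray
    M: int

    def __post_init__(self) -> None:
        r = np.asarray(self.roots, dtype=float)
        if len(r) != self.M or np.any(np.diff(r) <= 0) or r[0] <= 0:
            raise ValueError("roots must be M strictly increasing positive values")


def _root_equation(a: float) -> float:
    return jv(1.5, a) - a * jv(2.5, a)


@lru_cache(maxsize=8)
def sphere_spectrum(M: int = 50) -> SphereSpectrum:
    """Compute the first M roots of J_{3/2}(a) = a J_{5/2}(a) by bracketed
    root finding (brentq, 1e-12 tolerance); results are cached.

    The roots interlace pi-spaced intervals beyond the first; brackets are
    located by a fine sign scan.
    """
    roots: list[float] = []
    # first root sits near 2.08; spacing approaches pi
    grid = np.linspace(0.5, (M + 3) * np.pi, 60 * (M + 3))
    vals = _root_equation(grid)
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(_root_equation, grid[i], grid[i + 1],
                                xtol=1e-12, rtol=8.9e-16))
        if len(roots) >= M:
            break
    if len(roots) < M:
        raise RuntimeError("sphere eigenvalue root finding did not converge")
    return SphereSpectrum(roots=np.array(roots[:M]), M=M)


def gaussian_signal(b, D):
    """Isotropic Gaussian compartment: exp(-b D)."""
    b = np.asarray(b, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(b < 0) or np.any(D < 0):
        raise ValueError("b and D must be nonnegative")
    return np.exp(-b * D)


def stick_powder_signal(b, Dn):
    """Powder-averaged stick signal sqrt(pi/(4 b Dn)) erf(sqrt(b Dn)).

    Equals the orientation integral over eps in [0, 1] of
    exp(-b Dn eps^2).  The b*Dn -> 0 limit is 1 and is evaluated by a
    Taylor series below 1e-6 to avoid 0/0; at large b*Dn the signal
    approaches the b^(-1/2) power-law asymptote sqrt(pi/(4 b Dn)).
    """
    x = np.asarray(b, dtype=float) * np.asarray(Dn, dtype=float)
    if np.any(x < 0):
        raise ValueError("b*Dn must be nonnegative")
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    small = x < 1e-6
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs * xs / 10.0
    xl = x[~small]
    out[~small] = np.sqrt(np.pi / (4.0 * xl)) * erf(np.sqrt(xl))
    return float(out[0]) if scalar else out


def sphere_diffusivity_narrow_pulse(Delta: float, R: float, D0: float,
                                    spectrum: SphereSpectrum | None = None):
    """Narrow-pulse apparent diffusivity of a sphere of radius R.

    Ds = (2 R^2 / Delta) sum_m alpha_m^-2/(alpha_m^2 - 2)
         (1 - exp(-alpha_m^2 D0 Delta / R^2))

    Bounded by the free diffusivity D0 and approaching R^2/(5 Delta) in
    the long-time limit (the displacement variance of two independent
    uniform points in a ball).  The slowly converging constant part of
    the sum is taken exactly via sum_m 1/(alpha_m^2 (alpha_m^2 - 2)) =
    1/10, leaving only exponentially suppressed terms to truncate.
    """
    if R <= 0 or Delta <= 0:
        raise ValueError("R and Delta must be positive")
    if spectrum is None:
        spectrum = sphere_spectrum()
    al2 = spectrum.roots**2
    tail = np.sum(np.exp(-al2 * D0 * Delta / R**2) / (al2 * (al2 - 2.0)))
    return float(2.0 * R**2 / Delta * (0.1 - tail))


def sphere_diffusivity_gpa(Delta: float, delta: float, R: float, D0: float,
                           spectrum: SphereSpectrum | None = None):
    """Finite-pulse GPA apparent diffusivity of a sphere.

    The Gaussian-phase sum over sphere eigenmodes (Murday-Cotts/Balinov)
    expressed as an apparent diffusivity such that the soma signal is
    exp(-b * Ds(Delta, delta)); reduces to the narrow-pulse expression as
    delta -> 0 and vanishes as R -> 0.
    """
    if R <= 0 or Delta <= 0:
        raise ValueError("R and Delta must be positive")
    if delta <= 0 or delta > Delta:
        raise ValueError("need 0 < delta <= Delta")
    if spectrum is None:
        spectrum = sphere_spectrum()
    al2 = spectrum.roots**2
    lam = al2 * D0 / R**2  # eigenvalue rates, 1/ms
    num = (2.0
           + np.exp(-lam * (Delta - delta))
           - 2.0 * np.exp(-lam * delta)
           - 2.0 * np.exp(-lam * Delta)
           + np.exp(-lam * (Delta + delta)))
    bracket = 2.0 * delta / lam - num / lam**2
    coeff = R**2 / (al2 * (al2 - 2.0))
    minus_lnS_over_g2 = 2.0 * np.sum(coeff * bracket)  # times gamma^2 g^2
    # b = gamma^2 g^2 delta^2 (Delta - delta/3)
    return float(minus_lnS_over_g2 / (delta**2 * (Delta - delta / 3.0)))
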