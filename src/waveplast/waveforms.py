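"""Closed-form traveling-wave profiles and driver-field constructors.

The neural activity field obeys a Schrödinger-type evolution whose
traveling-wave reduction (co-moving coordinate ``xi = x - c*t``) is the
second-order profile equation

    Phi'' = alpha * Phi + beta * Phi**2,

with first integral

    (Phi')**2 = alpha * Phi**2 + (2/3) * beta * Phi**3 + C1.

For ``alpha > 0`` and ``beta < 0`` the cubic on the right has three real
roots ``Phi1 <= Phi2 <= Phi3`` for ``C1`` in ``(-alpha**3/(3*beta**2), 0]``,
and the bounded solutions oscillate on ``[Phi2, Phi3]`` as cnoidal waves

    Phi(xi) = Phi2 + (Phi3 - Phi2) * cn(nu*xi | m)**2,
    m  = (Phi3 - Phi2) / (Phi3 - Phi1),
    nu = sqrt(-beta * (Phi3 - Phi1) / 6).

At ``C1 = 0`` the lower roots merge (``Phi1 = Phi2 = 0``, ``m -> 1``) and
the profile degenerates into the localized soliton

    Phi(xi) = A * sech(sqrt(alpha)*xi / 2)**2,   A = -3*alpha/(2*beta).

This module also builds the composite drivers used in the simulations:
superpositions of traveling waves, frozen Gaussian background noise,
theta-modulated gamma carriers, and 2D plane-wave interference sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import ellipj, ellipk

from .fields import ComplexField, GridError, SpatialGrid

__all__ = [
    "TravelingWaveParams",
    "CnoidalParams",
    "ThetaGammaParams",
    "PlaneWaveSpec2D",
    "NoiseParams",
    "BranchError",
    "soliton_profile",
    "soliton_amplitude",
    "cnoidal_profile",
    "profile_residuals",
    "traveling_field",
    "superpose",
    "add_gaussian_noise",
    "theta_gamma_field",
    "interference_field_2d",
]


class BranchError(ValueError):
    """Parameters outside the region where the requested solution exists."""


@dataclass(frozen=True)
class TravelingWaveParams:
    """Coefficients of the traveling-wave profile equation.

    ``alpha_wave`` is the linear amplification coefficient, ``beta_wave``
    the quadratic (compressive) one, ``c`` the co-moving frame speed and
    ``c1`` the first-integral constant (0 for the localized soliton).
    """

    alpha_wave: float
    beta_wave: float
    c: float = 1.0
    c1: float = 0.0


def soliton_amplitude(p: TravelingWaveParams) -> float:
    """Peak height of the sech^2 soliton, ``-3*alpha/(2*beta)``."""
    return -3.0 * p.alpha_wave / (2.0 * p.beta_wave)


def _require_soliton_branch(p: TravelingWaveParams) -> None:
    if not (p.alpha_wave > 0 and p.beta_wave < 0):
        raise BranchError(
            "soliton branch requires alpha_wave > 0 and beta_wave < 0 "
            f"(got alpha={p.alpha_wave}, beta={p.beta_wave})"
        )
    if p.c1 != 0:
        raise BranchError("soliton branch requires c1 = 0 (decay at infinity)")


def soliton_profile(xi, p: TravelingWaveParams) -> np.ndarray:
    """Localized sech^2 wave packet solving the profile equation.

    ``Phi(xi) = A / cosh(sqrt(alpha)*xi/2)**2`` with ``A = -3a/(2b)``.
    """
    _require_soliton_branch(p)
    xi = np.asarray(xi, dtype=float)
    arg = 0.5 * np.sqrt(p.alpha_wave) * xi
    return soliton_amplitude(p) / np.cosh(arg) ** 2


def _cubic_roots(alpha: float, beta: float, c1: float) -> np.ndarray:
    # roots of (2/3) b x^3 + a x^2 + c1, ascending
    r = np.roots([2.0 * beta / 3.0, alpha, 0.0, c1])
    if np.max(np.abs(r.imag)) > 1e-9 * max(1.0, np.max(np.abs(r))):
        raise BranchError(
            "first-integral cubic has complex roots; no bounded cnoidal branch "
            f"for alpha={alpha}, beta={beta}, c1={c1}"
        )
    return np.sort(r.real)


@dataclass(frozen=True)
class CnoidalParams:
    """Cnoidal-branch parameters: coefficients plus the cubic's real roots.

    Construct via :meth:`from_c1` or :meth:`from_modulus` so that the
    roots, the elliptic parameter ``m`` and ``c1`` stay mutually
    consistent (which makes the first-integral residual vanish by
    construction).
    """

    alpha_wave: float
    beta_wave: float
    c: float
    c1: float
    roots: tuple[float, float, float]
    m: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.m < 1.0):
            raise BranchError(f"elliptic parameter m={self.m} outside [0, 1)")
        r = np.asarray(self.roots)
        resid = np.abs(
            2.0 * self.beta_wave / 3.0 * r**3 + self.alpha_wave * r**2 + self.c1
        )
        scale = max(1.0, abs(self.c1), float(np.max(np.abs(r))) ** 3)
        if np.max(resid) > 1e-9 * scale:
            raise BranchError("roots inconsistent with (alpha, beta, c1)")

    @classmethod
    def from_c1(
        cls, alpha_wave: float, beta_wave: float, c1: float, c: float = 1.0
    ) -> "CnoidalParams":
        if not (alpha_wave > 0 and beta_wave < 0):
            raise BranchError("cnoidal branch implemented for alpha > 0, beta < 0")
        r1, r2, r3 = _cubic_roots(alpha_wave, beta_wave, c1)
        if r3 - r1 <= 0:
            raise BranchError("degenerate roots; no oscillation interval")
        m = (r3 - r2) / (r3 - r1)
        if m >= 1.0:
            m = np.nextafter(1.0, 0.0)
        return cls(alpha_wave, beta_wave, c, c1, (r1, r2, r3), float(m))

    @classmethod
    def from_modulus(
        cls, alpha_wave: float, beta_wave: float, m: float, c: float = 1.0
    ) -> "CnoidalParams":
        """Solve for the ``c1`` whose root triple has elliptic parameter ``m``."""
        if not (alpha_wave > 0 and beta_wave < 0):
            raise BranchError("cnoidal branch implemented for alpha > 0, beta < 0")
        if not (0.0 < m < 1.0):
            raise BranchError("m must lie strictly in (0, 1)")
        s = -3.0 * alpha_wave / (2.0 * beta_wave)  # sum of roots, > 0

        # roots written as (r3 - L, r3 - m*L, r3); enforce e2 = 0
        def e2(L: float) -> float:
            r3 = (s + (1.0 + m) * L) / 3.0
            r1, r2 = r3 - L, r3 - m * L
            return r1 * r2 + r1 * r3 + r2 * r3

        hi = s
        while e2(hi) > 0:
            hi *= 2.0
            if hi > 1e8 * s:  # pragma: no cover - defensive
                raise BranchError("failed to bracket root spread")
        L = brentq(e2, 1e-14 * s, hi, xtol=1e-15, rtol=4 * np.finfo(float).eps)
        r3 = (s + (1.0 + m) * L) / 3.0
        roots = (r3 - L, r3 - m * L, r3)
        c1 = -(2.0 * beta_wave / 3.0) * roots[0] * roots[1] * roots[2]
        return cls(alpha_wave, beta_wave, c, float(c1), roots, float(m))

    @property
    def nu(self) -> float:
        """Spatial scale factor of the cn argument."""
        r1, _, r3 = self.roots
        return float(np.sqrt(-self.beta_wave * (r3 - r1) / 6.0))

    @property
    def wavelength(self) -> float:
        """Spatial period ``2*K(m)/nu`` from the complete elliptic integral."""
        return float(2.0 * ellipk(self.m) / self.nu)


def cnoidal_profile(xi, p: CnoidalParams) -> np.ndarray:
    """Periodic cnoidal profile ``Phi2 + (Phi3 - Phi2) * cn(nu*xi|m)^2``."""
    xi = np.asarray(xi, dtype=float)
    _, r2, r3 = p.roots
    _, cn, _, _ = ellipj(p.nu * xi, p.m)
    return r2 + (r3 - r2) * cn**2


def profile_residuals(
    profile, xi, p: TravelingWaveParams
) -> tuple[float, float]:
    """Max-norm residuals of the profile ODE and of its first integral.

    ``ode_residual  = max |Phi'' - a*Phi - b*Phi^2|`` (central differences,
    interior nodes); ``integral_residual = max |(Phi')^2 - a*Phi^2 -
    (2/3)*b*Phi^3 - c1|``. Requires a uniformly spaced ``xi`` with at
    least 32 samples.
    """
    phi = np.asarray(profile, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if phi.shape != xi.shape or phi.ndim != 1 or phi.size < 32:
        raise ValueError("profile and xi must be matching 1D arrays, >= 32 points")
    h = np.diff(xi)
    if h.min() <= 0 or (h.max() - h.min()) > 1e-9 * h.mean():
        raise ValueError("xi must be uniformly spaced and increasing")
    dx = h.mean()
    d1 = np.gradient(phi, dx, edge_order=2)
    d2 = (phi[2:] - 2.0 * phi[1:-1] + phi[:-2]) / dx**2
    a, b = p.alpha_wave, p.beta_wave
    ode = np.max(np.abs(d2 - a * phi[1:-1] - b * phi[1:-1] ** 2))
    integral = np.max(
        np.abs(d1**2 - a * phi**2 - (2.0 / 3.0) * b * phi**3 - p.c1)
    )
    return float(ode), float(integral)


def traveling_field(
    profile_fn: Callable[[np.ndarray], np.ndarray],
    grid: SpatialGrid,
    t: float,
    c: float,
) -> ComplexField:
    """Evaluate ``psi(x, t) = Phi(x - c*t)`` on a 1D grid.

    On periodic grids the co-moving argument is wrapped back into the
    domain, so a wave leaving one side re-enters on the other.
    """
    if grid.dims != 1:
        raise GridError("traveling_field is 1D; use interference_field_2d in 2D")
    x = grid.x
    xi = x - c * t
    if grid.boundary == "periodic":
        lo, hi = grid.extents[0]
        xi = (xi - lo) % (hi - lo) + lo
    return ComplexField(grid, profile_fn(xi).astype(complex))


def superpose(fields: Sequence[ComplexField]) -> ComplexField:
    """Pointwise sum of fields sharing one grid (``psi = psi1 + psi2 + ...``)."""
    if len(fields) == 0:
        raise ValueError("superpose needs at least one field")
    g = fields[0].grid
    for f in fields[1:]:
        if f.grid != g:
            raise GridError("superpose requires identical grids")
    return ComplexField(g, np.sum([f.values for f in fields], axis=0))


@dataclass(frozen=True)
class NoiseParams:
    """Gaussian perturbation: SD ``sigma`` on the real and imaginary parts."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def add_gaussian_noise(f: ComplexField, p: NoiseParams) -> ComplexField:
    """Add independent seeded Gaussian noise to Re and Im at every node."""
    if p.sigma == 0:
        return f.copy()
    rng = np.random.default_rng(p.seed)
    noise = rng.normal(0.0, p.sigma, f.values.shape) + 1j * rng.normal(
        0.0, p.sigma, f.values.shape
    )
    return ComplexField(f.grid, f.values + noise)


@dataclass(frozen=True)
class ThetaGammaParams:
    """Theta-envelope-on-gamma-carrier driver.

    ``psi(x, t) = (1 + A*sin(2*pi*f_theta*t)) * sin(omega_gamma*(x - c*t))``
    — a slow (theta) amplitude envelope nested on a fast spatial (gamma)
    carrier; ``A = 0`` recovers the pure carrier.
    """

    omega_gamma: float
    c: float = 1.0
    amplitude: float = 0.5
    f_theta: float = 0.02

    def __post_init__(self) -> None:
        if self.omega_gamma <= 0:
            raise ValueError("omega_gamma must be positive")
        if self.amplitude < 0:
            raise ValueError("theta amplitude must be non-negative")
        if self.f_theta <= 0:
            raise ValueError("f_theta must be positive")

    def envelope(self, t: float) -> float:
        return self.amplitude * np.sin(2.0 * np.pi * self.f_theta * t)


def theta_gamma_field(grid: SpatialGrid, t: float, p: ThetaGammaParams) -> ComplexField:
    """Amplitude-modulated carrier on a 1D grid."""
    if grid.dims != 1:
        raise GridError("theta_gamma_field is 1D")
    carrier = np.sin(p.omega_gamma * (grid.x - p.c * t))
    return ComplexField(grid, ((1.0 + p.envelope(t)) * carrier).astype(complex))


@dataclass(frozen=True)
class PlaneWaveSpec2D:
    """One traveling plane wave in 2D: direction (degrees), wavenumber,
    amplitude and propagation speed."""

    angle_deg: float
    k: float = 1.0
    amplitude: float = 1.0
    speed: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("wavenumber k must be positive")


def interference_field_2d(
    grid: SpatialGrid, specs: Sequence[PlaneWaveSpec2D], t: float
) -> ComplexField:
    """Superposition of traveling plane waves on a 2D grid.

    ``psi = sum_j A_j * cos(k_j*(x*cos(th_j) + y*sin(th_j)) - k_j*c_j*t)``.
    Three equal waves at 0/60/120 degrees tile the plane with triangular-
    lattice intensity maxima of spacing ``4*pi/(sqrt(3)*k)``.
    """
    if grid.dims != 2:
        raise GridError("interference_field_2d requires a 2D grid")
    if len(specs) == 0:
        raise ValueError("need at least one plane-wave spec")
    X, Y = grid.meshgrid()
    out = np.zeros(grid.shape)
    for s in specs:
        th = np.deg2rad(s.angle_deg)
        phase = s.k * (X * np.cos(th) + Y * np.sin(th)) - s.k * s.speed * t
        out += s.amplitude * np.cos(phase)
    return ComplexField(grid, out.astype(complex))
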