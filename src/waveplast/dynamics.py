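"""Time evolution of the Schrödinger-type activity field and the profile ODE.

The activity field obeys

    i*D*dpsi/dt + D**2 * Lap(psi) - V(x, t)*psi = 0,

i.e. ``dpsi/dt = i*D*Lap(psi) - (i/D)*V*psi`` with ``D`` the fractal
diffusion coefficient and ``V`` a real external potential. For a plane
wave ``exp(i*k*x)`` with ``V = 0`` the dispersion relation is
``omega = D*k**2``.

A naive forward-Euler discretization of this equation is unconditionally
unstable, so the integrator uses norm-preserving schemes instead: Strang
split-step Fourier on periodic grids (exact for the free propagator) and
an implicit-midpoint (Crank–Nicolson) solve on Neumann grids. Both keep
the discrete norm constant to round-off for real potentials, matching the
unitarity of the continuous equation; time-dependent potentials are
sampled at the step midpoint.

``integrate_profile_ode`` is an independent fixed-step RK4 integrator of
the traveling-wave profile equation ``Phi'' = alpha*Phi + beta*Phi**2``,
used to cross-check the closed-form soliton/cnoidal profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import ComplexField, GridError, RealField, SpatialGrid
from .waveforms import TravelingWaveParams

__all__ = [
    "SchrodingerParams",
    "EvolutionResult",
    "ProfileTrajectory",
    "schrodinger_step",
    "evolve_schrodinger",
    "integrate_profile_ode",
    "field_norm",
]

Potential = Union[None, RealField, Callable[..., np.ndarray]]


@dataclass(frozen=True)
class SchrodingerParams:
    """Fractal diffusion coefficient ``D > 0`` and the external potential.

    ``potential`` may be ``None`` (free evolution), a :class:`RealField`
    snapshot, or a callable ``V(coords..., t) -> array`` taking the
    meshgrid coordinate arrays and time.
    """

    D: float
    potential: Potential = None

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be positive (the equation degenerates at D=0)")

    def potential_values(self, grid: SpatialGrid, t: float) -> np.ndarray:
        if self.potential is None:
            return np.zeros(grid.shape)
        if isinstance(self.potential, RealField):
            if self.potential.grid != grid:
                raise GridError("potential snapshot lives on a different grid")
            return self.potential.values
        return np.broadcast_to(
            np.asarray(self.potential(*grid.meshgrid(), t), dtype=float), grid.shape
        )


def field_norm(psi: ComplexField) -> float:
    """Discrete norm ``integral |psi|^2 dx`` (trapezoid on Neumann grids)."""
    w = psi.grid.quadrature_weights()
    return float(np.sum(w * np.abs(psi.values) ** 2) * psi.grid.node_volume())


def _ksq(grid: SpatialGrid) -> np.ndarray:
    ks = [
        2.0 * np.pi * np.fft.fftfreq(n, d=dx)
        for n, dx in zip(grid.npoints, grid.spacing)
    ]
    if grid.dims == 1:
        return ks[0] ** 2
    KX, KY = np.meshgrid(ks[0], ks[1])
    return KX**2 + KY**2


def _neumann_matrix(grid: SpatialGrid) -> sp.csc_matrix:
    """1D/2D mirror-closure Laplacian as a sparse matrix (row-major nodes)."""

    def lap1(n: int, dx: float) -> sp.csr_matrix:
        main = -2.0 * np.ones(n)
        off = np.ones(n - 1)
        L = sp.diags([off, main, off], [-1, 0, 1], format="lil")
        L[0, 1] = 2.0
        L[n - 1, n - 2] = 2.0
        return (L / dx**2).tocsr()

    if grid.dims == 1:
        return lap1(grid.npoints[0], grid.spacing[0]).tocsc()
    nx, ny = grid.npoints
    dx, dy = grid.spacing
    Lx = lap1(nx, dx)
    Ly = lap1(ny, dy)
    return (sp.kron(sp.identity(ny), Lx) + sp.kron(Ly, sp.identity(nx))).tocsc()


def _step_periodic(
    psi: ComplexField, p: SchrodingerParams, t: float, dt: float
) -> ComplexField:
    V = p.potential_values(psi.grid, t + 0.5 * dt)
    half_kick = np.exp(-0.5j * dt * V / p.D)
    v = psi.values * half_kick
    ksq = _ksq(psi.grid)
    v = np.fft.ifftn(np.fft.fftn(v) * np.exp(-1j * p.D * ksq * dt))
    return ComplexField(psi.grid, v * half_kick)


def _step_neumann(
    psi: ComplexField, p: SchrodingerParams, t: float, dt: float
) -> ComplexField:
    g = psi.grid
    V = p.potential_values(g, t + 0.5 * dt).ravel()
    L = _neumann_matrix(g)
    A = 1j * p.D * L - sp.diags(1j * V / p.D)
    I = sp.identity(g.nnodes, format="csc")
    rhs = (I + 0.5 * dt * A) @ psi.values.ravel()
    new = spla.spsolve((I - 0.5 * dt * A).tocsc(), rhs)
    return ComplexField(g, new.reshape(g.shape))


def schrodinger_step(
    psi: ComplexField, p: SchrodingerParams, t: float, dt: float
) -> ComplexField:
    """Advance ``psi`` by one step of size ``dt`` starting at time ``t``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if psi.grid.boundary == "periodic":
        return _step_periodic(psi, p, t, dt)
    return _step_neumann(psi, p, t, dt)


@dataclass
class EvolutionResult:
    """Snapshots of an activity-field evolution plus the norm history."""

    times: np.ndarray
    fields: list[ComplexField]
    norms: np.ndarray


def evolve_schrodinger(
    psi0: ComplexField,
    p: SchrodingerParams,
    t_final: float,
    dt: float,
    snapshot_every: int = 1,
) -> EvolutionResult:
    """Integrate to ``t_final``, recording every ``snapshot_every`` steps.

    The initial state and the final state are always included; the last
    step is shortened if ``t_final`` is not a multiple of ``dt``.
    """
    if t_final < 0:
        raise ValueError("t_final must be non-negative")
    if snapshot_every < 1:
        raise ValueError("snapshot_every must be >= 1")
    times = [0.0]
    fields = [psi0.copy()]
    norms = [field_norm(psi0)]
    psi, t, k = psi0, 0.0, 0
    while t < t_final - 1e-12:
        step = min(dt, t_final - t)
        psi = schrodinger_step(psi, p, t, step)
        t += step
        k += 1
        if k % snapshot_every == 0 or t >= t_final - 1e-12:
            times.append(t)
            fields.append(psi.copy())
            norms.append(field_norm(psi))
    return EvolutionResult(np.asarray(times), fields, np.asarray(norms))


@dataclass
class ProfileTrajectory:
    """RK4 trajectory of the profile equation: ``(xi, phi, dphi)`` samples."""

    xi: np.ndarray
    phi: np.ndarray
    dphi: np.ndarray
    diverged: bool = False

    def first_integral(self, p: TravelingWaveParams) -> np.ndarray:
        """``(Phi')^2 - a*Phi^2 - (2/3)*b*Phi^3`` along the trajectory."""
        a, b = p.alpha_wave, p.beta_wave
        return self.dphi**2 - a * self.phi**2 - (2.0 / 3.0) * b * self.phi**3


_BLOWUP = 1.0e6


def integrate_profile_ode(
    phi0: float,
    dphi0: float,
    p: TravelingWaveParams,
    xi_max: float,
    step: float,
) -> ProfileTrajectory:
    """Fixed-step RK4 integration of ``Phi'' = a*Phi + b*Phi**2`` from xi=0.

    Truncates and flags the trajectory as divergent if ``|Phi|`` exceeds
    1e6 (the quadratic nonlinearity has genuine blow-up solutions).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    a, b = p.alpha_wave, p.beta_wave

    def f(y: np.ndarray) -> np.ndarray:
        return np.array([y[1], a * y[0] + b * y[0] ** 2])

    n = int(round(xi_max / step))
    y = np.array([phi0, dphi0], dtype=float)
    xs, phis, dphis = [0.0], [y[0]], [y[1]]
    diverged = False
    for i in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * step * k1)
        k3 = f(y + 0.5 * step * k2)
        k4 = f(y + step * k3)
        y = y + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.isfinite(y).all() or abs(y[0]) > _BLOWUP:
            diverged = True
            break
        xs.append((i + 1) * step)
        phis.append(y[0])
        dphis.append(y[1])
    return ProfileTrajectory(
        np.asarray(xs), np.asarray(phis), np.asarray(dphis), diverged
    )
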