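"""Logistic reaction–diffusion dynamics of the synaptic weight field.

The weight field ``W(x, t)`` evolves under

    dW/dt = rho*W*(1 - W/K) + s*alpha*|psi|^2*W + D_W*Lap(W),

where ``rho`` is the intrinsic growth rate, ``K`` the carrying capacity,
``alpha`` the activity-coupling gain, ``D_W`` the weight diffusion and
``s`` the coupling sign. With ``s = -1`` activity suppresses local
weights (activity-dependent depression); with ``s = +1`` activity drives
localized potentiation, saturated by the logistic term. Both regimes are
supported; ``s = -1`` is the default.

Integration is forward Euler with a no-flux (mirror) closure for the
diffusion term, subject to the explicit-diffusion CFL bound
``dt <= dx^2 / (2*d*D_W)``. From non-negative initial data the dynamics
keep ``W`` in ``[0, K*(1 + dt*rho)]``; any negative undershoot (possible
only for very strong drives at coarse ``dt``) is clamped to zero with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fields import (
    ComplexField,
    GridError,
    RealField,
    cfl_max_timestep,
    laplacian,
)

__all__ = [
    "PlasticityParams",
    "PlasticityState",
    "CoupledTrajectory",
    "plasticity_rhs",
    "plasticity_step",
    "evolve_coupled",
    "logistic_closed_form",
    "uniform_steady_state",
    "StabilityError",
]


class StabilityError(ValueError):
    """Time step violates an explicit-scheme stability bound."""


@dataclass(frozen=True)
class PlasticityParams:
    """Parameters of the weight-field equation (defaults per the reference
    simulation setup: ``rho = 1``, ``K = 1``, ``alpha = 1``, ``D_W = 0.5``)."""

    rho: float = 1.0
    K: float = 1.0
    alpha_plast: float = 1.0
    D_W: float = 0.5
    coupling_sign: int = -1

    def __post_init__(self) -> None:
        if self.rho < 0 or self.K <= 0:
            raise ValueError("rho must be non-negative and K positive")
        if self.alpha_plast < 0 or self.D_W < 0:
            raise ValueError("alpha_plast and D_W must be non-negative")
        if self.coupling_sign not in (-1, 1):
            raise ValueError("coupling_sign must be -1 or +1")


@dataclass
class PlasticityState:
    """Weight field plus the simulation clock."""

    W: RealField
    time: float = 0.0


def plasticity_rhs(
    W: RealField, intensity: RealField, p: PlasticityParams
) -> RealField:
    """Pointwise right-hand side of the weight equation.

    The diffusion term always uses the no-flux closure, regardless of the
    wave grid's boundary tag (waves are periodic, plasticity is no-flux).
    """
    if intensity.grid != W.grid:
        raise GridError("W and intensity must share a grid")
    if np.any(intensity.values < 0):
        raise ValueError("intensity must be non-negative")
    w = W.values
    rhs = p.rho * w * (1.0 - w / p.K)
    rhs = rhs + p.coupling_sign * p.alpha_plast * intensity.values * w
    if p.D_W > 0:
        rhs = rhs + p.D_W * laplacian(W, boundary="neumann").values
    return RealField(W.grid, rhs)


def plasticity_step(
    state: PlasticityState,
    intensity: RealField,
    p: PlasticityParams,
    dt: float,
) -> PlasticityState:
    """One forward-Euler update; refuses CFL-violating time steps."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    bound = cfl_max_timestep(p.D_W, state.W.grid)
    if dt > bound * (1.0 + 1e-12):
        raise StabilityError(
            f"dt={dt} exceeds the explicit-diffusion CFL bound {bound}; "
            "reduce dt or sub-step"
        )
    if dt * p.rho >= 1.0:
        raise StabilityError(f"dt*rho = {dt * p.rho} must be < 1 for explicit Euler")
    new = state.W.values + dt * plasticity_rhs(state.W, intensity, p).values
    if np.any(new < 0):
        warnings.warn(
            "weight field undershot zero and was clamped", RuntimeWarning
        )
        new = np.maximum(new, 0.0)
    return PlasticityState(RealField(state.W.grid, new), state.time + dt)


def logistic_closed_form(
    w0: float, t: float, rho: float = 1.0, K: float = 1.0
) -> float:
    """Exact uniform logistic solution (zero drive, zero diffusion)."""
    e = np.exp(rho * t)
    return K * w0 * e / (K + w0 * (e - 1.0))


def uniform_steady_state(intensity: float, p: PlasticityParams) -> float:
    """Homogeneous fixed point for constant intensity.

    ``K * max(0, 1 + s*alpha*I/rho)`` — the non-trivial root of the
    reaction terms, clipped at extinction.
    """
    return p.K * max(
        0.0, 1.0 + p.coupling_sign * p.alpha_plast * intensity / p.rho
    )


@dataclass
class CoupledTrajectory:
    """Snapshots of a driven plasticity run plus summary time series.

    ``mean_intensity`` is the running time average of the drive
    ``|psi|^2`` over all steps taken (not just snapshot instants).
    """

    times: np.ndarray
    W_snapshots: list[RealField]
    intensity_snapshots: list[RealField]
    mean_W: np.ndarray
    max_W: np.ndarray
    sd_W: np.ndarray
    mean_intensity: RealField

    @property
    def final_W(self) -> RealField:
        return self.W_snapshots[-1]


def evolve_coupled(
    driver: Callable[[float], ComplexField],
    W0: RealField,
    p: PlasticityParams,
    t_final: float,
    dt: float,
    snapshot_every: int = 100,
    allow_substep: bool = True,
) -> CoupledTrajectory:
    """Drive the weight field with ``|driver(t)|^2`` from 0 to ``t_final``.

    The drive is sampled once per outer step of size ``dt``; if ``dt``
    violates the diffusion CFL bound and ``allow_substep`` is true, each
    outer step is split into equal stable sub-steps (holding the
    intensity fixed across them), mirroring the reference setup where the
    nominal step can exceed the 2D stability limit.
    """
    if t_final < 0:
        raise ValueError("t_final must be non-negative")
    bound = cfl_max_timestep(p.D_W, W0.grid)
    nsub = 1
    if dt > bound:
        if not allow_substep:
            raise StabilityError(
                f"dt={dt} exceeds CFL bound {bound} and sub-stepping is disabled"
            )
        nsub = int(np.ceil(dt / bound))
    state = PlasticityState(W0.copy(), 0.0)
    nsteps = int(round(t_final / dt))
    times = [0.0]
    Ws = [state.W.copy()]
    intens0 = driver(0.0).intensity()
    intensities = [intens0]
    mean_W = [float(state.W.values.mean())]
    max_W = [float(state.W.values.max())]
    sd_W = [float(state.W.values.std())]
    accum = np.zeros(W0.grid.shape)
    for k in range(nsteps):
        t = k * dt
        intensity = driver(t).intensity()
        accum += intensity.values
        for j in range(nsub):
            state = plasticity_step(state, intensity, p, dt / nsub)
        state = PlasticityState(state.W, (k + 1) * dt)  # avoid dt round-off drift
        if (k + 1) % snapshot_every == 0 or k + 1 == nsteps:
            times.append(state.time)
            Ws.append(state.W.copy())
            intensities.append(intensity)
            mean_W.append(float(state.W.values.mean()))
            max_W.append(float(state.W.values.max()))
            sd_W.append(float(state.W.values.std()))
    mean_int = RealField(W0.grid, accum / max(nsteps, 1))
    return CoupledTrajectory(
        np.asarray(times),
        Ws,
        intensities,
        np.asarray(mean_W),
        np.asarray(max_W),
        np.asarray(sd_W),
        mean_int,
    )
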