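"""Spatial grids, field containers, discrete Laplacians and stability bounds.

Everything in the package is sampled on a :class:`SpatialGrid` — a uniform
1D or 2D lattice with either periodic or Neumann (no-flux) boundaries.
Conventions:

* periodic grids exclude the duplicate right endpoint, so ``dx = L / n``
  and the fast Fourier transform sees exactly one period;
* Neumann grids include both endpoints, so ``dx = L / (n - 1)`` and the
  no-flux condition is imposed by a ghost-node mirror (``f[-1] == f[1]``),
  which is exact for fields symmetric about the boundary;
* 1D arrays are indexed by x; 2D arrays are row-major with y on axis 0 and
  x on axis 1 (``values[j, i]`` is the node at ``(x_i, y_j)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SpatialGrid",
    "RealField",
    "ComplexField",
    "make_grid",
    "laplacian",
    "cfl_max_timestep",
    "GridError",
]

Boundary = Literal["periodic", "neumann"]

_MIN_POINTS = 8


class GridError(ValueError):
    """Invalid grid construction or mismatched grids."""


@dataclass(frozen=True)
class SpatialGrid:
    """A uniform rectangular lattice in one or two spatial dimensions.

    Parameters
    ----------
    extents
        One ``(lo, hi)`` interval per axis, ordered (x,) or (x, y).
    npoints
        Number of nodes per axis, same order.
    boundary
        ``"periodic"`` or ``"neumann"``; fixes both the endpoint
        convention and the Laplacian closure.
    """

    extents: tuple[tuple[float, float], ...]
    npoints: tuple[int, ...]
    boundary: Boundary

    def __post_init__(self) -> None:
        if self.boundary not in ("periodic", "neumann"):
            raise GridError(f"unknown boundary tag {self.boundary!r}")
        if len(self.extents) != len(self.npoints) or len(self.npoints) not in (1, 2):
            raise GridError("grid must have 1 or 2 axes with matching extents")
        for (lo, hi), n in zip(self.extents, self.npoints):
            if not np.isfinite([lo, hi]).all() or hi <= lo:
                raise GridError(f"degenerate extent ({lo}, {hi})")
            if n < _MIN_POINTS:
                raise GridError(f"need at least {_MIN_POINTS} points per axis, got {n}")

    @property
    def dims(self) -> int:
        return len(self.npoints)

    @property
    def spacing(self) -> tuple[float, ...]:
        out = []
        for (lo, hi), n in zip(self.extents, self.npoints):
            denom = n if self.boundary == "periodic" else n - 1
            out.append((hi - lo) / denom)
        return tuple(out)

    @property
    def axes(self) -> tuple[np.ndarray, ...]:
        """Coordinate arrays per axis, ordered (x,) or (x, y)."""
        return tuple(
            lo + dx * np.arange(n)
            for (lo, _), dx, n in zip(self.extents, self.spacing, self.npoints)
        )

    @property
    def shape(self) -> tuple[int, ...]:
        # y outer, x inner for 2D arrays
        return tuple(reversed(self.npoints))

    @property
    def nnodes(self) -> int:
        return int(np.prod(self.npoints))

    @property
    def x(self) -> np.ndarray:
        return self.axes[0]

    def meshgrid(self) -> tuple[np.ndarray, ...]:
        """Node coordinate arrays broadcast to ``self.shape``.

        Returns ``(X,)`` in 1D and ``(X, Y)`` in 2D, each of shape
        ``self.shape`` with x varying along the last axis.
        """
        if self.dims == 1:
            return (self.axes[0].copy(),)
        X, Y = np.meshgrid(self.axes[0], self.axes[1])
        return X, Y

    def node_volume(self) -> float:
        """dx (1D) or dx*dy (2D) — the quadrature weight of one node."""
        return float(np.prod(self.spacing))

    def quadrature_weights(self) -> np.ndarray:
        """Trapezoid weights for integrals over the grid.

        Uniform for periodic grids; half-weight endpoints for Neumann
        grids so that ``sum(w * f) * node_volume`` is the trapezoid rule.
        """
        ws = []
        for n in self.npoints:
            w = np.ones(n)
            if self.boundary == "neumann":
                w[0] = w[-1] = 0.5
            ws.append(w)
        if self.dims == 1:
            return ws[0]
        return np.outer(ws[1], ws[0])


def make_grid(
    dims: int,
    extent: Sequence[float] | Sequence[Sequence[float]],
    n: int | Sequence[int],
    boundary: Boundary = "periodic",
) -> SpatialGrid:
    """Build a :class:`SpatialGrid`.

    ``extent`` may be a single ``(lo, hi)`` pair (replicated across axes)
    or one pair per axis; likewise ``n`` may be a scalar or per-axis.
    """
    if dims not in (1, 2):
        raise GridError("dims must be 1 or 2")
    ext = np.asarray(extent, dtype=float)
    if ext.ndim == 1:
        extents = tuple((float(ext[0]), float(ext[1])) for _ in range(dims))
    else:
        if ext.shape[0] != dims:
            raise GridError("one extent interval required per axis")
        extents = tuple((float(lo), float(hi)) for lo, hi in ext)
    if np.isscalar(n):
        ns = (int(n),) * dims
    else:
        ns = tuple(int(v) for v in n)
        if len(ns) != dims:
            raise GridError("one point count required per axis")
    return SpatialGrid(extents=extents, npoints=ns, boundary=boundary)


def _check_values(grid: SpatialGrid, values: np.ndarray) -> None:
    if values.shape != grid.shape:
        raise GridError(
            f"value shape {values.shape} does not match grid shape {grid.shape}"
        )
    if not np.isfinite(values).all():
        raise GridError("field contains non-finite values")


@dataclass
class RealField:
    """Real scalar field sampled on a grid (synaptic weight, intensity, ...)."""

    grid: SpatialGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_values(self.grid, self.values)

    def copy(self) -> "RealField":
        return RealField(self.grid, self.values.copy())


@dataclass
class ComplexField:
    """Complex scalar field sampled on a grid (the neural activity psi)."""

    grid: SpatialGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        _check_values(self.grid, self.values)

    def copy(self) -> "ComplexField":
        return ComplexField(self.grid, self.values.copy())

    def intensity(self) -> RealField:
        """|psi|^2 — the activity intensity that drives plasticity."""
        return RealField(self.grid, np.abs(self.values) ** 2)


def _lap1d(v: np.ndarray, dx: float, boundary: str, axis: int = 0) -> np.ndarray:
    if boundary == "periodic":
        out = np.roll(v, -1, axis=axis) + np.roll(v, 1, axis=axis) - 2.0 * v
    else:
        # ghost-node mirror: f[-1] = f[1], f[n] = f[n-2]
        pad = np.concatenate(
            [
                np.take(v, [1], axis=axis),
                v,
                np.take(v, [-2], axis=axis),
            ],
            axis=axis,
        )
        n = v.shape[axis]
        sl = [slice(None)] * v.ndim
        sl_lo, sl_mid, sl_hi = list(sl), list(sl), list(sl)
        sl_lo[axis] = slice(0, n)
        sl_mid[axis] = slice(1, n + 1)
        sl_hi[axis] = slice(2, n + 2)
        out = pad[tuple(sl_lo)] + pad[tuple(sl_hi)] - 2.0 * pad[tuple(sl_mid)]
    return out / dx**2


def laplacian(f: RealField | ComplexField, boundary: Boundary | None = None):
    """Second-order central-difference Laplacian of a field.

    3-point stencil in 1D, 5-point in 2D. The boundary closure follows the
    grid's tag unless ``boundary`` overrides it (the weight field uses a
    no-flux closure even when it shares nodes with a periodic wave grid).
    """
    g = f.grid
    b = boundary if boundary is not None else g.boundary
    if b not in ("periodic", "neumann"):
        raise GridError(f"unknown boundary tag {b!r}")
    v = f.values
    if g.dims == 1:
        out = _lap1d(v, g.spacing[0], b, axis=0)
    else:
        dx, dy = g.spacing
        out = _lap1d(v, dx, b, axis=1) + _lap1d(v, dy, b, axis=0)
    return type(f)(g, out)


def cfl_max_timestep(diffusion_coefficient: float, grid: SpatialGrid) -> float:
    """Largest stable forward-Euler time step for explicit diffusion.

    ``dt_max = dx^2 / (2 * d * D)`` with ``d`` the number of spatial
    dimensions; ``inf`` when the coefficient is zero. The smallest grid
    spacing is used for anisotropic 2D grids.
    """
    if diffusion_coefficient < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if diffusion_coefficient == 0:
        return float("inf")
    dx = min(grid.spacing)
    return dx**2 / (2.0 * grid.dims * diffusion_coefficient)
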