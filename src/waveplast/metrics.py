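"""Quantitative analysis of weight and intensity fields.

Covers the Fourier power spectrum and its Shannon (spectral) entropy,
lagged cross-correlation between drive and weights, field summary
statistics, the hysteresis suite of the forward–reverse stimulation
protocol (loop area, normalized loop area, reversibility, trace overlap,
per-position hysteresis density), and a nearest-neighbor lattice-spacing
estimator for 2D weight maps.

Spectral-entropy conventions (transform sidedness, log base, DC handling)
are not standardized across the literature, so every entropy/spectrum
call takes an explicit :class:`EntropyConvention` that is echoed into
serialized outputs. The package default is base-2 (bits), one-sided
spectrum, DC bin excluded: a pure tone then has entropy exactly 0 and a
flat N-bin spectrum exactly ``log2(N)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .fields import RealField

__all__ = [
    "EntropyConvention",
    "SpectrumResult",
    "HysteresisResult",
    "power_spectrum",
    "spectral_entropy",
    "cross_correlation",
    "field_summary",
    "hysteresis_metrics",
    "lattice_peak_spacing",
    "InsufficientStructureError",
]


class InsufficientStructureError(ValueError):
    """The field lacks the structure the estimator needs (e.g. < 3 peaks)."""


@dataclass(frozen=True)
class EntropyConvention:
    """Fixes the spectral-entropy conventions for one analysis run."""

    log_base: Literal["2", "e"] = "2"
    side: Literal["one", "two"] = "one"
    include_dc: bool = False

    def log(self, x: np.ndarray) -> np.ndarray:
        return np.log2(x) if self.log_base == "2" else np.log(x)

    def as_dict(self) -> dict:
        return {
            "log_base": self.log_base,
            "side": self.side,
            "include_dc": self.include_dc,
        }


DEFAULT_CONVENTION = EntropyConvention()


@dataclass
class SpectrumResult:
    """Frequency bins (cycles per unit length) and unit-sum power."""

    frequencies: np.ndarray
    power: np.ndarray


def power_spectrum(
    f: RealField | np.ndarray,
    convention: EntropyConvention = DEFAULT_CONVENTION,
    spacing: float | None = None,
) -> SpectrumResult:
    """Normalized Fourier power spectrum of a 1D field.

    The squared DFT magnitudes are folded per the convention (one- or
    two-sided, with or without the DC bin) and normalized to sum to one.
    """
    if isinstance(f, RealField):
        if f.grid.dims != 1:
            raise ValueError("power_spectrum expects a 1D field")
        v = f.values
        d = f.grid.spacing[0]
    else:
        v = np.asarray(f, dtype=float)
        d = 1.0 if spacing is None else spacing
    if v.size < 8:
        raise ValueError("need at least 8 samples")
    if convention.side == "one":
        amp = np.fft.rfft(v)
        freqs = np.fft.rfftfreq(v.size, d=d)
    else:
        amp = np.fft.fft(v)
        freqs = np.fft.fftfreq(v.size, d=d)
    power = np.abs(amp) ** 2
    if not convention.include_dc:
        keep = freqs != 0.0
        freqs, power = freqs[keep], power[keep]
    total = power.sum()
    if total == 0:
        raise ValueError("spectrum has zero total power; normalization undefined")
    return SpectrumResult(freqs, power / total)


def spectral_entropy(
    f: RealField | np.ndarray,
    convention: EntropyConvention = DEFAULT_CONVENTION,
    spacing: float | None = None,
) -> float:
    """Shannon entropy of the normalized power spectrum.

    Zero-power bins contribute nothing (the ``p*log p -> 0`` limit).
    Units are bits for base 2, nats for base e.
    """
    p = power_spectrum(f, convention, spacing).power
    p = p[p > 0]
    return float(-np.sum(p * convention.log(p)))


def cross_correlation(
    a: RealField | np.ndarray,
    b: RealField | np.ndarray,
    mode: Literal["raw_mean", "pearson"] = "raw_mean",
) -> tuple[float, int]:
    """Peak circular cross-correlation and the lag (in nodes) achieving it.

    ``raw_mean``: ``max_lag (1/N) * sum_x a(x) * b(x + lag)`` — an
    unnormalized product correlation whose peak can exceed 1.
    ``pearson``: the lagged Pearson coefficient, bounded in [-1, 1].
    Lags are reported signed in ``(-N/2, N/2]``; ties resolve to the
    smallest ``|lag|``.
    """
    av = a.values if isinstance(a, RealField) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, RealField) else np.asarray(b, dtype=float)
    if av.ndim != 1 or av.shape != bv.shape:
        raise ValueError("cross_correlation expects matching 1D inputs")
    n = av.size
    if mode == "pearson":
        if av.std() == 0 or bv.std() == 0:
            raise ValueError("pearson mode undefined for constant input")
        av = (av - av.mean()) / av.std()
        bv = (bv - bv.mean()) / bv.std()
    elif mode != "raw_mean":
        raise ValueError(f"unknown mode {mode!r}")
    # c[lag] = (1/N) sum_x a(x) b(x+lag), circular, via FFT
    corr = np.fft.ifft(np.conj(np.fft.fft(av)) * np.fft.fft(bv)).real / n
    lags = np.arange(n)
    signed = np.where(lags > n // 2, lags - n, lags)
    order = np.lexsort((np.abs(signed), -corr))
    best = order[0]
    return float(corr[best]), int(signed[best])


def field_summary(W: RealField) -> tuple[float, float, float]:
    """(mean, max, population SD) of a weight field."""
    v = W.values
    return float(v.mean()), float(v.max()), float(v.std())


@dataclass
class HysteresisResult:
    """Outputs of the forward–reverse protocol quantification.

    ``h_signed`` is the signed loop area ``closed-integral of Wbar dI``;
    ``h_norm`` normalizes ``|H|`` by the bounding-box area of the loop;
    ``r`` measures recovery toward baseline; ``omega`` is the cosine
    similarity of the post-forward and post-reverse fields; ``h_x`` (when
    a weight trajectory is supplied) is the per-position loop area, whose
    spatial mean equals ``h_signed``.
    """

    h_signed: float
    h_abs: float
    h_norm: float
    r: float
    omega: float
    h_x: Optional[RealField] = None


def _trapezoid_loop_area(w: np.ndarray, i: np.ndarray, axis: int = -1) -> np.ndarray:
    # sum_k (1/2) (w_{k+1} + w_k) (i_{k+1} - i_k)
    wm = np.moveaxis(w, axis, -1)
    return 0.5 * np.sum((wm[..., 1:] + wm[..., :-1]) * np.diff(i), axis=-1)


def hysteresis_metrics(
    wbar: Sequence[float],
    I: Sequence[float],
    w_fwd: RealField,
    w_rev: RealField,
    w_0: RealField,
    w_traj: Optional[Sequence[RealField]] = None,
    closure_tol: float = 1e-8,
) -> HysteresisResult:
    """Quantify path dependence of a closed drive loop.

    Parameters
    ----------
    wbar, I
        Spatial-mean weight and signed drive amplitude at matched times;
        ``I`` must close its loop (first value == last within tolerance).
    w_fwd, w_rev, w_0
        Weight fields after the forward epoch, after the reverse epoch,
        and at baseline.
    w_traj
        Optional weight snapshots aligned with ``I``; enables the
        per-position hysteresis density.
    """
    wbar = np.asarray(wbar, dtype=float)
    I = np.asarray(I, dtype=float)
    if wbar.shape != I.shape or wbar.ndim != 1 or wbar.size < 3:
        raise ValueError("wbar and I must be matching 1D series of length >= 3")
    span = max(np.ptp(I), 1.0)
    if abs(I[0] - I[-1]) > closure_tol * span:
        raise ValueError("drive series does not close its loop (I[0] != I[-1])")

    h_signed = float(_trapezoid_loop_area(wbar, I))
    h_abs = abs(h_signed)

    di, dw = np.ptp(I), np.ptp(wbar)
    if di == 0 or dw == 0:
        if h_abs == 0:
            h_norm = 0.0  # degenerate zero-area loop: nothing to normalize
        else:
            raise ValueError("degenerate drive or weight range; h_norm undefined")
    else:
        h_norm = h_abs / (di * dw)

    num = np.linalg.norm(w_rev.values - w_0.values)
    den = np.linalg.norm(w_fwd.values - w_0.values)
    r = 1.0 if den == 0 else float(1.0 - num / den)

    nf = np.linalg.norm(w_fwd.values)
    nr = np.linalg.norm(w_rev.values)
    if nf == 0 or nr == 0:
        raise ValueError("zero-norm field; trace overlap undefined")
    omega = float(np.vdot(w_fwd.values.ravel(), w_rev.values.ravel()) / (nf * nr))

    h_x = None
    if w_traj is not None:
        if len(w_traj) != I.size:
            raise ValueError("w_traj must align with the drive series")
        stack = np.stack([w.values for w in w_traj], axis=-1)
        h_x = RealField(w_traj[0].grid, _trapezoid_loop_area(stack, I))
    return HysteresisResult(h_signed, h_abs, float(h_norm), r, omega, h_x)


def lattice_peak_spacing(
    W: RealField,
    min_prominence: float = 0.7,
    neighborhood_radius: int = 3,
) -> tuple[float, int]:
    """Median nearest-neighbor spacing among local maxima of a 2D field.

    Local maxima are nodes matching the maximum of their
    ``(2r+1) x (2r+1)`` neighborhood and exceeding
    ``min + min_prominence * (max - min)``; plateau/ridge maxima are
    merged into their connected-component centroid (so a pure stripe
    pattern reports the stripe period). Needs at least 3 peaks.
    """
    if W.grid.dims != 2:
        raise ValueError("lattice_peak_spacing expects a 2D field")
    if not 0 < min_prominence <= 1:
        raise ValueError("min_prominence must lie in (0, 1]")
    v = W.values
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        raise InsufficientStructureError("field is constant; no peaks")
    thresh = lo + min_prominence * (hi - lo)
    size = 2 * neighborhood_radius + 1
    # +inf padding keeps monotone ramps cut off by the domain edge from
    # registering as spurious border maxima
    filt = ndimage.maximum_filter(v, size=size, mode="constant", cval=np.inf)
    mask = (v >= filt) & (v >= thresh)
    labels, ncomp = ndimage.label(mask)
    if ncomp < 3:
        raise InsufficientStructureError(
            f"found {ncomp} peaks; need at least 3 for a spacing estimate"
        )
    centroids = ndimage.center_of_mass(mask, labels, range(1, ncomp + 1))
    dx, dy = W.grid.spacing
    x0, _ = W.grid.extents[0]
    y0, _ = W.grid.extents[1]
    pts = np.array([(x0 + cx * dx, y0 + cy * dy) for cy, cx in centroids])
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    return float(np.median(dists[:, 1])), int(ncomp)
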