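"""Pairwise non-rigid motion estimation between same-contrast image pairs.

A multi-resolution variational optical-flow scheme: the sum-of-squared
-difference data term is linearized around the current warp (Gauss-Newton)
and the Euler-Lagrange system with the ``lam``-weighted Laplacian smoothness
term is relaxed by Jacobi sweeps, coarse-to-fine over a Gaussian pyramid.
The fixed image is the model-synthesized one; the returned field warps the
acquired (moving) image into the model frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .signal_model import WeightedSeries

__all__ = [
    "MotionField",
    "MotionFieldSet",
    "RegConfig",
    "warp",
    "estimate_motion",
    "estimate_series_motion",
]


@dataclass
class MotionField:
    """Dense 2D displacement field in pixels; zero field is the identity.

    ``dy``/``dx`` give, per output pixel, the offset at which the source
    image is sampled (``out(x) = img(x + d(x))``).
    """

    dy: np.ndarray
    dx: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.dy = np.asarray(self.dy, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        if self.dy.shape != self.dx.shape or self.dy.ndim != 2:
            raise ValueError("dy and dx must be 2D arrays of one shape")
        if not (np.all(np.isfinite(self.dy)) and np.all(np.isfinite(self.dx))):
            raise ValueError("motion field must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dy.shape

    @classmethod
    def zero(cls, shape, spacing=(1.0, 1.0)) -> "MotionField":
        return cls(np.zeros(shape), np.zeros(shape), spacing)

    def magnitude(self) -> np.ndarray:
        """Per-pixel displacement magnitude in pixels."""
        return np.hypot(self.dy, self.dx)

    def magnitude_mm(self) -> np.ndarray:
        return np.hypot(self.dy * self.spacing[0], self.dx * self.spacing[1])

    def gradient_energy(self) -> float:
        """Sum of squared forward-difference gradients of both components."""
        e = 0.0
        for c in (self.dy, self.dx):
            e += float(np.sum(np.diff(c, axis=0) ** 2))
            e += float(np.sum(np.diff(c, axis=1) ** 2))
        return e

    def copy(self) -> "MotionField":
        return MotionField(self.dy.copy(), self.dx.copy(), self.spacing)


@dataclass
class MotionFieldSet:
    """One displacement field per image of a weighted series."""

    fields: list

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("MotionFieldSet needs at least one field")
        shp = self.fields[0].shape
        if any(f.shape != shp for f in self.fields):
            raise ValueError("all motion fields must share one grid")

    def __len__(self) -> int:
        return len(self.fields)

    def __iter__(self):
        return iter(self.fields)

    @classmethod
    def zero(cls, n: int, shape, spacing=(1.0, 1.0)) -> "MotionFieldSet":
        return cls([MotionField.zero(shape, spacing) for _ in range(n)])

    def copy(self) -> "MotionFieldSet":
        return MotionFieldSet([f.copy() for f in self.fields])


@dataclass
class RegConfig:
    lam: float = 0.008
    levels: int = 4
    inner_iter: int = 100
    n_warps: int = 10
    update_step: float = 1.0  # Jacobi relaxation factor
    median_filter: bool = True
    presmooth_sigma: float = 0.8  # Gaussian blur before flow (px); 0 = off

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.inner_iter < 1 or self.n_warps < 1:
            raise ValueError("inner_iter and n_warps must be >= 1")


def warp(image: np.ndarray, field: MotionField) -> np.ndarray:
    """Resample ``image`` along ``field``: ``out(x) = image(x + d(x))`` with
    bilinear interpolation and edge-clamped (replicate) sampling."""
    image = np.asarray(image, dtype=float)
    if image.shape != field.shape:
        raise ValueError("image and field shapes must match")
    if not np.any(field.dy) and not np.any(field.dx):
        return image.copy()
    yy, xx = np.meshgrid(
        np.arange(image.shape[0], dtype=float),
        np.arange(image.shape[1], dtype=float),
        indexing="ij",
    )
    return ndimage.map_coordinates(
        image, [yy + field.dy, xx + field.dx], order=1, mode="nearest"
    )


def _downsample(img: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma=1.0, mode="nearest")[::2, ::2]


def _pyramid(img: np.ndarray, levels: int) -> list:
    pyr = [img]
    for _ in range(levels - 1):
        if min(pyr[-1].shape) < 8:
            break
        pyr.append(_downsample(pyr[-1]))
    return pyr[::-1]  # coarse to fine


def _upsample_to(fld: np.ndarray, shape) -> np.ndarray:
    zy = shape[0] / fld.shape[0]
    zx = shape[1] / fld.shape[1]
    out = ndimage.zoom(fld, (zy, zx), order=1, mode="nearest", grid_mode=True)
    return out[: shape[0], : shape[1]]


def _neighbor_mean(a: np.ndarray) -> np.ndarray:
    """4-neighbor average with replicate boundary."""
    p = np.pad(a, 1, mode="edge")
    return 0.25 * (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:])


def _flow_level(fixed, moving, u, v, lam, inner_iter, n_warps, step, use_median):
    """Refine flow (v=dy, u=dx) at one pyramid level."""
    gy_f, gx_f = np.gradient(fixed)
    for _ in range(n_warps):
        warped = warp(moving, MotionField(v, u))
        gy_w, gx_w = np.gradient(warped)
        ix = 0.5 * (gx_w + gx_f)
        iy = 0.5 * (gy_w + gy_f)
        # residual at the linearization point: data term is
        # it + ix*(U-u0) + iy*(V-v0)
        it = warped - fixed
        u0, v0 = u.copy(), v.copy()
        denom = lam + ix * ix + iy * iy
        for _ in range(inner_iter):
            ub = _neighbor_mean(u)
            vb = _neighbor_mean(v)
            shared = (ix * (ub - u0) + iy * (vb - v0) + it) / denom
            u_new = ub - ix * shared
            v_new = vb - iy * shared
            u = u + step * (u_new - u)
            v = v + step * (v_new - v)
        if use_median:
            u = ndimage.median_filter(u, size=3, mode="nearest")
            v = ndimage.median_filter(v, size=3, mode="nearest")
    return u, v


def estimate_motion(
    fixed: np.ndarray,
    moving: np.ndarray,
    config: RegConfig | None = None,
    init: MotionField | None = None,
) -> MotionField:
    """Estimate the displacement field aligning ``moving`` to ``fixed``.

    Minimizes (locally) ``||fixed - warp(moving, d)||^2 + lam ||grad d||^2``
    coarse-to-fine. Intensities are normalized by the fixed image's 95th
    percentile so ``lam`` is comparable across intensity scales. ``init``
    warm-starts the solve (the field is carried down to the coarsest level),
    which lets an outer alternation refine fields across iterations instead
    of re-converging from zero. A flat (zero-variance) fixed image yields a
    zero field with a warning.
    """
    config = config or RegConfig()
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share one shape")
    if float(fixed.std()) == 0.0:
        warnings.warn(
            "flat fixed image: returning zero motion field", RuntimeWarning
        )
        return MotionField.zero(fixed.shape)

    s = float(np.percentile(np.abs(fixed), 95))
    if s <= 0:
        s = float(np.abs(fixed).max()) or 1.0
    fixed = fixed / s
    moving = moving / s
    if config.presmooth_sigma > 0:
        fixed = ndimage.gaussian_filter(fixed, config.presmooth_sigma,
                                        mode="nearest")
        moving = ndimage.gaussian_filter(moving, config.presmooth_sigma,
                                         mode="nearest")

    pf = _pyramid(fixed, config.levels)
    pm = _pyramid(moving, config.levels)
    if init is not None and (np.any(init.dy) or np.any(init.dx)):
        shape0 = pf[0].shape
        u = _upsample_to(init.dx, shape0) * (shape0[1] / fixed.shape[1])
        v = _upsample_to(init.dy, shape0) * (shape0[0] / fixed.shape[0])
    else:
        u = np.zeros(pf[0].shape)
        v = np.zeros(pf[0].shape)
    for lvl, (f_l, m_l) in enumerate(zip(pf, pm)):
        if lvl > 0:
            u = _upsample_to(u, f_l.shape) * (f_l.shape[1] / pf[lvl - 1].shape[1])
            v = _upsample_to(v, f_l.shape) * (f_l.shape[0] / pf[lvl - 1].shape[0])
        u, v = _flow_level(
            f_l, m_l, u, v, config.lam, config.inner_iter,
            config.n_warps, config.update_step, config.median_filter,
        )
    return MotionField(dy=v, dx=u)


def estimate_series_motion(
    synth: WeightedSeries,
    acquired: WeightedSeries,
    config: RegConfig | None = None,
    init: MotionFieldSet | None = None,
) -> MotionFieldSet:
    """Independent pairwise motion estimation per TSL index: the synthetic
    (model) image is the fixed target, the acquired image is moving."""
    if synth.n_tsl != acquired.n_tsl or synth.shape != acquired.shape:
        raise ValueError("synthetic and acquired series must share grid and N_TSL")
    if init is not None and len(init) != synth.n_tsl:
        raise ValueError("init must hold one field per TSL image")
    fields = []
    for t in range(synth.n_tsl):
        f = estimate_motion(
            synth.images[t], acquired.images[t], config,
            init=None if init is None else init.fields[t],
        )
        f.spacing = acquired.spacing
        fields.append(f)
    return MotionFieldSet(fields)
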