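"""Regularized mono-exponential map fitting.

Solves, per pixel stack, ``min_p sum_t ||f_t(p) - y_t||^2 + mu ||G p||^2``
with a vectorized Levenberg-Marquardt scheme. ``G`` is the forward-difference
spatial gradient applied to each parameter map (T1rho and M0), each map
normalized by its masked median magnitude so that ``mu`` stays dimensionless.
With ``mu = 0`` the normal equations are 2x2 block-diagonal and solved in
closed form per pixel; with ``mu > 0`` the pixels couple and the damped
normal equations are solved by conjugate gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse.linalg import LinearOperator, cg

from .signal_model import (
    T1RHO_MAX,
    T1RHO_MIN,
    ParameterMap,
    WeightedSeries,
)

__all__ = [
    "FitConfig",
    "default_fit_mask",
    "init_loglinear",
    "init_robust",
    "fit",
    "objective",
]


@dataclass
class FitConfig:
    """Settings for the Levenberg-Marquardt map fit.

    ``mu`` weights the spatial-smoothness penalty on the parameter maps.
    The damping schedule is multiplicative: ``damping_up`` on a rejected
    step, ``damping_down`` on an accepted one.
    """

    mu: float = 0.01
    max_iter: int = 30
    tol: float = 1e-10
    damping_init: float = 1e-2
    damping_up: float = 10.0
    damping_down: float = 10.0
    bounds: tuple[float, float] = (T1RHO_MIN, T1RHO_MAX)
    cg_tol: float = 1e-10
    cg_maxiter: int = 200
    normalize: bool = True
    # Fixed (t1rho, m0) scales for the gradient penalty; computed from the
    # initial map when None. The outer motion-correction loop pins these so
    # its objective stays well-defined across iterations.
    grad_scales: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def default_fit_mask(series: WeightedSeries, threshold: float = 0.05) -> np.ndarray:
    """Foreground mask: pixels whose first-TSL intensity reaches ``threshold``
    times the series' 95th-percentile intensity. Background (air) pixels carry
    noise only and are excluded from fitting."""
    p95 = float(np.percentile(series.images, 95))
    if p95 <= 0:
        return np.zeros(series.shape, dtype=bool)
    return series.images[0] >= threshold * p95


# ---------------------------------------------------------------------------
# masked forward-difference gradient operator


class _MaskedGradient:
    """Forward differences on a boolean mask (replicate boundary: differences
    are only taken between pairs of masked pixels, everything else is zero).
    Acts on vectors of masked-pixel values."""

    def __init__(self, mask: np.ndarray):
        self.mask = mask
        self.shape = mask.shape
        idx = -np.ones(mask.shape, dtype=np.int64)
        idx[mask] = np.arange(int(mask.sum()))
        self.n = int(mask.sum())
        # vertical pairs (i, i+1) both inside mask
        vy = mask[:-1, :] & mask[1:, :]
        self.y_lo = idx[:-1, :][vy]
        self.y_hi = idx[1:, :][vy]
        vx = mask[:, :-1] & mask[:, 1:]
        self.x_lo = idx[:, :-1][vx]
        self.x_hi = idx[:, 1:][vx]

    def apply(self, v: np.ndarray) -> np.ndarray:
        """G v: stacked [row-diffs; col-diffs]."""
        return np.concatenate([v[self.y_hi] - v[self.y_lo], v[self.x_hi] - v[self.x_lo]])

    def normal(self, v: np.ndarray) -> np.ndarray:
        """G^T G v."""
        out = np.zeros_like(v)
        dy = v[self.y_hi] - v[self.y_lo]
        np.add.at(out, self.y_hi, dy)
        np.add.at(out, self.y_lo, -dy)
        dx = v[self.x_hi] - v[self.x_lo]
        np.add.at(out, self.x_hi, dx)
        np.add.at(out, self.x_lo, -dx)
        return out

    def diag_normal(self) -> np.ndarray:
        """diag(G^T G): number of difference terms touching each pixel."""
        d = np.zeros(self.n)
        for ind in (self.y_lo, self.y_hi, self.x_lo, self.x_hi):
            np.add.at(d, ind, 1.0)
        return d


def _grad_penalty(grad: _MaskedGradient, t: np.ndarray, m: np.ndarray,
                  scales: tuple[float, float]) -> float:
    st, sm = scales
    return float(np.sum(grad.apply(t / st) ** 2) + np.sum(grad.apply(m / sm) ** 2))


def _default_scales(t: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    st = float(np.median(np.abs(t)))
    sm = float(np.median(np.abs(m)))
    return (max(st, 1e-12), max(sm, 1e-12))


# ---------------------------------------------------------------------------
# initialization


def init_loglinear(
    series: WeightedSeries, mask: np.ndarray | None = None
) -> ParameterMap:
    """Per-pixel ordinary least squares of ``log(signal)`` against TSL.

    The slope gives ``-1/T1rho`` and the intercept ``log(M0)``; results are
    clamped to the T1rho bounds. Intensities are floored at a tiny positive
    epsilon before the log; all-zero pixels are dropped from the mask.
    """
    if mask is None:
        mask = default_fit_mask(series)
    mask = np.asarray(mask, dtype=bool)
    mask = mask & (series.images.max(axis=0) > 0)

    y = series.images[:, mask]  # (N, P)
    eps = max(float(series.images.max()), 1.0) * 1e-12
    logy = np.log(np.maximum(y, eps))
    t = series.tsl[:, None]
    tbar = t.mean()
    lbar = logy.mean(axis=0)
    var_t = float(np.sum((t - tbar) ** 2))
    slope = np.sum((t - tbar) * (logy - lbar), axis=0) / var_t
    intercept = lbar - slope * tbar

    t1rho = np.full(slope.shape, T1RHO_MAX)
    decaying = slope < -1.0 / T1RHO_MAX
    t1rho[decaying] = -1.0 / slope[decaying]
    t1rho = np.clip(t1rho, T1RHO_MIN, T1RHO_MAX)
    # a mono-exponential decay never exceeds its t=0 value, so cap the
    # extrapolated intercept at a sane multiple of the observed intensities
    m0 = np.minimum(np.exp(intercept), 2.0 * float(series.images.max()))

    t1rho_map = np.zeros(series.shape)
    m0_map = np.zeros(series.shape)
    t1rho_map[mask] = t1rho
    m0_map[mask] = m0
    return ParameterMap(t1rho_map, m0_map, mask)


def init_robust(
    series: WeightedSeries, mask: np.ndarray | None = None, subset_size: int = 3
) -> ParameterMap:
    """Motion-tolerant initialization: least-median-of-squares log-linear fit.

    For every pixel, a log-linear fit is computed on each ``subset_size``
    combination of TSL samples and scored by the median squared log-residual
    over all samples; the best-scoring subset wins. Samples corrupted by
    inter-image motion (a minority of frames showing displaced tissue)
    produce large residuals and are voted out, so the resulting map reflects
    the consensus motion state and is a usable registration target even
    before any correction. Falls back to :func:`init_loglinear` when there
    are too few samples to form strict subsets.
    """
    from itertools import combinations

    if mask is None:
        mask = default_fit_mask(series)
    mask = np.asarray(mask, dtype=bool)
    mask = mask & (series.images.max(axis=0) > 0)
    n = series.n_tsl
    if subset_size < 2:
        raise ValueError("subset_size must be >= 2")
    if n <= subset_size:
        return init_loglinear(series, mask)

    y = series.images[:, mask]  # (N, P)
    eps = max(float(series.images.max()), 1.0) * 1e-12
    logy = np.log(np.maximum(y, eps))
    t = series.tsl

    best_score = None
    best_slope = None
    best_intercept = None
    for combo in combinations(range(n), subset_size):
        idx = np.asarray(combo)
        tc = t[idx][:, None]
        lc = logy[idx]
        tbar = tc.mean()
        lbar = lc.mean(axis=0)
        slope = np.sum((tc - tbar) * (lc - lbar), axis=0) / np.sum((tc - tbar) ** 2)
        intercept = lbar - slope * tbar
        resid = logy - (intercept[None, :] + slope[None, :] * t[:, None])
        score = np.median(resid**2, axis=0)
        if best_score is None:
            best_score, best_slope, best_intercept = score, slope, intercept
        else:
            better = score < best_score
            best_score = np.where(better, score, best_score)
            best_slope = np.where(better, slope, best_slope)
            best_intercept = np.where(better, intercept, best_intercept)

    t1rho = np.full(best_slope.shape, T1RHO_MAX)
    decaying = best_slope < -1.0 / T1RHO_MAX
    t1rho[decaying] = -1.0 / best_slope[decaying]
    m0 = np.minimum(np.exp(best_intercept), 2.0 * float(series.images.max()))
    # A pixel whose median intensity across frames sits at the background
    # level is background in the consensus frame (only a minority of frames
    # ever shows tissue there); the log-residual vote is meaningless on
    # noise-only samples and would synthesize ghosts along the motion path.
    dark = np.median(y, axis=0) < 0.05 * float(
        np.percentile(series.images, 95)
    )
    m0[dark] = 0.0
    t1rho[dark] = T1RHO_MIN
    t1rho_map = np.zeros(series.shape)
    m0_map = np.zeros(series.shape)
    t1rho_map[mask] = np.clip(t1rho, T1RHO_MIN, T1RHO_MAX)
    m0_map[mask] = m0
    # isolated pixels where the subset vote failed (e.g. noise-only pixels
    # swept by motion) would synthesize bright ghosts that mislead the
    # registration; a median filter removes them without moving edges
    t1rho_map = ndimage.median_filter(t1rho_map, size=3, mode="nearest")
    m0_map = ndimage.median_filter(m0_map, size=3, mode="nearest")
    return ParameterMap(t1rho_map, m0_map, mask)


# ---------------------------------------------------------------------------
# Levenberg-Marquardt fit


def fit(
    series: WeightedSeries,
    mask: np.ndarray | None = None,
    config: FitConfig | None = None,
    init: ParameterMap | None = None,
    return_info: bool = False,
):
    """Fit ``(T1rho, M0)`` maps to a weighted series.

    Minimizes the data misfit plus ``mu`` times the squared masked
    forward-difference gradients of the (scale-normalized) maps. Returns a
    :class:`ParameterMap`; with ``return_info=True`` also a dict carrying the
    per-iteration objective trace.
    """
    config = config or FitConfig()
    if not np.all(np.isfinite(series.images)):
        raise ValueError("series intensities must be finite")
    if mask is None:
        mask = default_fit_mask(series)
    mask = np.asarray(mask, dtype=bool)
    if init is not None:
        mask = mask & init.mask
    if not np.any(mask):
        raise ValueError("empty fit mask: nothing to fit")

    # Normalize intensities so the printed mu is meaningful across scales.
    scale = float(np.percentile(series.images, 95)) if config.normalize else 1.0
    if scale <= 0:
        scale = 1.0
    nseries = WeightedSeries(
        series.images / scale, series.tsl, series.spacing, series.fsl
    )

    if init is None:
        init_map = init_loglinear(nseries, mask)
    else:
        init_map = ParameterMap(init.t1rho, init.m0 / scale, init.mask)
    mask = mask & init_map.mask
    if not np.any(mask):
        raise ValueError("empty fit mask after initialization")

    grad = _MaskedGradient(mask)
    y = nseries.images[:, mask]  # (N, P)
    tsl = nseries.tsl
    lo, hi = config.bounds

    t = np.clip(init_map.t1rho[mask], lo, hi)
    m = np.maximum(init_map.m0[mask], 0.0)
    scales = config.grad_scales or _default_scales(t, m)
    mu = config.mu

    def objective_at(tv, mv):
        f = mv[None, :] * np.exp(-tsl[:, None] / tv[None, :])
        val = float(np.sum((f - y) ** 2))
        if mu > 0:
            val += mu * _grad_penalty(grad, tv, mv, scales)
        return val

    obj = objective_at(t, m)
    trace = [obj]
    nu = config.damping_init
    st, sm = scales
    diag_gtg = grad.diag_normal() if mu > 0 else None

    n_pix = t.size
    for _ in range(config.max_iter):
        e = np.exp(-tsl[:, None] / t[None, :])  # (N, P)
        f = m[None, :] * e
        r = f - y
        jt = f * (tsl[:, None] / t[None, :] ** 2)  # d f / d T1rho
        jm = e  # d f / d M0
        a = np.sum(jt * jt, axis=0)
        b = np.sum(jt * jm, axis=0)
        c = np.sum(jm * jm, axis=0)
        gt = np.sum(jt * r, axis=0)
        gm = np.sum(jm * r, axis=0)
        if mu > 0:
            gt = gt + mu / st**2 * grad.normal(t)
            gm = gm + mu / sm**2 * grad.normal(m)
            diag_t = a + mu / st**2 * diag_gtg
            diag_m = c + mu / sm**2 * diag_gtg
        else:
            diag_t, diag_m = a, c
        diag_t = np.maximum(diag_t, 1e-30)
        diag_m = np.maximum(diag_m, 1e-30)

        accepted = False
        for _trial in range(12):
            if mu == 0:
                # damped 2x2 block solve per pixel
                at = a + nu * diag_t
                ct = c + nu * diag_m
                det = at * ct - b * b
                det = np.where(np.abs(det) < 1e-30, 1e-30, det)
                dt = (-gt * ct + gm * b) / det
                dm = (-gm * at + gt * b) / det
            else:
                def matvec(v, a=a, b=b, c=c, nu=nu):
                    vt, vm = v[:n_pix], v[n_pix:]
                    out_t = a * vt + b * vm + mu / st**2 * grad.normal(vt)
                    out_m = b * vt + c * vm + mu / sm**2 * grad.normal(vm)
                    out_t = out_t + nu * diag_t * vt
                    out_m = out_m + nu * diag_m * vm
                    return np.concatenate([out_t, out_m])

                op = LinearOperator(
                    (2 * n_pix, 2 * n_pix), matvec=matvec, dtype=float
                )
                rhs = -np.concatenate([gt, gm])
                sol, _info = cg(
                    op, rhs, rtol=config.cg_tol, atol=0.0,
                    maxiter=config.cg_maxiter,
                )
                dt, dm = sol[:n_pix], sol[n_pix:]

            t_new = np.clip(t + dt, lo, hi)
            m_new = np.maximum(m + dm, 0.0)
            obj_new = objective_at(t_new, m_new)
            if obj_new <= obj:
                accepted = True
                nu = max(nu / config.damping_down, 1e-14)
                break
            nu *= config.damping_up
        if not accepted:
            break
        drop = obj - obj_new
        t, m, obj = t_new, m_new, obj_new
        trace.append(obj)
        if drop <= config.tol * max(obj, 1e-30):
            break

    t1rho_map = np.zeros(series.shape)
    m0_map = np.zeros(series.shape)
    t1rho_map[mask] = t
    m0_map[mask] = m * scale
    result = ParameterMap(t1rho_map, m0_map, mask)
    if return_info:
        return result, {"objective_trace": trace, "grad_scales": scales,
                        "intensity_scale": scale}
    return result


# ---------------------------------------------------------------------------
# full three-term objective


def objective(
    series: WeightedSeries,
    param_map: ParameterMap,
    fields=None,
    mu: float = 0.0,
    lam: float = 0.0,
    mask: np.ndarray | None = None,
    grad_scales: tuple[float, float] | None = None,
) -> float:
    """The joint objective: data misfit of the model against the (optionally
    warped) series, plus ``mu`` times the map smoothness penalty, plus
    ``lam`` times the summed squared motion-field gradients.

    ``fields`` is a ``MotionFieldSet`` (or None for identity warps). The data
    term is evaluated over ``mask`` (default: the map's mask).
    """
    from .registration import MotionFieldSet, warp  # local: avoid cycle

    if mu < 0 or lam < 0:
        raise ValueError("mu and lam must be >= 0")
    if mask is None:
        mask = param_map.mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != param_map.shape or series.shape != param_map.shape:
        raise ValueError("series, map and mask shapes must agree")

    total = 0.0
    for i, t in enumerate(series.tsl):
        mdl = param_map.m0 * np.exp(
            -t / np.where(param_map.mask, param_map.t1rho, 1.0)
        )
        mdl[~param_map.mask] = 0.0
        img = series.images[i]
        if fields is not None:
            if not isinstance(fields, MotionFieldSet):
                raise TypeError("fields must be a MotionFieldSet or None")
            img = warp(img, fields.fields[i])
        total += float(np.sum(((mdl - img)[mask]) ** 2))

    if mu > 0:
        grad = _MaskedGradient(param_map.mask)
        scales = grad_scales or _default_scales(
            param_map.t1rho[param_map.mask], param_map.m0[param_map.mask]
        )
        total += mu * _grad_penalty(
            grad, param_map.t1rho[param_map.mask],
            param_map.m0[param_map.mask], scales,
        )
    if lam > 0 and fields is not None:
        for f in fields.fields:
            total += lam * f.gradient_energy()
    return total
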