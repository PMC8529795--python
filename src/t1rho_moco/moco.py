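"""Joint map fitting and model-based non-rigid motion correction.

Alternates between (a) estimating per-image displacement fields against
same-contrast images synthesized from the current parameter map and (b)
re-fitting the map on the motion-corrected series, so that registration
never has to compare images of different contrast. Each sub-step is
guaranteed not to increase the joint objective (candidate fields that would
are discarded per image; the fit is warm-started and monotone), so the
objective trace is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fitting import FitConfig, _default_scales, fit, init_robust, objective
from .registration import (
    MotionField,
    MotionFieldSet,
    RegConfig,
    estimate_series_motion,
    warp,
)
from .signal_model import ParameterMap, WeightedSeries, synthesize_series

__all__ = ["MocoConfig", "MocoResult", "run_moco", "convergence_report"]


@dataclass
class MocoConfig:
    """Defaults mirror the validated configuration: mu=0.01, lam=0.008,
    five outer iterations, four pyramid levels."""

    mu: float = 0.01
    lam: float = 0.008
    outer_iter: int = 5
    reg: RegConfig | None = None
    fit: FitConfig | None = None
    early_stop_tol: float = 0.01  # mean |field update| in px
    anchor_to_first: bool = False

    def __post_init__(self) -> None:
        if self.outer_iter < 1:
            raise ValueError("outer_iter must be >= 1")
        if self.reg is None:
            self.reg = RegConfig(lam=self.lam)
        if self.fit is None:
            self.fit = FitConfig(mu=self.mu)


@dataclass
class MocoResult:
    map: ParameterMap
    corrected: WeightedSeries
    fields: MotionFieldSet
    objective_trace: list
    uncorrected_map: ParameterMap
    mean_field_updates: list = field(default_factory=list)
    iterates: list = field(default_factory=list)  # (ParameterMap, MotionFieldSet)


def _union_mask(images: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Foreground over every motion state: union of per-image intensity
    masks, closed and slightly dilated so the swept corridor is covered."""
    p95 = float(np.percentile(images, 95))
    if p95 <= 0:
        raise ValueError("series has no signal")
    m = (images >= threshold * p95).any(axis=0)
    m = ndimage.binary_fill_holes(m)
    return ndimage.binary_dilation(m, iterations=2)


def _data_term(model_img, acquired_img, fld, mask) -> float:
    return float(np.sum(((model_img - warp(acquired_img, fld))[mask]) ** 2))


def run_moco(series: WeightedSeries, config: MocoConfig | None = None) -> MocoResult:
    """Run the full alternating optimization on an acquired series.

    The initial map is fitted on the uncorrected series (identity fields);
    each outer iteration re-estimates all fields against the synthesized
    series, warps the original acquired images, and re-fits the map. Stops
    at ``outer_iter`` or when the mean field update falls below
    ``early_stop_tol`` pixels.
    """
    config = config or MocoConfig()
    scale = float(np.percentile(series.images, 95))
    if scale <= 0:
        raise ValueError("series has no signal")
    nser = WeightedSeries(series.images / scale, series.tsl, series.spacing,
                          series.fsl)
    mask = _union_mask(nser.images)

    fit_cfg = FitConfig(**{**config.fit.__dict__})
    fit_cfg.mu = config.mu
    fit_cfg.normalize = False  # already normalized once, keeps mu consistent

    try:
        un_map = fit(nser, mask, fit_cfg, init=None)
    except Exception as exc:
        raise RuntimeError(f"initial fitting stage failed: {exc}") from exc
    uncorrected_map = ParameterMap(un_map.t1rho, un_map.m0 * scale, un_map.mask)

    # The alternation starts from a motion-tolerant (least-median-of-squares)
    # initialization rather than the uncorrected least-squares map: when a
    # minority of frames is displaced, the plain fit is corrupted at every
    # pixel the motion sweeps over and the synthesized registration targets
    # would mislead the flow estimation.
    pmap = init_robust(nser, mask)
    # Pin the gradient-penalty scales so the objective is fixed across
    # outer iterations.
    scales = _default_scales(pmap.t1rho[pmap.mask], pmap.m0[pmap.mask])
    fit_cfg.grad_scales = scales

    fields = MotionFieldSet.zero(nser.n_tsl, nser.shape, nser.spacing)
    trace = [objective(nser, pmap, fields, config.mu, config.lam, mask, scales)]
    mean_updates: list[float] = []
    iterates: list = []

    corrected = nser
    for _it in range(config.outer_iter):
        synth = synthesize_series(pmap, nser.tsl, nser.spacing, nser.fsl)
        try:
            # Two candidate field sets: one warm-started from the current
            # fields, one re-converged from scratch (escapes warm-start
            # lock-in once the model has improved).
            cand_warm = estimate_series_motion(synth, nser, config.reg,
                                               init=fields)
            cand_cold = estimate_series_motion(synth, nser, config.reg)
        except Exception as exc:
            raise RuntimeError(f"registration stage failed: {exc}") from exc

        # A candidate set is accepted only as a whole, and only if it does
        # not increase the registration part of the objective. All-or-nothing
        # acceptance keeps every image in one common frame (mixing old and
        # new fields would let the consensus frame drift differentially,
        # which pairwise overlap metrics cannot cancel) while still
        # guaranteeing a non-increasing objective trace.
        def reg_val(fset):
            return sum(
                _data_term(synth.images[t], nser.images[t], fset.fields[t], mask)
                + config.lam * fset.fields[t].gradient_energy()
                for t in range(nser.n_tsl)
            )

        # Require a minimal relative improvement: accepting marginal updates
        # would chase noise on an already-aligned series.
        old_val = reg_val(fields)
        best = min((cand_warm, cand_cold), key=reg_val)
        accepted = reg_val(best) <= old_val * (1.0 - 1e-2)
        new_set = best if accepted else fields

        upd = float(np.mean([
            np.mean(np.hypot(nf.dy - of.dy, nf.dx - of.dx))
            for nf, of in zip(new_set.fields, fields.fields)
        ]))
        mean_updates.append(upd)
        fields = new_set

        corrected = WeightedSeries(
            np.stack([warp(nser.images[t], fields.fields[t])
                      for t in range(nser.n_tsl)]),
            nser.tsl, nser.spacing, nser.fsl,
        )
        try:
            pmap = fit(corrected, mask, fit_cfg, init=pmap)
        except Exception as exc:
            raise RuntimeError(f"fitting stage failed: {exc}") from exc
        trace.append(
            objective(nser, pmap, fields, config.mu, config.lam, mask, scales)
        )
        iterates.append((
            ParameterMap(pmap.t1rho, pmap.m0 * scale, pmap.mask),
            fields.copy(),
        ))
        # stop only on a small *accepted* update; a rejected candidate
        # (update 0) means the registration stalled, not that it converged
        if accepted and upd < config.early_stop_tol:
            break

    if config.anchor_to_first:
        fields = _anchor_to_first(series, fields)
        corrected = WeightedSeries(
            np.stack([warp(nser.images[t], fields.fields[t])
                      for t in range(nser.n_tsl)]),
            nser.tsl, nser.spacing, nser.fsl,
        )
        pmap = fit(corrected, mask, fit_cfg, init=pmap)

    final_map = ParameterMap(pmap.t1rho, pmap.m0 * scale, pmap.mask)
    corrected_out = WeightedSeries(
        np.stack([warp(series.images[t], fields.fields[t])
                  for t in range(series.n_tsl)]),
        series.tsl, series.spacing, series.fsl,
    )
    return MocoResult(
        map=final_map,
        corrected=corrected_out,
        fields=fields,
        objective_trace=trace,
        uncorrected_map=uncorrected_map,
        mean_field_updates=mean_updates,
        iterates=iterates,
    )


def _anchor_to_first(series: WeightedSeries, fields: MotionFieldSet) -> MotionFieldSet:
    """Optionally re-anchor the consensus frame to the first image by
    removing the first field's mean (rigid) displacement from every field."""
    oy = float(np.mean(fields.fields[0].dy))
    ox = float(np.mean(fields.fields[0].dx))
    return MotionFieldSet([
        MotionField(f.dy - oy, f.dx - ox, f.spacing) for f in fields.fields
    ])


def convergence_report(result: MocoResult, rois: dict | None = None) -> pd.DataFrame:
    """One row per outer iteration: objective value, mean field update and
    (when ``rois`` maps names to boolean masks) per-ROI mean T1rho."""
    from .metrics import roi_stats

    rows = []
    for i, upd in enumerate(result.mean_field_updates):
        row = {
            "iteration": i + 1,
            "objective": result.objective_trace[i + 1],
            "mean_field_update_px": upd,
        }
        if rois:
            pmap = result.iterates[i][0] if i < len(result.iterates) else result.map
            for name, roi in rois.items():
                row[f"t1rho_mean_{name}"] = roi_stats(pmap, roi).mean
        rows.append(row)
    return pd.DataFrame(rows)
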