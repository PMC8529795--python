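"""Mono-exponential spin-lock relaxation model and weighted-image synthesis.

The signal model is ``S(TSL) = M0 * exp(-TSL / T1rho)``: a two-parameter
decay across the spin-lock duration axis. Synthesis turns a parameter map
(per-pixel ``T1rho`` in ms and ``M0`` in arbitrary units) into the weighted
image expected at a given spin-lock time, which is the bridge between
fitting and model-driven registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "T1RHO_MIN",
    "T1RHO_MAX",
    "WeightedSeries",
    "ParameterMap",
    "synthesize",
    "synthesize_series",
]

#: Clamp bounds for fitted T1rho (ms). Chosen to keep exp() well-conditioned
#: while covering fluid, fat and fixed-tissue values.
T1RHO_MIN = 1.0
T1RHO_MAX = 10_000.0


@dataclass
class WeightedSeries:
    """Stack of co-planar 2D magnitude images, one per spin-lock time.

    Parameters
    ----------
    images : ndarray, shape (N_TSL, H, W)
        Non-negative, finite magnitude intensities (arbitrary units).
    tsl : ndarray, shape (N_TSL,)
        Spin-lock durations in ms, strictly increasing, ``tsl[0] >= 0``.
    spacing : tuple of float
        Pixel size (row, col) in mm.
    fsl : float or None
        Spin-lock pulse frequency in Hz (metadata only).
    """

    images: np.ndarray
    tsl: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    fsl: float | None = 500.0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.tsl = np.asarray(self.tsl, dtype=float)
        if self.images.ndim != 3:
            raise ValueError(
                f"images must be a (N_TSL, H, W) stack, got ndim={self.images.ndim}"
            )
        if self.tsl.ndim != 1 or self.tsl.size < 2:
            raise ValueError("tsl must be a 1D list of at least 2 spin-lock times")
        if self.images.shape[0] != self.tsl.size:
            raise ValueError(
                f"image count {self.images.shape[0]} != number of TSLs {self.tsl.size}"
            )
        if self.tsl[0] < 0 or np.any(np.diff(self.tsl) <= 0):
            raise ValueError("tsl must be strictly increasing with tsl[0] >= 0")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("image intensities must be finite")
        if np.any(self.images < 0):
            raise ValueError("image intensities must be non-negative")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def n_tsl(self) -> int:
        return int(self.tsl.size)

    @property
    def shape(self) -> tuple[int, int]:
        """Grid shape (H, W)."""
        return self.images.shape[1:]

    def copy(self) -> "WeightedSeries":
        return WeightedSeries(
            self.images.copy(), self.tsl.copy(), self.spacing, self.fsl
        )


@dataclass
class ParameterMap:
    """Per-pixel relaxation parameters: ``t1rho`` (ms), ``m0`` (a.u.), mask.

    Within the mask ``t1rho`` is clamped to ``[T1RHO_MIN, T1RHO_MAX]`` and
    ``m0`` is non-negative; outside the mask both maps are zero and the
    pixels are excluded from all statistics.
    """

    t1rho: np.ndarray
    m0: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t1rho = np.asarray(self.t1rho, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.t1rho.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.t1rho.shape == self.m0.shape == self.mask.shape):
            raise ValueError("t1rho, m0 and mask must share one (H, W) shape")
        if self.t1rho.ndim != 2:
            raise ValueError("parameter maps must be 2D")
        if not np.all(np.isfinite(self.t1rho[self.mask])) or not np.all(
            np.isfinite(self.m0[self.mask])
        ):
            raise ValueError("masked parameter values must be finite")
        # Enforce the invariants rather than merely checking them: clamp
        # inside the mask, zero outside.
        inside = self.mask
        self.t1rho = np.where(
            inside, np.clip(self.t1rho, T1RHO_MIN, T1RHO_MAX), 0.0
        )
        self.m0 = np.where(inside, np.maximum(self.m0, 0.0), 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.t1rho.shape

    def copy(self) -> "ParameterMap":
        return ParameterMap(self.t1rho.copy(), self.m0.copy(), self.mask.copy())


def synthesize(param_map: ParameterMap, tsl: float) -> np.ndarray:
    """Model-predicted weighted image ``M0 * exp(-tsl / T1rho)`` at one TSL.

    Pixels outside the map's mask are zero. ``tsl`` is in ms and must be
    non-negative.
    """
    tsl = float(tsl)
    if tsl < 0:
        raise ValueError(f"spin-lock time must be non-negative, got {tsl}")
    out = np.zeros(param_map.shape, dtype=float)
    m = param_map.mask
    if np.any(m):
        out[m] = param_map.m0[m] * np.exp(-tsl / param_map.t1rho[m])
    return out


def synthesize_series(
    param_map: ParameterMap,
    tsl_list,
    spacing: tuple[float, float] = (1.0, 1.0),
    fsl: float | None = 500.0,
) -> WeightedSeries:
    """Synthesize one weighted image per TSL into a :class:`WeightedSeries`.

    Intensities are monotone non-increasing across increasing TSL at every
    masked pixel (pure mono-exponential decay).
    """
    tsl_arr = np.asarray(tsl_list, dtype=float)
    images = np.stack([synthesize(param_map, t) for t in tsl_arr])
    return WeightedSeries(images=images, tsl=tsl_arr, spacing=spacing, fsl=fsl)
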