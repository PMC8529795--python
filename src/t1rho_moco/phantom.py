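"""Digital short-axis moving-heart phantom.

A blood pool inside a myocardial annulus (with an optional lesion sector)
on a zero background, with known per-tissue T1rho/M0 values. Inter-image
motion follows a sinusoid (motion-platform style), a linear drift (failed
breath-hold style) or explicit per-image offsets, optionally with a smooth
non-rigid modulation; noise is added last, per image, from a seeded RNG.
Every downstream module is testable against the returned ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .registration import MotionField, MotionFieldSet
from .signal_model import ParameterMap, WeightedSeries, synthesize

__all__ = [
    "PhantomSpec",
    "Trajectory",
    "default_sample_times",
    "make_phantom",
    "sample_trajectory",
    "generate_series",
]


@dataclass
class PhantomSpec:
    """Geometry, tissue values and noise of the synthetic heart.

    Radii and spacing are in mm; T1rho values in ms; ``noise_sigma`` is
    relative to the myocardial M0. Background is zero signal and excluded
    from the truth mask.
    """

    shape: tuple[int, int] = (160, 160)
    spacing: tuple[float, float] = (1.4, 1.4)
    center: tuple[float, float] | None = None  # pixels; default grid center
    r_endo: float = 25.0
    r_epi: float = 35.0
    blood_radius: float | None = None  # defaults to r_endo
    t1rho_myo: float = 48.8
    t1rho_blood: float = 150.0
    t1rho_lesion: float = 68.4
    m0_myo: float = 800.0
    m0_blood: float = 1000.0
    m0_lesion: float = 800.0
    lesion_start_deg: float = 0.0
    lesion_width_deg: float = 0.0
    lesion_transmurality: float = 1.0
    noise_model: str = "gaussian"
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_endo < self.r_epi):
            raise ValueError("need 0 < r_endo < r_epi")
        if self.blood_radius is None:
            self.blood_radius = self.r_endo
        if self.blood_radius > self.r_endo:
            raise ValueError("blood pool must fit inside the endocardium")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.lesion_width_deg < 0 or self.lesion_width_deg > 360:
            raise ValueError("lesion sector width must be in [0, 360] degrees")
        if not (0 < self.lesion_transmurality <= 1):
            raise ValueError("lesion transmurality must be in (0, 1]")
        for name, val in (
            ("t1rho_myo", self.t1rho_myo),
            ("t1rho_blood", self.t1rho_blood),
            ("t1rho_lesion", self.t1rho_lesion),
        ):
            if not (1.0 <= val <= 10_000.0):
                raise ValueError(f"{name}={val} outside fit bounds")


@dataclass
class Trajectory:
    """Bulk displacement of the heart over the acquisition.

    kinds: ``sinusoid`` d(t) = A sin(2 pi (f/60) t) * direction;
    ``linear_drift`` d(t) = A (t / t_max) * direction;
    ``per_image_offsets`` uses ``offsets_mm`` directly.
    ``warp_scale`` adds a smooth spatially varying modulation of the bulk
    displacement (0 = rigid translation).
    """

    kind: str = "sinusoid"
    amplitude: float = 18.0  # mm
    frequency: float = 15.0  # cycles/min
    direction: tuple[float, float] = (1.0, 0.0)  # (row, col), unit vector
    sample_times: np.ndarray = field(default_factory=lambda: default_sample_times())
    offsets_mm: np.ndarray | None = None
    warp_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoid", "linear_drift", "per_image_offsets"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        d = np.asarray(self.direction, dtype=float)
        nrm = float(np.hypot(*d))
        if nrm == 0:
            raise ValueError("direction must be a nonzero vector")
        self.direction = (d[0] / nrm, d[1] / nrm)
        if self.kind == "per_image_offsets":
            if self.offsets_mm is None:
                raise ValueError("per_image_offsets requires offsets_mm")
            self.offsets_mm = np.asarray(self.offsets_mm, dtype=float)
            if self.offsets_mm.shape != (self.sample_times.size, 2):
                raise ValueError("offsets_mm must have shape (N_TSL, 2)")


def default_sample_times(
    n_images: int = 5, heart_rate_bpm: float = 60.0, rr_per_image: int = 3
) -> np.ndarray:
    """Acquisition times (s) of the single-shot images: one image every
    ``rr_per_image`` heartbeats starting at t=0."""
    rr = 60.0 / heart_rate_bpm
    return np.arange(n_images) * rr_per_image * rr


def make_phantom(spec: PhantomSpec):
    """Build the reference-frame phantom.

    Returns ``(truth_map, masks)`` where ``masks`` holds pairwise-disjoint
    tissue masks (``blood``, ``myocardium`` = remote annulus, ``lesion``,
    ``background``) plus the convenience key ``annulus`` (= myocardium with
    the lesion included; the segmentation used by the evaluation metrics).
    """
    h, w = spec.shape
    cy, cx = spec.center if spec.center is not None else ((h - 1) / 2, (w - 1) / 2)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ry = (yy - cy) * spec.spacing[0]
    rx = (xx - cx) * spec.spacing[1]
    r = np.hypot(ry, rx)

    blood = r <= spec.blood_radius
    annulus = (r > spec.r_endo) & (r <= spec.r_epi)

    lesion = np.zeros(spec.shape, dtype=bool)
    if spec.lesion_width_deg > 0:
        ang = np.degrees(np.arctan2(ry, rx)) % 360.0
        a0 = spec.lesion_start_deg % 360.0
        span = (ang - a0) % 360.0
        r_out = spec.r_endo + spec.lesion_transmurality * (spec.r_epi - spec.r_endo)
        lesion = annulus & (span <= spec.lesion_width_deg) & (r <= r_out)
        if not lesion.any():
            raise ValueError("lesion sector does not intersect the myocardium")

    myocardium = annulus & ~lesion
    background = ~(blood | annulus)

    t1rho = np.zeros(spec.shape)
    m0 = np.zeros(spec.shape)
    t1rho[blood] = spec.t1rho_blood
    m0[blood] = spec.m0_blood
    t1rho[myocardium] = spec.t1rho_myo
    m0[myocardium] = spec.m0_myo
    t1rho[lesion] = spec.t1rho_lesion
    m0[lesion] = spec.m0_lesion
    truth_map = ParameterMap(t1rho, m0, mask=~background)

    masks = {
        "blood": blood,
        "myocardium": myocardium,
        "lesion": lesion,
        "background": background,
        "annulus": annulus,
    }
    return truth_map, masks


def sample_trajectory(traj: Trajectory) -> np.ndarray:
    """Displacement vectors (mm), one (row, col) pair per image."""
    t = traj.sample_times
    d = np.asarray(traj.direction)
    if traj.kind == "sinusoid":
        mag = traj.amplitude * np.sin(2.0 * np.pi * (traj.frequency / 60.0) * t)
    elif traj.kind == "linear_drift":
        t_max = float(t.max())
        mag = traj.amplitude * (t / t_max if t_max > 0 else np.zeros_like(t))
    else:  # per_image_offsets
        return traj.offsets_mm.copy()
    return mag[:, None] * d[None, :]


def _smooth_modulation(shape: tuple[int, int]) -> np.ndarray:
    """Fixed smooth spatial modulation in [0, 1] used by warp_scale."""
    h, w = shape
    yy, xx = np.meshgrid(np.arange(h) / h, np.arange(w) / w, indexing="ij")
    return 0.5 * (1.0 + np.sin(2.0 * np.pi * yy) * np.cos(2.0 * np.pi * xx))


def generate_series(spec: PhantomSpec, tsl_list, traj: Trajectory):
    """Simulate the acquired multi-TSL series with motion and noise.

    Per image t the truth maps are displaced by the trajectory (mm converted
    to pixels via the spacing, nearest-neighbor resampling so tissues stay
    piecewise constant), synthesized at ``tsl_list[t]`` and then corrupted
    by noise from the seeded RNG.

    Returns a dict with keys ``series`` (:class:`WeightedSeries`),
    ``truth_fields`` (:class:`MotionFieldSet`, in the convention that warping
    the acquired image by the field recovers the reference frame),
    ``truth_map`` (:class:`ParameterMap` at the reference frame),
    ``image_masks`` (per-image myocardium annulus, (N, H, W) bool) and
    ``masks`` (reference-frame tissue masks).
    """
    tsl_arr = np.asarray(tsl_list, dtype=float)
    if tsl_arr.size != traj.sample_times.size:
        raise ValueError("tsl_list length must match trajectory sample_times")
    truth_map, masks = make_phantom(spec)
    disp_mm = sample_trajectory(traj)
    disp_px = disp_mm / np.asarray(spec.spacing)[None, :]

    h, w = spec.shape
    cy, cx = spec.center if spec.center is not None else ((h - 1) / 2, (w - 1) / 2)
    margin_px = spec.r_epi / min(spec.spacing)
    for d in disp_px:
        ny, nx = cy + d[0], cx + d[1]
        if (
            ny - margin_px < 0 or ny + margin_px > h - 1
            or nx - margin_px < 0 or nx + margin_px > w - 1
        ):
            raise ValueError(
                f"displacement {d} px moves the heart outside the grid"
            )

    mod = _smooth_modulation(spec.shape) if traj.warp_scale else None
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    rng = np.random.default_rng(spec.seed)
    sigma = spec.noise_sigma * spec.m0_myo

    images = []
    image_masks = []
    truth_fields = []
    annulus = masks["annulus"]
    for i, (tsl, d) in enumerate(zip(tsl_arr, disp_px)):
        dy = np.full(spec.shape, d[0])
        dx = np.full(spec.shape, d[1])
        if mod is not None:
            dy = dy * (1.0 + traj.warp_scale * (mod - 0.5))
            dx = dx * (1.0 + traj.warp_scale * (mod - 0.5))
        moved = (dy.any() or dx.any())
        if moved:
            coords = [yy - dy, xx - dx]
            t1 = ndimage.map_coordinates(truth_map.t1rho, coords, order=0,
                                         mode="constant")
            m0 = ndimage.map_coordinates(truth_map.m0, coords, order=0,
                                         mode="constant")
            msk = ndimage.map_coordinates(truth_map.mask.astype(np.uint8),
                                          coords, order=0, mode="constant")
            frame_map = ParameterMap(t1, m0, msk.astype(bool))
            img_mask = ndimage.map_coordinates(annulus.astype(np.uint8),
                                               coords, order=0,
                                               mode="constant").astype(bool)
        else:
            frame_map = truth_map
            img_mask = annulus
        img = synthesize(frame_map, tsl)
        if sigma > 0:
            if spec.noise_model == "gaussian":
                img = img + rng.normal(0.0, sigma, size=img.shape)
            else:  # rician
                n1 = rng.normal(0.0, sigma, size=img.shape)
                n2 = rng.normal(0.0, sigma, size=img.shape)
                img = np.hypot(img + n1, n2)
        images.append(np.maximum(img, 0.0))
        image_masks.append(img_mask)
        truth_fields.append(MotionField(dy, dx, spec.spacing))

    series = WeightedSeries(
        images=np.stack(images), tsl=tsl_arr, spacing=spec.spacing
    )
    return {
        "series": series,
        "truth_fields": MotionFieldSet(truth_fields),
        "truth_map": truth_map,
        "image_masks": np.stack(image_masks),
        "masks": masks,
    }
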