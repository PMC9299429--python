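"""Intrinsic respiratory motion scoring and projection rejection.

Pipeline, repeated per mouse of interest (MOI):

1. a coarse preview reconstruction from all raw projections;
2. a spherical ROI placed at the MOI's diaphragm is cone-beam projected onto
   every acquired frame and the mean measured intensity inside the projected
   sphere gives the raw curve;
3. the same sphere signal computed on the forward-projected coarse
   reconstruction (the baseline) is subtracted, removing the variation that
   merely reflects gantry rotation;
4. a sliding median filter (radius 4, i.e. 9-sample window) estimates the
   slowly varying part of the residual and is subtracted — a high-pass whose
   output is the motion score;
5. the rejection fraction RF selects exactly ``round(RF * n)`` projections
   by rank on the score.

Because breathing is only a brief deviation, the score of quiescent
projections stays near zero and gasps land in the extreme tail of the score
distribution; the rank-based selection makes rejection sets nested across
increasing RF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .geometry import ScanGeometry
from .projections import ProjectionSet
from .projector import apply_detector_model, forward_project_all, log_transform
from .recon import ReconConfig, iterative_reconstruct
from .volume import Volume

__all__ = ["RoiSphere", "MotionCurve", "RejectionMask", "coarse_reconstruct",
           "sphere_signal_curve", "motion_score", "select_rejections",
           "compute_motion_curve", "gate_mouse", "write_rejection_csv",
           "write_sinogram_map"]


@dataclass(frozen=True)
class RoiSphere:
    center_mm: tuple[float, float, float]
    diameter_mm: float

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("sphere diameter must be > 0")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass
class MotionCurve:
    raw: np.ndarray
    baseline: np.ndarray
    residual: np.ndarray
    smoothed: np.ndarray
    score: np.ndarray

    def __post_init__(self):
        n = len(self.raw)
        for s in (self.baseline, self.residual, self.smoothed, self.score):
            if len(s) != n:
                raise ValueError("all curve stages must have equal length")


@dataclass
class RejectionMask:
    rejected: np.ndarray                # boolean per projection
    rejection_fraction: float
    moi_index: int = 0
    score: np.ndarray | None = None

    def __post_init__(self):
        self.rejected = np.asarray(self.rejected, dtype=bool)

    @property
    def keep(self) -> np.ndarray:
        return ~self.rejected

    @property
    def n_rejected(self) -> int:
        return int(np.count_nonzero(self.rejected))


def coarse_reconstruct(projections: ProjectionSet, geometry: ScanGeometry,
                       config: ReconConfig) -> Volume:
    """Fast unweighted preview reconstruction from all projections."""
    if projections.domain == "intensity":
        frames = log_transform(projections.frames, projections.i0)
    else:
        frames = projections.frames
    vol, _ = iterative_reconstruct(frames, geometry, config)
    return vol


def _sphere_pixel_mask(geometry: ScanGeometry, roi: RoiSphere,
                       angle_index: int) -> np.ndarray:
    """Pixels whose source ray passes within the ROI sphere radius."""
    src = geometry.source_position(angle_index)
    corner, du, dv = geometry.detector_basis(angle_index)
    iu = np.arange(geometry.detector_cols)
    iv = np.arange(geometry.detector_rows)
    pix = (corner[None, None, :]
           + iu[None, :, None] * du[None, None, :]
           + iv[:, None, None] * dv[None, None, :])
    d = pix - src
    d /= np.linalg.norm(d, axis=-1, keepdims=True)
    rel = np.asarray(roi.center_mm) - src
    # distance from the ray line to the sphere center
    cross = np.cross(np.broadcast_to(rel, d.shape), d)
    dist = np.linalg.norm(cross, axis=-1)
    return dist <= roi.radius_mm


def sphere_signal_curve(projections: ProjectionSet | np.ndarray,
                        geometry: ScanGeometry, roi: RoiSphere) -> np.ndarray:
    """Mean frame value inside the cone-beam projected ROI sphere, per angle.

    Raises if at any angle the projected sphere is empty or clipped by the
    detector border (the error names the angle).
    """
    frames = projections.frames if isinstance(projections, ProjectionSet) \
        else np.asarray(projections, dtype=float)
    if frames.shape[0] != geometry.n_angles:
        raise ValueError("frame count does not match geometry angles")
    curve = np.empty(geometry.n_angles)
    for a in range(geometry.n_angles):
        mask = _sphere_pixel_mask(geometry, roi, a)
        if not mask.any():
            raise ValueError(f"ROI sphere projects to no pixel at angle index {a}")
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            raise ValueError(f"ROI sphere projects outside the detector "
                             f"at angle index {a}")
        curve[a] = frames[a][mask].mean()
    return curve


def motion_score(raw: np.ndarray, baseline: np.ndarray,
                 median_radius: int = 4) -> MotionCurve:
    """Baseline subtraction followed by a sliding-median high-pass.

    The median window is ``2 * median_radius + 1`` samples with reflected
    boundaries; the score is ``(raw - baseline) - median(raw - baseline)``.
    """
    raw = np.asarray(raw, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if raw.shape != baseline.shape or raw.ndim != 1:
        raise ValueError("raw and baseline must be equal-length 1-D curves")
    residual = raw - baseline
    smoothed = median_filter(residual, size=2 * median_radius + 1, mode="reflect")
    return MotionCurve(raw=raw, baseline=baseline, residual=residual,
                       smoothed=smoothed, score=residual - smoothed)


def select_rejections(score: np.ndarray, rejection_fraction: float,
                      polarity: str = "lowest", moi_index: int = 0) -> RejectionMask:
    """Reject exactly ``round(RF * n)`` projections by rank on the score.

    ``polarity`` picks which tail counts as motion: ``lowest`` (most negative
    scores first), ``highest``, or ``absolute`` (largest magnitude first).
    Ties break toward the lower projection index.
    """
    score = np.asarray(score, dtype=float)
    n = len(score)
    if not (0.0 <= rejection_fraction < 1.0):
        raise ValueError("rejection fraction must be in [0, 1)")
    if polarity == "lowest":
        key = score
    elif polarity == "highest":
        key = -score
    elif polarity == "absolute":
        key = -np.abs(score)
    else:
        raise ValueError(f"unknown polarity: {polarity!r}")
    k = int(np.floor(rejection_fraction * n + 0.5))
    rejected = np.zeros(n, dtype=bool)
    order = np.argsort(key, kind="stable")
    rejected[order[:k]] = True
    return RejectionMask(rejected, rejection_fraction, moi_index, score=score)


def compute_motion_curve(projections: ProjectionSet, geometry: ScanGeometry,
                         roi: RoiSphere, coarse_config: ReconConfig,
                         median_radius: int = 4) -> MotionCurve:
    """Coarse recon -> sphere curves -> baseline subtraction -> high-pass."""
    if projections.domain != "intensity":
        raise ValueError("gating operates on intensity-domain projections")
    coarse = coarse_reconstruct(projections, geometry, coarse_config)
    simulated = forward_project_all(coarse, geometry)
    baseline_frames = apply_detector_model(np.maximum(simulated, 0.0),
                                           projections.i0)
    raw = sphere_signal_curve(projections, geometry, roi)
    baseline = sphere_signal_curve(baseline_frames, geometry, roi)
    return motion_score(raw, baseline, median_radius)


def gate_mouse(projections: ProjectionSet, geometry: ScanGeometry,
               roi: RoiSphere, rejection_fraction: float,
               coarse_config: ReconConfig, polarity: str = "lowest",
               moi_index: int = 0, median_radius: int = 4) -> RejectionMask:
    """Full intrinsic gating of one mouse of interest."""
    curve = compute_motion_curve(projections, geometry, roi, coarse_config,
                                 median_radius)
    return select_rejections(curve.score, rejection_fraction, polarity,
                             moi_index)


# -- exports ----------------------------------------------------------------


def write_rejection_csv(mask: RejectionMask, path) -> None:
    score = mask.score if mask.score is not None else np.full(len(mask.rejected),
                                                              np.nan)
    with open(path, "w") as fh:
        fh.write("projection_index,score,rejected\n")
        for i, (s, r) in enumerate(zip(score, mask.rejected)):
            fh.write(f"{i},{s:.9g},{int(r)}\n")


def write_sinogram_map(projections: ProjectionSet, mask: RejectionMask,
                       path) -> None:
    """Rejection map: central-row sinogram with rejected angles as red stripes."""
    from PIL import Image

    row = projections.frames[:, projections.frames.shape[1] // 2, :]
    lo, hi = row.min(), row.max()
    gray = np.zeros_like(row) if hi == lo else (row - lo) / (hi - lo)
    rgb = np.repeat((gray[..., None] * 255).astype(np.uint8), 3, axis=-1)
    rgb[mask.rejected, :, 0] = 255
    rgb[mask.rejected, :, 1] //= 3
    rgb[mask.rejected, :, 2] //= 3
    Image.fromarray(rgb).save(path)
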