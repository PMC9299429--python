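"""Weighted-least-squares iterative reconstruction tolerant of missing angles.

The image ``x`` minimizes the weighted squared difference between simulated
and measured pixels, ``sum_kept w * (A x - b)^2``, where ``A`` is the
line-integral forward model, ``b`` the log-transformed measurements and the
per-pixel weight ``w = I / i0`` follows a Poisson-like noise model (the
variance of ``-ln(I/i0)`` is ~ 1/I for Poisson counts, so the inverse
variance is proportional to the measured intensity).  The normal equations
``A' W A x = A' W b`` are solved by plain linear conjugate gradient with a
fixed iteration count (default 30) and zero initialization; masked-out
projections are simply omitted from the sum — no substitution, interpolation
or phase binning of missing angles takes place, which is what makes
arbitrary per-mouse rejection masks possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ScanGeometry
from .projections import ProjectionSet
from .projector import backproject, forward_project_all, log_transform
from .volume import MU_WATER_DEFAULT, Volume

__all__ = ["ReconConfig", "compute_weights", "iterative_reconstruct",
           "reconstruct_gated", "desk_recon_config"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconConfig:
    shape: tuple[int, int, int]
    voxel_size_mm: float = 0.08
    origin_mm: tuple[float, float, float] | None = None
    n_iterations: int = 30
    tol: float | None = None            # optional relative-gradient stop
    mu_water: float = MU_WATER_DEFAULT

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def grid(self) -> Volume:
        origin = self.origin_mm
        if origin is None:
            origin = -0.5 * self.voxel_size_mm * np.asarray(self.shape)
        return Volume.zeros(self.shape, self.voxel_size_mm,
                            np.asarray(origin, dtype=float))

    def coarsened(self, factor: int = 4, n_iterations: int = 5) -> "ReconConfig":
        """Preview-scale config: ``factor``-times coarser voxels, few iterations."""
        shape = tuple(max(s // factor, 2) for s in self.shape)
        return replace(self, shape=shape,
                       voxel_size_mm=self.voxel_size_mm * factor,
                       n_iterations=n_iterations, tol=None)


def desk_recon_config(n_iterations: int = 30, **overrides) -> ReconConfig:
    """Reconstruction grid matching the packaged phantom's field of view."""
    kwargs = dict(shape=(60, 16, 26), voxel_size_mm=1.0,
                  origin_mm=(-30.0, -5.5, -13.0), n_iterations=n_iterations)
    kwargs.update(overrides)
    return ReconConfig(**kwargs)


def compute_weights(intensity_frames: np.ndarray, i0: float,
                    clip_min: float = 1e-6) -> np.ndarray:
    """Per-pixel statistical weights ``w = I / i0``, normalized to max 1."""
    if i0 <= 0:
        raise ValueError("i0 must be > 0")
    I = np.asarray(intensity_frames, dtype=float)
    if np.any(~np.isfinite(I)):
        raise ValueError("non-finite intensities")
    w = np.clip(I, clip_min * i0, None) / i0
    return w / w.max()


def iterative_reconstruct(frames: np.ndarray, geometry: ScanGeometry,
                          config: ReconConfig, weights: np.ndarray | None = None,
                          keep_mask: np.ndarray | None = None,
                          x0: Volume | None = None):
    """Minimize ``sum_kept w * (A x - b)^2`` by linear conjugate gradient.

    ``frames`` must be in the line-integral domain.  Returns
    ``(Volume in attenuation domain, info dict)`` where ``info['cost']`` is
    the cost trace (monotonically nonincreasing) and ``info['n_kept']`` the
    number of projections entering the cost.
    """
    frames = np.asarray(frames, dtype=float)
    n = len(frames)
    if n != geometry.n_angles:
        raise ValueError("frames/geometry angle count mismatch")
    if frames.shape[1:] != (geometry.detector_rows, geometry.detector_cols):
        raise ValueError("frame shape does not match detector geometry")
    if keep_mask is None:
        keep_mask = np.ones(n, dtype=bool)
    keep_mask = np.asarray(keep_mask, dtype=bool)
    kept = np.flatnonzero(keep_mask)
    if kept.size == 0:
        raise ValueError("empty keep set: nothing to reconstruct from")
    b = frames[kept]
    if weights is None:
        w = np.ones_like(b)
    else:
        weights = np.asarray(weights, dtype=float)
        w = weights[kept] if weights.shape == frames.shape else weights
        if w.shape != b.shape:
            raise ValueError("weights shape mismatch")
        if np.any(w < 0) or np.any(~np.isfinite(w)):
            raise ValueError("weights must be finite and >= 0")

    grid = config.grid()
    x = np.array(x0.values, dtype=float) if x0 is not None else np.zeros(grid.shape)
    vol = grid.like(x)

    def A(values: np.ndarray) -> np.ndarray:
        return forward_project_all(grid.like(values), geometry, kept)

    def At(residual: np.ndarray) -> np.ndarray:
        return backproject(residual, kept, geometry, grid).values

    resid = b - A(x)
    cost = float(np.sum(w * resid * resid))
    costs = [cost]
    r = At(w * resid)
    p = r.copy()
    rs = float(np.sum(r * r))
    rs0 = rs
    for _ in range(config.n_iterations):
        if rs == 0.0:
            break
        Ap = A(p)
        q = At(w * Ap)
        pq = float(np.sum(p * q))
        if pq <= 0.0:
            break
        alpha = rs / pq
        x += alpha * p
        # exact CG identity: the WLS cost drops by alpha * r'r per step
        cost = cost - alpha * rs
        costs.append(cost)
        r -= alpha * q
        rs_new = float(np.sum(r * r))
        if config.tol is not None and np.sqrt(rs_new) <= config.tol * np.sqrt(rs0):
            rs = rs_new
            break
        p = r + (rs_new / rs) * p
        rs = rs_new

    vol.values = x
    info = {"cost": np.asarray(costs), "n_kept": int(kept.size),
            "n_rejected": int(n - kept.size)}
    log.info("recon: kept %d/%d projections, final cost %.6g",
             info["n_kept"], n, costs[-1])
    return vol, info


def reconstruct_gated(projections: ProjectionSet, geometry: ScanGeometry,
                      mask, config: ReconConfig):
    """Gated reconstruction from an intensity-domain projection set.

    ``mask`` is a :class:`~mousect.gating.RejectionMask` or a boolean
    rejected-per-projection array.  Kept frames are log-transformed, weighted
    by their binned intensities and reconstructed; returns
    ``(Volume in HU, info)``.
    """
    rejected = np.asarray(getattr(mask, "rejected", mask), dtype=bool)
    if projections.domain != "intensity":
        raise ValueError("reconstruct_gated expects intensity-domain projections")
    keep = ~rejected
    p = log_transform(projections.frames, projections.i0)
    w = compute_weights(projections.frames, projections.i0)
    vol, info = iterative_reconstruct(p, geometry, config, weights=w,
                                      keep_mask=keep)
    return vol.to_hu(config.mu_water), info
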