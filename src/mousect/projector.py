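"""Forward line-integral projection, matched adjoint, and the detector model.

The forward model integrates the attenuation volume along each source-to-pixel
ray with trilinearly interpolated sampling at a fixed step of half a voxel
(scaled by the actual step length), which keeps the operator linear in the
volume.  The backprojector is the exact algebraic transpose of that sampling
operator — the same rays, sample positions and interpolation weights, with
gather replaced by scatter — so the adjoint identity ``<Ax, y> == <x, A'y>``
holds to rounding error by construction.

The detector/beam model converts line integrals ``p`` to measured intensities
``I = i0 * exp(-(c0 + c1*p + c2*p^2))``.  The default coefficients
``(0, 1, 0)`` give monochromatic Beer-Lambert; the quadratic term is a
configurable stand-in for beam hardening of the source spectrum and detector
response, and the model stays a strictly decreasing bijection as long as
``c1 > 0`` and ``c2 >= 0`` on ``p >= 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import ScanGeometry
from .volume import Volume

__all__ = [
    "BeamModel",
    "forward_project",
    "forward_project_all",
    "backproject",
    "apply_detector_model",
    "invert_detector_model",
    "log_transform",
]

log = logging.getLogger(__name__)

#: ray sampling step as a fraction of the voxel size
STEP_FRACTION = 0.5


@njit(cache=True, fastmath=True)
def _ray_entry_exit(sx, sy, sz, rx, ry, rz, L, lox, loy, loz, hix, hiy, hiz):
    """Clip ray ``s + t*r``, t in [0, L], against the volume bounding box."""
    t0, t1 = 0.0, L
    for axis in range(3):
        if axis == 0:
            o, d, lo, hi = sx, rx, lox, hix
        elif axis == 1:
            o, d, lo, hi = sy, ry, loy, hiy
        else:
            o, d, lo, hi = sz, rz, loz, hiz
        if d != 0.0:
            ta = (lo - o) / d
            tb = (hi - o) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
        elif o < lo or o > hi:
            return 1.0, 0.0
    return t0, t1


@njit(cache=True, fastmath=True)
def _forward_kernel(vol, ox, oy, oz, vs, sx, sy, sz,
                    c0x, c0y, c0z, dux, duy, duz, dvx, dvy, dvz,
                    n_u, n_v, step, out):
    nx, ny, nz = vol.shape
    hix, hiy, hiz = ox + nx * vs, oy + ny * vs, oz + nz * vs
    for iv in range(n_v):
        for iu in range(n_u):
            px = c0x + iu * dux + iv * dvx
            py = c0y + iu * duy + iv * dvy
            pz = c0z + iu * duz + iv * dvz
            rx, ry, rz = px - sx, py - sy, pz - sz
            L = np.sqrt(rx * rx + ry * ry + rz * rz)
            rx /= L; ry /= L; rz /= L
            t0, t1 = _ray_entry_exit(sx, sy, sz, rx, ry, rz, L,
                                     ox, oy, oz, hix, hiy, hiz)
            acc = 0.0
            if t1 > t0:
                m = int(np.ceil((t1 - t0) / step))
                h = (t1 - t0) / m
                for k in range(m):
                    t = t0 + (k + 0.5) * h
                    gx = (sx + t * rx - ox) / vs - 0.5
                    gy = (sy + t * ry - oy) / vs - 0.5
                    gz = (sz + t * rz - oz) / vs - 0.5
                    ix = int(np.floor(gx)); iy = int(np.floor(gy)); iz = int(np.floor(gz))
                    fx = gx - ix; fy = gy - iy; fz = gz - iz
                    s = 0.0
                    for cx in range(2):
                        jx = ix + cx
                        if jx < 0 or jx >= nx:
                            continue
                        wx = fx if cx == 1 else 1.0 - fx
                        for cy in range(2):
                            jy = iy + cy
                            if jy < 0 or jy >= ny:
                                continue
                            wxy = wx * (fy if cy == 1 else 1.0 - fy)
                            for cz in range(2):
                                jz = iz + cz
                                if jz < 0 or jz >= nz:
                                    continue
                                s += vol[jx, jy, jz] * wxy * (fz if cz == 1 else 1.0 - fz)
                    acc += s
                acc *= h
            out[iv, iu] = acc


@njit(cache=True, fastmath=True)
def _adjoint_kernel(frame, vol, ox, oy, oz, vs, sx, sy, sz,
                    c0x, c0y, c0z, dux, duy, duz, dvx, dvy, dvz,
                    n_u, n_v, step):
    # Exact transpose of _forward_kernel: identical rays, sample positions and
    # trilinear weights; deposits frame value * weight * step into the volume.
    nx, ny, nz = vol.shape
    hix, hiy, hiz = ox + nx * vs, oy + ny * vs, oz + nz * vs
    for iv in range(n_v):
        for iu in range(n_u):
            val = frame[iv, iu]
            if val == 0.0:
                continue
            px = c0x + iu * dux + iv * dvx
            py = c0y + iu * duy + iv * dvy
            pz = c0z + iu * duz + iv * dvz
            rx, ry, rz = px - sx, py - sy, pz - sz
            L = np.sqrt(rx * rx + ry * ry + rz * rz)
            rx /= L; ry /= L; rz /= L
            t0, t1 = _ray_entry_exit(sx, sy, sz, rx, ry, rz, L,
                                     ox, oy, oz, hix, hiy, hiz)
            if t1 <= t0:
                continue
            m = int(np.ceil((t1 - t0) / step))
            h = (t1 - t0) / m
            dep = val * h
            for k in range(m):
                t = t0 + (k + 0.5) * h
                gx = (sx + t * rx - ox) / vs - 0.5
                gy = (sy + t * ry - oy) / vs - 0.5
                gz = (sz + t * rz - oz) / vs - 0.5
                ix = int(np.floor(gx)); iy = int(np.floor(gy)); iz = int(np.floor(gz))
                fx = gx - ix; fy = gy - iy; fz = gz - iz
                for cx in range(2):
                    jx = ix + cx
                    if jx < 0 or jx >= nx:
                        continue
                    wx = fx if cx == 1 else 1.0 - fx
                    for cy in range(2):
                        jy = iy + cy
                        if jy < 0 or jy >= ny:
                            continue
                        wxy = wx * (fy if cy == 1 else 1.0 - fy)
                        for cz in range(2):
                            jz = iz + cz
                            if jz < 0 or jz >= nz:
                                continue
                            vol[jx, jy, jz] += dep * wxy * (fz if cz == 1 else 1.0 - fz)


def _kernel_args(volume: Volume, geometry: ScanGeometry, angle_index: int):
    src = geometry.source_position(angle_index)
    corner, du, dv = geometry.detector_basis(angle_index)
    o = volume.origin_mm
    return (o[0], o[1], o[2], volume.voxel_size_mm,
            src[0], src[1], src[2],
            corner[0], corner[1], corner[2],
            du[0], du[1], du[2], dv[0], dv[1], dv[2],
            geometry.detector_cols, geometry.detector_rows,
            STEP_FRACTION * volume.voxel_size_mm)


def forward_project(volume: Volume, geometry: ScanGeometry, angle_index: int) -> np.ndarray:
    """Line-integral frame ``(rows, cols)`` of ``volume`` at one gantry angle.

    The volume must be in the attenuation ("mu") domain; rays that miss the
    volume give 0.
    """
    if volume.domain != "mu":
        raise ValueError("forward projection requires an attenuation-domain volume")
    if not np.all(np.isfinite(volume.values)):
        raise ValueError("volume contains non-finite values")
    if not (0 <= angle_index < geometry.n_angles):
        raise IndexError(f"angle index {angle_index} out of range")
    args = _kernel_args(volume, geometry, angle_index)
    out = np.zeros((geometry.detector_rows, geometry.detector_cols))
    _forward_kernel(np.ascontiguousarray(volume.values), *args[:-1], args[-1], out)
    return out


def forward_project_all(volume: Volume, geometry: ScanGeometry,
                        angle_indices=None) -> np.ndarray:
    """Stack of line-integral frames at the given (default: all) angles."""
    if angle_indices is None:
        angle_indices = range(geometry.n_angles)
    return np.stack([forward_project(volume, geometry, i) for i in angle_indices])


def backproject(frames: np.ndarray, angle_indices, geometry: ScanGeometry,
                grid: Volume) -> Volume:
    """Apply the exact transpose of :func:`forward_project`.

    ``frames`` (line-integral or residual domain) are scattered back into a
    volume with the grid (shape, voxel size, origin) of ``grid``.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    angle_indices = list(angle_indices)
    if len(frames) != len(angle_indices):
        raise ValueError("frames and angle indices length mismatch")
    if frames.shape[1:] != (geometry.detector_rows, geometry.detector_cols):
        raise ValueError("frame shape does not match detector geometry")
    vol = np.zeros(grid.shape)
    for frame, idx in zip(frames, angle_indices):
        args = _kernel_args(grid, geometry, idx)
        _adjoint_kernel(np.ascontiguousarray(frame), vol, *args)
    return Volume(vol, grid.voxel_size_mm, grid.origin_mm.copy(), "mu")


# -- detector / beam model -------------------------------------------------

@dataclass(frozen=True)
class BeamModel:
    """Polynomial response ``p' = c0 + c1*p + c2*p**2`` applied before
    Beer-Lambert.  Identity by default (monochromatic beam)."""

    c0: float = 0.0
    c1: float = 1.0
    c2: float = 0.0

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 < 0:
            raise ValueError("require c1 > 0 and c2 >= 0 (strict monotonicity)")

    def apply(self, p):
        p = np.asarray(p, dtype=float)
        return self.c0 + self.c1 * p + self.c2 * p * p

    def invert(self, q):
        q = np.asarray(q, dtype=float)
        if self.c2 == 0.0:
            return (q - self.c0) / self.c1
        disc = self.c1 * self.c1 + 4.0 * self.c2 * (q - self.c0)
        return (-self.c1 + np.sqrt(disc)) / (2.0 * self.c2)


def apply_detector_model(line_integrals, i0: float, beam: BeamModel | None = None):
    """Measured intensities ``I = i0 * exp(-beam(p))`` from line integrals."""
    if i0 <= 0:
        raise ValueError("i0 must be > 0")
    p = np.asarray(line_integrals, dtype=float)
    if np.any(p < 0):
        raise ValueError("line integrals must be >= 0")
    beam = beam or BeamModel()
    return i0 * np.exp(-beam.apply(p))


def invert_detector_model(intensities, i0: float, beam: BeamModel | None = None):
    """Exact inverse of :func:`apply_detector_model` on its stated domain."""
    if i0 <= 0:
        raise ValueError("i0 must be > 0")
    beam = beam or BeamModel()
    I = np.asarray(intensities, dtype=float)
    return beam.invert(-np.log(I / i0))


def log_transform(intensities, i0: float, floor: float = 1e-9):
    """Line integrals ``p = -ln(I / i0)``.

    Non-positive intensities (possible under heavy noise) are clamped at
    ``floor * i0`` with a logged warning.
    """
    if i0 <= 0:
        raise ValueError("i0 must be > 0")
    I = np.asarray(intensities, dtype=float)
    n_bad = int(np.count_nonzero(I <= 0))
    if n_bad:
        log.warning("log transform: clamping %d non-positive intensities", n_bad)
        I = np.maximum(I, floor * i0)
    return -np.log(I / i0)
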