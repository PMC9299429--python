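"""Cone-beam acquisition geometry.

World frame: right-handed, origin at the isocenter, ``z`` along the animal
(craniocaudal) axis.  The gantry rotates in the x-y plane; the gantry angle is
measured counter-clockwise from ``+x``.  At angle ``theta`` the source sits at
``SID * (cos t, sin t, 0)`` and the (flat) detector is centered at
``-(SDD - SID) * (cos t, sin t, 0)``, spanned by the in-plane unit vector
``u = (-sin t, cos t, 0)`` and the axial unit vector ``v = (0, 0, 1)``.
Detector pixel centers are laid out symmetrically around the detector center
plus an optional ``(u, v)`` offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ScanGeometry", "fullscale_geometry", "desk_geometry"]


@dataclass(frozen=True)
class ScanGeometry:
    """Step-and-shoot full-rotation cone-beam scan description.

    Distances are in mm.  Defaults describe the full-resolution acquisition
    (1440 projections of 1944 x 1536 pixels); tests and the packaged phantom
    use the much smaller :func:`desk_geometry`.
    """

    source_isocenter_mm: float = 117.578
    source_detector_mm: float = 297.459
    n_angles: int = 1440
    detector_cols: int = 1944
    detector_rows: int = 1536
    pixel_pitch_mm: float = 0.167
    detector_offset_mm: tuple[float, float] = (0.0, 0.0)
    angles_deg: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if not (self.source_detector_mm > self.source_isocenter_mm > 0):
            raise ValueError("require SDD > SID > 0")
        if self.detector_cols < 1 or self.detector_rows < 1:
            raise ValueError("detector dims must be >= 1")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be > 0")
        if self.angles_deg is None:
            angles = np.arange(self.n_angles, dtype=float) * (360.0 / self.n_angles)
        else:
            angles = np.asarray(self.angles_deg, dtype=float)
            if angles.ndim != 1 or len(angles) != self.n_angles:
                raise ValueError("angles must be 1-D and match n_angles")
            if np.any(np.diff(angles) <= 0):
                raise ValueError("angles must be strictly increasing")
            if angles[0] < 0 or angles[-1] >= 360.0:
                raise ValueError("angles must lie in [0, 360)")
        object.__setattr__(self, "angles_deg", angles)

    # -- derived quantities ------------------------------------------------

    @property
    def magnification(self) -> float:
        return self.source_detector_mm / self.source_isocenter_mm

    def source_position(self, angle_index: int) -> np.ndarray:
        t = np.deg2rad(self.angles_deg[angle_index])
        return np.array([self.source_isocenter_mm * np.cos(t),
                         self.source_isocenter_mm * np.sin(t), 0.0])

    def detector_basis(self, angle_index: int):
        """Return (corner pixel center, du, dv) world vectors for a frame.

        Frames are indexed ``frame[row, col]`` with ``row`` along v (axial)
        and ``col`` along u (transaxial).
        """
        t = np.deg2rad(self.angles_deg[angle_index])
        c, s = np.cos(t), np.sin(t)
        u_hat = np.array([-s, c, 0.0])
        v_hat = np.array([0.0, 0.0, 1.0])
        center = np.array([-(self.source_detector_mm - self.source_isocenter_mm) * c,
                           -(self.source_detector_mm - self.source_isocenter_mm) * s,
                           0.0])
        off_u, off_v = self.detector_offset_mm
        u0 = off_u - (self.detector_cols - 1) / 2.0 * self.pixel_pitch_mm
        v0 = off_v - (self.detector_rows - 1) / 2.0 * self.pixel_pitch_mm
        corner = center + u0 * u_hat + v0 * v_hat
        return corner, self.pixel_pitch_mm * u_hat, self.pixel_pitch_mm * v_hat

    def project_points(self, points: np.ndarray, angle_index: int) -> np.ndarray:
        """Cone-beam projection of world points to detector (u, v) mm.

        ``u``/``v`` are measured from the detector center (before pixel
        offsets).  Points must be on the source side of the detector.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        t = np.deg2rad(self.angles_deg[angle_index])
        w_hat = np.array([np.cos(t), np.sin(t), 0.0])   # iso -> source
        u_hat = np.array([-np.sin(t), np.cos(t), 0.0])
        depth = self.source_isocenter_mm - pts @ w_hat   # source-to-point along w
        if np.any(depth <= 0):
            raise ValueError("point at or behind the source")
        tau = self.source_detector_mm / depth
        u = tau * (pts @ u_hat)
        v = tau * pts[:, 2]
        out = np.stack([u, v], axis=-1)
        return out[0] if np.asarray(points).ndim == 1 else out

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) mm coordinate of every pixel center, detector-center origin."""
        off_u, off_v = self.detector_offset_mm
        u = (np.arange(self.detector_cols) - (self.detector_cols - 1) / 2.0) \
            * self.pixel_pitch_mm + off_u
        v = (np.arange(self.detector_rows) - (self.detector_rows - 1) / 2.0) \
            * self.pixel_pitch_mm + off_v
        return u, v

    def binned(self, factor: int) -> "ScanGeometry":
        """Geometry seen by frames after ``factor x factor`` software binning."""
        if factor < 1:
            raise ValueError("bin factor must be >= 1")
        return replace(
            self,
            detector_cols=self.detector_cols // factor,
            detector_rows=self.detector_rows // factor,
            pixel_pitch_mm=self.pixel_pitch_mm * factor,
        )


def fullscale_geometry(**overrides) -> ScanGeometry:
    """The full-resolution acquisition preset (1440 x 1944 x 1536)."""
    return ScanGeometry(**overrides)


def desk_geometry(n_angles: int = 288, **overrides) -> ScanGeometry:
    """Small-scale preset used by the packaged phantom study and the tests.

    The detector (196 x 116 pixels of 0.87 mm before binning) covers the
    four-mouse bed field of view (in-plane radius ~31.5 mm) with margin at
    the scanner's true magnification SDD/SID ~= 2.53.
    """
    kwargs = dict(
        n_angles=n_angles,
        detector_cols=196,
        detector_rows=116,
        pixel_pitch_mm=0.87,
    )
    kwargs.update(overrides)
    return ScanGeometry(**kwargs)
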