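"""Synthetic multi-mouse breathing phantom.

Emulates the imaging situation this package targets: several anesthetized,
contrast-enhanced tumor-bearing mice lying side by side in a multi-mouse bed
of a cone-beam micro-CT.  Each mouse is a soft-tissue ellipsoid (long axis =
craniocaudal z) containing a hypodense lung compartment cranial of the
diaphragm, a radiodense contrast-enhanced liver caudal of it, and hypodense
liver tumors.  Under inhalation anesthesia respiration consists of short
gasps separated by long quiescent phases; a gasp translates the diaphragm
interface (and the liver contents, tumors included) caudally by up to the
pattern amplitude, each mouse with independent timing.

The module also produces the ground truth an expert rater would provide:
integer 0-10 motion grades per (projection, mouse of interest), where a full
gasp of the MOI itself — or of another mouse whose silhouette overlaps the
MOI's at that gantry angle — grades 10, and motion of a non-overlapping mouse
grades 0.  Grades >= 3 mark projections a rater would discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .geometry import ScanGeometry, desk_geometry
from .projections import ProjectionSet
from .projector import BeamModel, apply_detector_model, forward_project
from .volume import Volume

__all__ = [
    "BreathingPattern",
    "TumorSphere",
    "MouseModel",
    "BedModel",
    "PhantomSpec",
    "NoiseConfig",
    "GroundTruthLabels",
    "sample_breathing_traces",
    "rasterize_phantom",
    "simulate_scan",
    "overlap_matrix",
    "overlap_fractions",
    "own_motion_labels",
    "label_motion",
    "default_phantom",
    "default_breathing",
    "desk_study",
]

AIR_HU = -1000.0


@dataclass(frozen=True)
class BreathingPattern:
    """Gasping-breathing kinematics, in units of projection index.

    ``amplitude_mm`` is the peak caudal diaphragm excursion of a gasp; the
    pulse shape is a raised cosine (sin^2 ramp) over ``gasp_duration``.
    """

    gasp_period: float = 18.0
    gasp_duration: float = 4.0
    amplitude_mm: float = 2.0
    phase_offset: float = 0.0
    timing_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.gasp_duration >= self.gasp_period:
            raise ValueError("gasp duration must be < period")
        if self.amplitude_mm < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class TumorSphere:
    center_mm: tuple[float, float, float]
    diameter_mm: float = 3.0
    hu: float = 60.0


@dataclass(frozen=True)
class MouseModel:
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float] = (4.0, 4.0, 12.0)
    body_hu: float = 40.0
    lung_hu: float = -500.0
    liver_hu: float = 400.0
    diaphragm_z_mm: float = 2.0          # rest-state lung/liver boundary
    lung_length_mm: float = 8.0
    liver_length_mm: float = 8.0
    tumors: tuple[TumorSphere, ...] = ()
    breathing: BreathingPattern = field(default_factory=BreathingPattern)

    @property
    def radius_xy_mm(self) -> float:
        return max(self.semi_axes_mm[0], self.semi_axes_mm[1])


@dataclass(frozen=True)
class BedModel:
    """Homogeneous bed: a cylinder along the row (x) axis."""

    center_yz_mm: tuple[float, float] = (7.0, 0.0)
    radius_mm: float = 3.2
    hu: float = -200.0


@dataclass
class PhantomSpec:
    mice: list[MouseModel]
    bed: BedModel = field(default_factory=BedModel)
    grid_shape: tuple[int, int, int] = (120, 32, 52)
    voxel_size_mm: float = 0.5
    origin_mm: tuple[float, float, float] = (-30.0, -5.5, -13.0)

    def __post_init__(self):
        if len(self.mice) < 1:
            raise ValueError("need at least one mouse")
        lo = np.asarray(self.origin_mm)
        hi = lo + np.asarray(self.grid_shape) * self.voxel_size_mm
        boxes = []
        for m in self.mice:
            c = np.asarray(m.center_mm)
            a = np.asarray(m.semi_axes_mm)
            if np.any(c - a < lo) or np.any(c + a > hi):
                raise ValueError("mouse body extends outside the phantom grid")
            boxes.append((c - a, c + a))
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                if np.all(boxes[i][1] > boxes[j][0]) and np.all(boxes[j][1] > boxes[i][0]):
                    raise ValueError(f"mouse bodies {i} and {j} overlap")

    @property
    def n_mice(self) -> int:
        return len(self.mice)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([m.breathing.amplitude_mm for m in self.mice])

    def grid(self) -> Volume:
        return Volume.zeros(self.grid_shape, self.voxel_size_mm,
                            np.asarray(self.origin_mm), domain="hu")

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        def tumor_d(t):
            return {"center_mm": list(t.center_mm), "diameter_mm": t.diameter_mm,
                    "hu": t.hu}

        def mouse_d(m):
            b = m.breathing
            return {
                "center_mm": list(m.center_mm),
                "semi_axes_mm": list(m.semi_axes_mm),
                "body_hu": m.body_hu, "lung_hu": m.lung_hu, "liver_hu": m.liver_hu,
                "diaphragm_z_mm": m.diaphragm_z_mm,
                "lung_length_mm": m.lung_length_mm,
                "liver_length_mm": m.liver_length_mm,
                "tumors": [tumor_d(t) for t in m.tumors],
                "breathing": {
                    "gasp_period": b.gasp_period, "gasp_duration": b.gasp_duration,
                    "amplitude_mm": b.amplitude_mm, "phase_offset": b.phase_offset,
                    "timing_jitter": b.timing_jitter, "seed": b.seed,
                },
            }

        return {
            "mice": [mouse_d(m) for m in self.mice],
            "bed": {"center_yz_mm": list(self.bed.center_yz_mm),
                    "radius_mm": self.bed.radius_mm, "hu": self.bed.hu},
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "origin_mm": list(self.origin_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        mice = []
        for md in d["mice"]:
            md = dict(md)
            md["center_mm"] = tuple(md["center_mm"])
            md["semi_axes_mm"] = tuple(md["semi_axes_mm"])
            md["tumors"] = tuple(
                TumorSphere(tuple(t["center_mm"]), t["diameter_mm"], t["hu"])
                for t in md.get("tumors", [])
            )
            md["breathing"] = BreathingPattern(**md["breathing"])
            mice.append(MouseModel(**md))
        bed = d.get("bed", {})
        return cls(
            mice=mice,
            bed=BedModel(tuple(bed.get("center_yz_mm", (7.0, 0.0))),
                         bed.get("radius_mm", 3.2), bed.get("hu", -200.0)),
            grid_shape=tuple(d["grid_shape"]),
            voxel_size_mm=d["voxel_size_mm"],
            origin_mm=tuple(d["origin_mm"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class NoiseConfig:
    """Photon noise model: Poisson sampling of detector counts at budget i0."""

    i0: float = 4000.0
    enabled: bool = True
    beam: BeamModel = field(default_factory=BeamModel)


@dataclass
class GroundTruthLabels:
    """Integer 0-10 motion grades, one column per mouse of interest."""

    labels: np.ndarray                  # (n_angles, n_mice) int
    discard_threshold: int = 3

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim == 1:
            self.labels = self.labels[:, None]
        if self.labels.min() < 0 or self.labels.max() > 10:
            raise ValueError("labels must lie in 0..10")

    def discard_mask(self, moi_index: int) -> np.ndarray:
        """Boolean per projection: a rater would discard it for this MOI."""
        return self.labels[:, moi_index] >= self.discard_threshold

    def save_csv(self, path) -> None:
        n, m = self.labels.shape
        with open(path, "w") as fh:
            fh.write("projection_index,mouse_index,label\n")
            for t in range(n):
                for k in range(m):
                    fh.write(f"{t},{k},{self.labels[t, k]}\n")


# ---------------------------------------------------------------------------
# breathing kinematics


def sample_breathing_traces(patterns, n_angles: int, seed: int = 0) -> np.ndarray:
    """Per-mouse caudal diaphragm displacement (mm), shape (n_angles, n_mice).

    A gasp starting at onset ``s`` contributes
    ``amplitude * sin(pi * (t + 0.5 - s) / duration)**2`` at projection ``t``
    for ``0 < t + 0.5 - s < duration`` and 0 elsewhere; onsets are spaced by
    ``gasp_period`` with Gaussian timing jitter.  Identical seeds reproduce
    identical traces.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    traces = np.zeros((n_angles, len(patterns)))
    t = np.arange(n_angles) + 0.5
    for m, pat in enumerate(patterns):
        if pat.gasp_duration >= pat.gasp_period:
            raise ValueError("gasp duration must be < period")
        rng = np.random.default_rng((int(seed), int(pat.seed), m))
        n_gasps = int(np.ceil((n_angles + pat.gasp_period) / pat.gasp_period)) + 1
        onsets = (pat.phase_offset
                  + np.arange(n_gasps) * pat.gasp_period
                  + pat.timing_jitter * rng.standard_normal(n_gasps))
        for s in onsets:
            x = t - s
            sel = (x > 0) & (x < pat.gasp_duration)
            traces[sel, m] = np.maximum(
                traces[sel, m],
                pat.amplitude_mm * np.sin(np.pi * x[sel] / pat.gasp_duration) ** 2,
            )
    return traces


# ---------------------------------------------------------------------------
# rasterization


def rasterize_phantom(spec: PhantomSpec, displacements=None,
                      grid: Volume | None = None) -> Volume:
    """Voxelize the phantom in HU with each mouse's diaphragm shifted caudally.

    ``displacements`` are the (nonnegative) per-mouse trace values in mm; the
    lung/liver interface, the liver span and the tumors of mouse ``m`` are
    translated by ``-displacements[m]`` along z.  Voxel membership is decided
    by the voxel center (inside test), so the operation is deterministic.
    """
    if displacements is None:
        displacements = np.zeros(spec.n_mice)
    displacements = np.asarray(displacements, dtype=float)
    if displacements.shape != (spec.n_mice,):
        raise ValueError("one displacement per mouse required")
    vol = grid if grid is not None else spec.grid()
    xs, ys, zs = vol.voxel_centers()
    values = np.full(vol.shape, AIR_HU)

    bcy, bcz = spec.bed.center_yz_mm
    bed_yz = ((ys[:, None] - bcy) ** 2 + (zs[None, :] - bcz) ** 2
              <= spec.bed.radius_mm ** 2)
    values[:, bed_yz] = spec.bed.hu

    for m, mouse in enumerate(spec.mice):
        dz = -displacements[m]
        cx, cy, cz = mouse.center_mm
        ax, ay, az = mouse.semi_axes_mm
        sx = _axis_slice(xs, cx - ax, cx + ax)
        sy = _axis_slice(ys, cy - ay, cy + ay)
        sz = _axis_slice(zs, cz - az, cz + az)
        X = xs[sx][:, None, None]
        Y = ys[sy][None, :, None]
        Z = zs[sz][None, None, :]
        body = (((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2
                + ((Z - cz) / az) ** 2) <= 1.0
        sub = values[sx, sy, sz]
        sub[body] = mouse.body_hu
        zd = mouse.diaphragm_z_mm + dz
        lung = body & (Z > zd) & (Z <= mouse.diaphragm_z_mm + mouse.lung_length_mm)
        sub[lung] = mouse.lung_hu
        liver = body & (Z > zd - mouse.liver_length_mm) & (Z <= zd)
        sub[liver] = mouse.liver_hu
        for tumor in mouse.tumors:
            tc = np.asarray(tumor.center_mm) + np.array([0.0, 0.0, dz])
            r = tumor.diameter_mm / 2.0
            inside = ((X - tc[0]) ** 2 + (Y - tc[1]) ** 2 + (Z - tc[2]) ** 2
                      <= r ** 2)
            sub[inside & liver] = tumor.hu
        values[sx, sy, sz] = sub

    return Volume(values, vol.voxel_size_mm, vol.origin_mm.copy(), "hu")


def _axis_slice(coords, lo, hi):
    i0 = int(np.searchsorted(coords, lo - 1e-9))
    i1 = int(np.searchsorted(coords, hi + 1e-9))
    return slice(max(i0 - 1, 0), min(i1 + 1, len(coords)))


# ---------------------------------------------------------------------------
# silhouette overlap and ground-truth labels


def overlap_fractions(spec: PhantomSpec, geometry: ScanGeometry) -> np.ndarray:
    """Graded silhouette overlap, (n_angles, n_mice, n_mice) in [0, 1].

    Each mouse is bounded by a cylinder (in-plane radius = max transaxial
    semi-axis, axial extent = body extent) that is cone-beam projected to a
    (u, v) rectangle on the detector.  The entry (a, i, j) is the length of
    the transaxial (u) intersection of the two rectangles divided by the
    narrower silhouette width — 0 for disjoint silhouettes, approaching 1
    when one mouse lies fully in front of or behind the other — and 0 when
    the axial (v) extents do not intersect.  Symmetric, diagonal 1.
    """
    n = geometry.n_angles
    m = spec.n_mice
    sdd = geometry.source_detector_mm
    out = np.zeros((n, m, m))
    for a in range(n):
        t = np.deg2rad(geometry.angles_deg[a])
        w_hat = np.array([np.cos(t), np.sin(t)])       # iso -> source
        u_hat = np.array([-np.sin(t), np.cos(t)])
        src2 = geometry.source_isocenter_mm * w_hat
        boxes = []
        for mouse in spec.mice:
            c = np.asarray(mouse.center_mm)
            r = mouse.radius_xy_mm
            d = c[:2] - src2
            da = -d @ w_hat                            # depth toward detector
            du = d @ u_hat
            dist = np.hypot(da, du)
            if dist <= r or da <= r:
                raise ValueError("mouse touches the source path")
            # exact tangent rays to the bounding circle
            alpha = np.arctan2(du, da)
            beta = np.arcsin(r / dist)
            ulo = sdd * np.tan(alpha - beta)
            uhi = sdd * np.tan(alpha + beta)
            # conservative axial extent (nearest-depth magnification)
            z_lo = c[2] - mouse.semi_axes_mm[2]
            z_hi = c[2] + mouse.semi_axes_mm[2]
            vlo = min(z_lo * sdd / (da - r), z_lo * sdd / (da + r))
            vhi = max(z_hi * sdd / (da - r), z_hi * sdd / (da + r))
            boxes.append((ulo, uhi, vlo, vhi))
        for i in range(m):
            out[a, i, i] = 1.0
            for j in range(i + 1, m):
                bi, bj = boxes[i], boxes[j]
                inter_u = min(bi[1], bj[1]) - max(bi[0], bj[0])
                v_hit = bi[2] < bj[3] and bj[2] < bi[3]
                if inter_u > 0 and v_hit:
                    frac = inter_u / min(bi[1] - bi[0], bj[1] - bj[0])
                    out[a, i, j] = out[a, j, i] = min(frac, 1.0)
    return out


def overlap_matrix(spec: PhantomSpec, geometry: ScanGeometry) -> np.ndarray:
    """Boolean (n_angles, n_mice, n_mice): silhouettes of i and j overlap.

    Thresholded :func:`overlap_fractions`; symmetric with a True diagonal.
    """
    return overlap_fractions(spec, geometry) > 0.0


def own_motion_labels(traces: np.ndarray, amplitudes) -> np.ndarray:
    """Round(10 * |displacement| / own amplitude), half-up; (n_angles, n_mice)."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    rel = np.zeros_like(traces)
    nz = amplitudes > 0
    rel[:, nz] = np.abs(traces[:, nz]) / amplitudes[nz]
    return np.floor(10.0 * rel + 0.5).astype(int)


def label_motion(traces: np.ndarray, overlaps: np.ndarray, moi_index: int,
                 amplitudes) -> np.ndarray:
    """Rater-protocol motion grade of each projection for one MOI.

    ``round(10 * max_m relative_displacement(m) * weight(m))`` where the
    weight is 1 for the MOI itself and the graded silhouette-overlap
    fraction for every other mouse (a boolean overlap matrix is accepted and
    acts as 0/1 weights).  A full gasp of the MOI — or of a mouse fully
    overlapping it — grades 10; weaker motion and slight overlaps are
    devalued proportionally; motion without overlap grades 0.
    """
    n, m = traces.shape
    if not (0 <= moi_index < m):
        raise IndexError("moi_index out of range")
    amplitudes = np.asarray(amplitudes, dtype=float)
    rel = np.zeros_like(traces)
    nz = amplitudes > 0
    rel[:, nz] = np.abs(traces[:, nz]) / amplitudes[nz]
    weight = overlaps[:, :, moi_index].astype(float).copy()
    weight[:, moi_index] = 1.0
    return np.floor(10.0 * np.max(rel * weight, axis=1) + 0.5).astype(int)


# ---------------------------------------------------------------------------
# scan simulation


def simulate_scan(spec: PhantomSpec, geometry: ScanGeometry,
                  traces: np.ndarray, noise: NoiseConfig | None = None,
                  seed: int = 0):
    """Simulate the intensity-domain scan and its ground-truth motion grades.

    Per angle the phantom is rasterized with that projection's displacements,
    forward projected, passed through the detector model and (optionally)
    Poisson sampled.  Returns ``(ProjectionSet, GroundTruthLabels)``.
    """
    noise = noise or NoiseConfig()
    if traces.shape != (geometry.n_angles, spec.n_mice):
        raise ValueError("traces must be (n_angles, n_mice)")
    rng = np.random.default_rng(int(seed))
    mu_water_scale = None  # default HU calibration
    static = rasterize_phantom(spec).to_mu()
    frames = np.empty((geometry.n_angles, geometry.detector_rows,
                       geometry.detector_cols))
    for a in range(geometry.n_angles):
        disp = traces[a]
        if np.any(disp != 0):
            vol = rasterize_phantom(spec, disp).to_mu()
        else:
            vol = static
        p = forward_project(vol, geometry, a)
        I = apply_detector_model(p, noise.i0, noise.beam)
        frames[a] = rng.poisson(I) if noise.enabled else I
    projections = ProjectionSet(frames, geometry.angles_deg.copy(),
                                "intensity", noise.i0)
    overlaps = overlap_fractions(spec, geometry)
    labels = np.stack(
        [label_motion(traces, overlaps, k, spec.amplitudes)
         for k in range(spec.n_mice)], axis=1)
    return projections, GroundTruthLabels(labels)


# ---------------------------------------------------------------------------
# packaged desk-scale study


def default_phantom() -> PhantomSpec:
    """The packaged four-mouse phantom used by the tests and examples.

    Four mice spaced 16 mm apart across the bed; each has an independent
    gasping pattern (period 18 projections, gasp duration 4, amplitude 2 mm).
    Gasps are short relative to the 9-sample median window of the motion
    score, and for an outer mouse the fraction of discard-grade projections
    (own gasps plus overlapped neighbours' gasps) comes out near 0.2.
    """
    mice = []
    phases = [2.0, 6.0, 11.0, 15.0]
    dia_z = [2.0, 1.5, 2.5, 2.0]
    for k, cx in enumerate([-24.0, -8.0, 8.0, 24.0]):
        tumors = (
            TumorSphere((cx + 1.4, -1.0, dia_z[k] - 3.5)),
            TumorSphere((cx - 1.4, -1.0, dia_z[k] - 5.5)),
        )
        mice.append(MouseModel(
            center_mm=(cx, 0.0, 0.0),
            diaphragm_z_mm=dia_z[k],
            tumors=tumors,
            breathing=BreathingPattern(phase_offset=phases[k], seed=k),
        ))
    return PhantomSpec(mice=mice)


def default_breathing(spec: PhantomSpec):
    return [m.breathing for m in spec.mice]


def desk_study(n_angles: int = 288):
    """Bundle of the packaged study conditions (phantom, geometry, noise)."""
    spec = default_phantom()
    return {
        "spec": spec,
        "geometry": desk_geometry(n_angles=n_angles),
        "patterns": default_breathing(spec),
        "noise": NoiseConfig(i0=4000.0),
        "bin_factor": 2,
        "smoothing_sigma_px": 1.34,
        "coarse_factor": 2,
        "coarse_iterations": 14,
    }


def analysis_rois(spec: PhantomSpec, moi_index: int) -> dict:
    """Standard evaluation geometry for one mouse of the packaged phantom.

    Returns the gating ROI sphere at the diaphragm, liver edge/center sample
    spheres, homogeneous-liver ROIs, tumor segmentations, a bed noise region
    and a craniocaudal line profile crossing the cranial liver edge.
    """
    mouse = spec.mice[moi_index]
    cx, cy, _ = mouse.center_mm
    zd = mouse.diaphragm_z_mm
    edge = [(cx + dx, cy + 1.5, zd - 1.2) for dx in (0.0, 1.2, -1.2)]
    center = [(cx, cy + 1.5, zd - 6.0), (cx + 1.2, cy + 1.5, zd - 5.0),
              (cx - 1.2, cy + 1.5, zd - 6.5)]
    return {
        "gating_roi": {"center_mm": (cx, cy, zd), "diameter_mm": 6.0},
        "edge_spheres": [{"center_mm": c, "diameter_mm": 2.0} for c in edge],
        "center_spheres": [{"center_mm": c, "diameter_mm": 2.0} for c in center],
        "liver_spheres": [{"center_mm": c, "diameter_mm": 2.0} for c in center],
        "tumor_spheres": [{"center_mm": t.center_mm, "diameter_mm": t.diameter_mm}
                          for t in mouse.tumors],
        "noise_sphere": {"center_mm": (0.0, spec.bed.center_yz_mm[0],
                                       spec.bed.center_yz_mm[1]),
                         "diameter_mm": 5.5},
        "profile": {
            "a_mm": (cx, cy + 1.5, zd - 6.0),
            "b_mm": (cx, cy + 1.5, zd + 1.2),
            "fit_segment_mm": (0.5, 5.5),
        },
    }
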