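"""Image-quality and gating-evaluation metrics.

Covers the evaluation protocol of a gated multi-mouse liver study: line
profiles across the cranial liver edge with an OLS slope over a stated fit
segment, spherical-ROI means, the liver center-vs-edge hypodensity
difference, liver/tumor contrast-to-noise ratio with the noise taken from a
homogeneous bed region, agreement of algorithmic gating with rater labels,
and the three projection-rejection modes a multi-mouse scan can be run in
(single-mouse, overlap-based, additive/breathing-pad style).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .gating import RejectionMask, RoiSphere, compute_motion_curve, select_rejections
from .recon import ReconConfig, reconstruct_gated
from .volume import Volume

__all__ = ["LineProfile", "ModeComparison", "line_profile_slope", "roi_mean",
           "edge_center_difference", "cnr", "gating_agreement",
           "simulate_rejection_modes", "difference_report", "rf_sweep"]


@dataclass
class LineProfile:
    a_mm: np.ndarray
    b_mm: np.ndarray
    samples: np.ndarray                # HU along the segment
    spacing_mm: float
    fit_segment_mm: tuple[float, float]

    @property
    def positions_mm(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.spacing_mm


@dataclass
class ModeComparison:
    """Used-projection percentages under the three rejection modes."""

    used_single_mouse: float
    used_overlap_based: float
    used_additive: float
    moi_index: int = 0
    n_angles: int | None = None
    per_mouse: dict = field(default_factory=dict)

    def __post_init__(self):
        for v in (self.used_single_mouse, self.used_overlap_based,
                  self.used_additive):
            if not (0.0 <= v <= 100.0):
                raise ValueError("used fractions must be percentages in [0, 100]")


def _sample_profile(volume: Volume, a_mm, b_mm):
    a = np.asarray(a_mm, dtype=float)
    b = np.asarray(b_mm, dtype=float)
    if np.allclose(a, b):
        raise ValueError("profile endpoints must differ")
    length = float(np.linalg.norm(b - a))
    spacing = volume.voxel_size_mm / 2.0
    n = int(np.floor(length / spacing)) + 1
    t = np.linspace(0.0, (n - 1) * spacing, n)
    pts = a[None, :] + np.outer(t / length, b - a)
    # world -> fractional voxel index (cell-centered)
    idx = (pts - volume.origin_mm) / volume.voxel_size_mm - 0.5
    samples = map_coordinates(volume.values, idx.T, order=1, mode="nearest")
    return samples, spacing


def line_profile_slope(volume: Volume, a_mm, b_mm,
                       fit_segment_mm: tuple[float, float]):
    """Trilinear line profile A->B and the OLS slope (HU/mm) over a segment.

    Returns ``(slope, LineProfile)``.  The fit segment is given in mm from
    endpoint A.
    """
    samples, spacing = _sample_profile(volume, a_mm, b_mm)
    t = np.arange(len(samples)) * spacing
    lo, hi = fit_segment_mm
    sel = (t >= lo) & (t <= hi)
    if np.count_nonzero(sel) < 2:
        raise ValueError("fit segment lies outside the profile")
    slope = np.polyfit(t[sel], samples[sel], 1)[0]
    return float(slope), LineProfile(np.asarray(a_mm, float),
                                     np.asarray(b_mm, float), samples,
                                     spacing, tuple(fit_segment_mm))


def _sphere(roi) -> RoiSphere:
    if isinstance(roi, RoiSphere):
        return roi
    if isinstance(roi, dict):
        return RoiSphere(tuple(roi["center_mm"]), float(roi["diameter_mm"]))
    center, diameter = roi
    return RoiSphere(tuple(center), float(diameter))


def roi_mean(volume: Volume, roi) -> float:
    """Mean of voxels whose centers lie inside the sphere."""
    s = _sphere(roi)
    xs, ys, zs = volume.voxel_centers()
    c = np.asarray(s.center_mm)
    d2 = ((xs[:, None, None] - c[0]) ** 2 + (ys[None, :, None] - c[1]) ** 2
          + (zs[None, None, :] - c[2]) ** 2)
    inside = d2 <= s.radius_mm ** 2
    if not inside.any():
        raise ValueError("sphere contains no voxel centers")
    return float(volume.values[inside].mean())


def edge_center_difference(volume: Volume, edge_spheres, center_spheres) -> float:
    """mean(center ROI means) - mean(edge ROI means), in HU."""
    edge = np.mean([roi_mean(volume, s) for s in edge_spheres])
    center = np.mean([roi_mean(volume, s) for s in center_spheres])
    return float(center - edge)


def cnr(volume: Volume, liver_rois, tumor_segments, noise_roi):
    """Liver-vs-tumor contrast and contrast-to-noise ratio.

    ``contrast = mean(liver) - mean(tumor)``; the noise is the sample
    standard deviation inside a homogeneous bed region.  Returns
    ``(contrast, cnr)``.
    """
    s = _sphere(noise_roi)
    xs, ys, zs = volume.voxel_centers()
    c = np.asarray(s.center_mm)
    inside = ((xs[:, None, None] - c[0]) ** 2 + (ys[None, :, None] - c[1]) ** 2
              + (zs[None, None, :] - c[2]) ** 2) <= s.radius_mm ** 2
    if np.count_nonzero(inside) < 2:
        raise ValueError("noise ROI must contain at least 2 voxels")
    noise = float(volume.values[inside].std(ddof=1))
    if noise == 0.0:
        raise ValueError("noise ROI has zero standard deviation")
    liver = np.mean([roi_mean(volume, r) for r in liver_rois])
    tumor = np.mean([roi_mean(volume, r) for r in tumor_segments])
    contrast = float(liver - tumor)
    return contrast, contrast / noise


def gating_agreement(algorithmic_mask, truth_discard, threshold: int = 3):
    """Fraction of projections with matching keep/discard decisions.

    ``truth_discard`` may be integer 0-10 rater labels (discard iff
    ``label >= threshold``) or a boolean discard mask.  Returns a dict with
    the agreement in percent, confusion counts and Cohen's kappa.
    """
    rejected = np.asarray(getattr(algorithmic_mask, "rejected", algorithmic_mask),
                          dtype=bool)
    truth = np.asarray(truth_discard)
    if truth.dtype != bool:
        truth = truth >= threshold
    if truth.shape != rejected.shape:
        raise ValueError("mask and labels must have equal length")
    n = len(truth)
    tp = int(np.sum(rejected & truth))
    tn = int(np.sum(~rejected & ~truth))
    fp = int(np.sum(rejected & ~truth))
    fn = int(np.sum(~rejected & truth))
    agree = (tp + tn) / n
    p_yes = ((tp + fp) / n) * ((tp + fn) / n)
    p_no = ((tn + fn) / n) * ((tn + fp) / n)
    pe = p_yes + p_no
    kappa = (agree - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    return {"agreement_pct": 100.0 * agree, "tp": tp, "tn": tn, "fp": fp,
            "fn": fn, "kappa": kappa}


def simulate_rejection_modes(own_labels: np.ndarray, overlaps: np.ndarray,
                             moi_index: int, threshold: int = 3) -> ModeComparison:
    """Used-projection fractions under the three multi-mouse rejection modes.

    ``own_labels``: integer 0-10 own-motion grades, shape (n_angles, n_mice).
    ``overlaps``: boolean (n_angles, n_mice, n_mice) silhouette overlaps.

    * single_mouse — only the MOI's own motion counts (emulates a
      single-mouse scan);
    * overlap_based — another mouse's motion counts only at angles where it
      overlaps the MOI;
    * additive — any mouse's motion counts (emulates conservative gating
      driven by breathing pads).
    """
    own_labels = np.asarray(own_labels)
    n, m = own_labels.shape
    if overlaps.shape != (n, m, m):
        raise ValueError("overlap matrix does not match the label grid")
    if not (0 <= moi_index < m):
        raise IndexError("moi_index out of range")
    moving = own_labels >= threshold
    single = moving[:, moi_index]
    relevant = overlaps[:, :, moi_index].copy()
    relevant[:, moi_index] = True
    overlap_based = np.any(moving & relevant, axis=1)
    additive = np.any(moving, axis=1)
    used = {
        "single_mouse": 100.0 * np.count_nonzero(~single) / n,
        "overlap_based": 100.0 * np.count_nonzero(~overlap_based) / n,
        "additive": 100.0 * np.count_nonzero(~additive) / n,
    }
    return ModeComparison(used["single_mouse"], used["overlap_based"],
                          used["additive"], moi_index, n)


def difference_report(comparison: ModeComparison) -> dict:
    """Single-mouse vs overlap-based used-fraction differences.

    Absolute difference in percentage points and relative difference in
    percent of the overlap-based fraction, both also rounded to one decimal
    for reporting.
    """
    abs_pp = comparison.used_single_mouse - comparison.used_overlap_based
    rel = 100.0 * abs_pp / comparison.used_overlap_based \
        if comparison.used_overlap_based else 0.0
    return {"absolute_pp": abs_pp, "relative_pct": rel,
            "absolute_pp_rounded": round(abs_pp, 1),
            "relative_pct_rounded": round(rel, 1)}


def rf_sweep(projections, geometry, roi, rf_list, metric_callbacks: dict,
             recon_config: ReconConfig, coarse_config: ReconConfig,
             polarity: str = "lowest", moi_index: int = 0):
    """Gated reconstruction and metrics for a list of rejection fractions.

    The motion score is computed once; each RF only re-ranks it, so the
    rejection sets are nested across the sweep.  ``metric_callbacks`` maps
    column name -> ``f(volume_hu) -> float``.  Returns a list of row dicts.
    """
    curve = compute_motion_curve(projections, geometry, roi, coarse_config)
    rows = []
    for rf in rf_list:
        mask = select_rejections(curve.score, rf, polarity, moi_index)
        vol, info = reconstruct_gated(projections, geometry, mask, recon_config)
        row = {"rf": float(rf), "n_rejected": mask.n_rejected,
               "final_cost": float(info["cost"][-1])}
        for name, cb in metric_callbacks.items():
            row[name] = float(cb(vol))
        rows.append(row)
    return rows


def write_sweep_csv(rows, path) -> None:
    if not rows:
        raise ValueError("empty sweep")
    cols = list(rows[0].keys())
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in rows:
            fh.write(",".join(f"{row[c]:.9g}" for c in cols) + "\n")
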