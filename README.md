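# mousect

Intrinsic respiratory gating and missing-angle-tolerant iterative
reconstruction for **simultaneous multi-mouse cone-beam micro-CT**, with a
synthetic breathing multi-mouse phantom so every stage can be exercised and
validated without scanner data.

## The problem

Liver tumors in contrast-enhanced mouse micro-CT appear as hypodense
structures inside a radiodense liver. Respiratory motion smears the cranial
liver edge into a hypodense gradient and blurs small tumors. Under
inhalation anesthesia mice breathe in a characteristic pattern — short gasps
separated by long quiescent phases — so most projections of a scan are
motion-free. Instead of gated acquisition or breathing pads, the breathing
signal is extracted from the projection data itself and the few gasp
projections are discarded. Because the reconstruction is model-based, the
missing angles are simply omitted, never interpolated or substituted.

In high-throughput settings several mice are scanned at once. A gasp of
*another* mouse only matters at gantry angles where its silhouette overlaps
the mouse of interest (MOI) on the detector, so each mouse gets its own
rejection mask, and multi-mouse scanning costs only a few percent of extra
rejected projections compared with a single-mouse scan.

The package is aimed at preclinical imaging groups and reconstruction
developers who want a transparent, fully testable reference implementation
of this pipeline.

## Method

**Reconstruction.** The image `x` (linear attenuation, 80 µm voxels at
production scale) minimizes the weighted least-squares cost

    C(x) = Σ_kept  w · (A x − b)²

where `A` is a cone-beam line-integral forward projector (trilinear
sampling at half-voxel steps; the backprojector is its exact algebraic
transpose), `b = −ln(I/I₀)` are the log-transformed measurements after
Gaussian smoothing (σ = 1.34 px) and 3×3 software binning, and `w = I/I₀`
is a Poisson-like statistical weight (inverse variance of the log
measurement). The normal equations `AᵀWA x = AᵀW b` are solved by plain
linear conjugate gradient, 30 iterations, zero start.

**Gating (per MOI).** A coarse preview reconstruction is computed from all
raw data; a user-placed sphere at the MOI's diaphragm is projected onto
every frame and the mean intensity inside the projected sphere gives a raw
curve; the same curve computed on the forward-projected preview is
subtracted (removing rotation-induced variation); a sliding median filter
(radius 4, 9-sample window) is subtracted as a high-pass; the *rejection
fraction* RF then discards exactly `round(RF · n)` projections by rank on
this motion score.

**Evaluation.** Liver-edge line-profile slopes (HU/mm), the difference
between liver-center and liver-edge ROI means, liver/tumor contrast-to-noise
ratio (noise from a homogeneous bed region), agreement with projection-wise
rater labels (0–10, discard at ≥ 3), and the three rejection modes of a
multi-mouse scan: single-mouse, overlap-based, and additive
(breathing-pad-style).

## Worked example

The packaged study: four tumor-bearing mice side by side, 288 projections,
independent gasping (period 18 projections, 2 mm diaphragm excursion),
Poisson noise at I₀ = 4000 counts.

```python
import numpy as np
from mousect import (analysis_rois, desk_study, gate_mouse, gating_agreement,
                     preprocess_projections, reconstruct_gated, RoiSphere,
                     sample_breathing_traces, simulate_scan, cnr,
                     line_profile_slope, edge_center_difference)
from mousect.recon import desk_recon_config

study = desk_study()
spec, geom = study["spec"], study["geometry"]
traces = sample_breathing_traces(study["patterns"], geom.n_angles, seed=1)
projections, labels = simulate_scan(spec, geom, traces, study["noise"], seed=1)
binned, bgeom = preprocess_projections(projections, geom, 1.34, 2)

rois = analysis_rois(spec, moi_index=0)
roi = RoiSphere(rois["gating_roi"]["center_mm"], rois["gating_roi"]["diameter_mm"])
coarse = desk_recon_config().coarsened(study["coarse_factor"],
                                       study["coarse_iterations"])
mask = gate_mouse(binned, bgeom, roi, rejection_fraction=0.2,
                  coarse_config=coarse, polarity="highest", moi_index=0)
print(gating_agreement(mask, labels.labels[:, 0])["agreement_pct"])

config = desk_recon_config(n_iterations=30)
ungated, _ = reconstruct_gated(binned, bgeom, np.zeros(geom.n_angles, bool), config)
gated, _ = reconstruct_gated(binned, bgeom, mask, config)
for name, vol in [("ungated", ungated), ("gated", gated)]:
    slope, _ = line_profile_slope(vol, rois["profile"]["a_mm"],
                                  rois["profile"]["b_mm"],
                                  rois["profile"]["fit_segment_mm"])
    diff = edge_center_difference(vol, rois["edge_spheres"], rois["center_spheres"])
    contrast, ratio = cnr(vol, rois["liver_spheres"], rois["tumor_spheres"],
                          rois["noise_sphere"])
    print(f"{name}: slope {slope:.1f} HU/mm, center-edge {diff:.1f} HU, CNR {ratio:.2f}")
```

Output of this run:

```
95.83333333333334
ungated: slope -47.1 HU/mm, center-edge 160.3 HU, CNR 3.29
gated: slope -18.9 HU/mm, center-edge 49.9 HU, CNR 3.50
```

Reading: without gating, lung contributions from gasp projections darken the
cranial liver edge — a steep negative profile slope and a 160 HU
center-vs-edge hypodensity. Rejecting the 20 % of projections the intrinsic
motion score ranks as breathing flattens the edge (slope −18.9 HU/mm),
shrinks the hypodensity to 50 HU, raises the liver/tumor CNR, and reproduces
95.8 % of the rater's per-projection keep/discard decisions.

The same workflow is available from the shell:

```bash
mousect simulate --seed 1 --out runs/sim
mousect gate --scan runs/sim --roi -24,0,2,6 --rf 0.2 --polarity highest --out runs/gate
mousect reconstruct --scan runs/sim --mask runs/gate/mask.csv --iters 30 --out runs/recon
mousect evaluate --scan runs/sim --volume runs/recon/volume.mhd \
                 --mask runs/gate/mask.csv --out runs/eval
```

## Layout

| module | contents |
| --- | --- |
| `mousect.geometry` | cone-beam scan geometry, full-scale and desk presets |
| `mousect.volume` | attenuation/HU volumes, MetaImage + NIfTI I/O |
| `mousect.projections` | angle-indexed frame stacks, TIFF + JSON sidecar I/O |
| `mousect.projector` | forward projector, matched adjoint, detector/beam model |
| `mousect.phantom` | breathing multi-mouse phantom, overlap + rater labels |
| `mousect.preprocess` | Gaussian smoothing + software binning |
| `mousect.gating` | motion score, rejection selection, mask exports |
| `mousect.recon` | weighted-least-squares conjugate-gradient reconstruction |
| `mousect.metrics` | profiles, ROI stats, CNR, agreement, rejection modes |
| `mousect.cli` | `mousect simulate / gate / reconstruct / evaluate / sweep / report` |

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
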