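"""Angle-indexed stacks of detector frames and their disk format.

A :class:`ProjectionSet` lives either in the intensity domain (detector
counts, unattenuated value ``i0``) or the line-integral domain
(``p = -ln(I / i0)``).  On disk a set is a multi-page TIFF (one page per
angle) plus a JSON sidecar with angles, domain, ``i0`` and the geometry.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import ScanGeometry

__all__ = ["ProjectionSet"]


@dataclass
class ProjectionSet:
    frames: np.ndarray                  # (n_angles, n_rows, n_cols)
    angles_deg: np.ndarray
    domain: str = "intensity"           # "intensity" | "line_integral"
    i0: float = 1.0
    keep_mask: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_angles, rows, cols)")
        if len(self.frames) != len(self.angles_deg):
            raise ValueError("frames and angles length mismatch")
        if self.domain not in ("intensity", "line_integral"):
            raise ValueError("domain must be 'intensity' or 'line_integral'")
        if self.i0 <= 0:
            raise ValueError("i0 must be > 0")
        if self.keep_mask is not None:
            self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
            if self.keep_mask.shape != (len(self.frames),):
                raise ValueError("keep_mask must be one boolean per frame")

    @property
    def n_angles(self) -> int:
        return len(self.frames)

    def save(self, path) -> None:
        """Write ``<path>.tif`` and ``<path>.json``."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path.with_suffix(".tif"),
                         self.frames.astype(np.float32), photometric="minisblack")
        meta = {
            "angles_deg": self.angles_deg.tolist(),
            "domain": self.domain,
            "i0": self.i0,
            "keep_mask": None if self.keep_mask is None else self.keep_mask.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "ProjectionSet":
        import tifffile

        path = Path(path)
        frames = np.asarray(tifffile.imread(path.with_suffix(".tif")), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        meta = json.loads(path.with_suffix(".json").read_text())
        keep = meta.get("keep_mask")
        return cls(frames, np.asarray(meta["angles_deg"]), meta["domain"],
                   float(meta["i0"]), None if keep is None else np.asarray(keep))


def geometry_to_dict(geometry: ScanGeometry) -> dict:
    d = dataclasses.asdict(geometry)
    d["angles_deg"] = geometry.angles_deg.tolist()
    return d


def geometry_from_dict(d: dict) -> ScanGeometry:
    d = dict(d)
    if d.get("angles_deg") is not None:
        d["angles_deg"] = np.asarray(d["angles_deg"], dtype=float)
    if "detector_offset_mm" in d:
        d["detector_offset_mm"] = tuple(d["detector_offset_mm"])
    return ScanGeometry(**d)
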