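"""3-D image volumes and their on-disk formats (MetaImage, NIfTI).

Voxels are cell-centered: voxel ``(i, j, k)`` sits at world position
``origin + (index + 0.5) * voxel_size``.  Arrays are indexed ``(x, y, z)``.
A volume stores either linear attenuation ("mu", 1/mm) or Hounsfield units
("hu"); the two are related by the affine calibration
``HU = 1000 * (mu - mu_water) / mu_water``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "MU_WATER_DEFAULT", "hu_to_mu", "mu_to_hu"]

#: Effective linear attenuation of water (1/mm) at the tube spectrum used for
#: HU calibration; configurable wherever a conversion happens.
MU_WATER_DEFAULT = 0.02


def hu_to_mu(hu, mu_water: float = MU_WATER_DEFAULT):
    return mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0)


def mu_to_hu(mu, mu_water: float = MU_WATER_DEFAULT):
    return 1000.0 * (np.asarray(mu, dtype=float) - mu_water) / mu_water


@dataclass
class Volume:
    values: np.ndarray                      # (nx, ny, nz)
    voxel_size_mm: float = 0.08
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    domain: str = "mu"                      # "mu" (1/mm) or "hu"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D (nx, ny, nz)")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be > 0")
        if self.domain not in ("mu", "hu"):
            raise ValueError("domain must be 'mu' or 'hu'")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self):
        """1-D world coordinates of voxel centers along each axis."""
        return tuple(
            self.origin_mm[a] + (np.arange(self.shape[a]) + 0.5) * self.voxel_size_mm
            for a in range(3)
        )

    def to_mu(self, mu_water: float = MU_WATER_DEFAULT) -> "Volume":
        if self.domain == "mu":
            return self
        return Volume(hu_to_mu(self.values, mu_water), self.voxel_size_mm,
                      self.origin_mm.copy(), "mu")

    def to_hu(self, mu_water: float = MU_WATER_DEFAULT) -> "Volume":
        if self.domain == "hu":
            return self
        return Volume(mu_to_hu(self.values, mu_water), self.voxel_size_mm,
                      self.origin_mm.copy(), "hu")

    @classmethod
    def zeros(cls, shape, voxel_size_mm, origin_mm=None, domain="mu") -> "Volume":
        if origin_mm is None:
            # grid centered on the isocenter
            origin_mm = -0.5 * voxel_size_mm * np.asarray(shape, dtype=float)
        return cls(np.zeros(shape), voxel_size_mm, origin_mm, domain)

    def like(self, values: np.ndarray) -> "Volume":
        return Volume(values, self.voxel_size_mm, self.origin_mm.copy(), self.domain)

    # -- I/O ---------------------------------------------------------------

    def save(self, path) -> None:
        path = str(path)
        if path.endswith((".mhd", ".mha")):
            import SimpleITK as sitk
            img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.T))
            img.SetSpacing((self.voxel_size_mm,) * 3)
            img.SetOrigin(tuple(self.origin_mm + 0.5 * self.voxel_size_mm))
            sitk.WriteImage(img, path)
        elif path.endswith((".nii", ".nii.gz")):
            import nibabel as nib
            affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
            affine[:3, 3] = self.origin_mm + 0.5 * self.voxel_size_mm
            nib.save(nib.Nifti1Image(self.values, affine), path)
        else:
            raise ValueError(f"unsupported volume format: {path}")

    @classmethod
    def load(cls, path, domain="mu") -> "Volume":
        path = str(path)
        if path.endswith((".mhd", ".mha")):
            import SimpleITK as sitk
            img = sitk.ReadImage(path)
            values = sitk.GetArrayFromImage(img).T
            voxel = float(img.GetSpacing()[0])
            origin = np.asarray(img.GetOrigin()) - 0.5 * voxel
        elif path.endswith((".nii", ".nii.gz")):
            import nibabel as nib
            img = nib.load(path)
            values = np.asarray(img.dataobj, dtype=float)
            voxel = float(img.affine[0, 0])
            origin = img.affine[:3, 3] - 0.5 * voxel
        else:
            raise ValueError(f"unsupported volume format: {path}")
        return cls(values, voxel, origin, domain)
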