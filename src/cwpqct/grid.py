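"""Volumetric CT container and NIfTI I/O.

A :class:`VolumeGrid` bundles a 3-D Hounsfield-unit array with its voxel
spacing (mm) and the masks downstream stages need: lung, airway, vessel and
an optional integer ground-truth label grid (phantoms only).  Axes are
(x, y, z) with x = patient-left, y = anterior, z = superior, so "most
superior" means the largest z index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

# Ground-truth label codes used by the phantom generator.
LABEL_OUTSIDE = 0
LABEL_LUMEN = 1
LABEL_WALL = 2
LABEL_VESSEL = 3
LABEL_PARENCHYMA_BASE = 10  # parenchymal class k -> 10 + k


@dataclass
class VolumeGrid:
    """A 3-D HU volume with spacing, masks and optional ground-truth labels."""

    hu: np.ndarray
    spacing: tuple[float, float, float]
    lung_mask: np.ndarray | None = None
    airway_mask: np.ndarray | None = None
    vessel_mask: np.ndarray | None = None
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float32)
        if self.hu.ndim != 3:
            raise ValueError(f"HU array must be 3-D, got shape {self.hu.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU values must be finite")
        for name in ("lung_mask", "airway_mask", "vessel_mask"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != self.hu.shape:
                    raise ValueError(f"{name} shape {m.shape} != HU shape {self.hu.shape}")
                setattr(self, name, m)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int16)
            if self.labels.shape != self.hu.shape:
                raise ValueError("label grid shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def coords_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (possibly fractional) to mm coordinates."""
        return np.asarray(ijk, dtype=float) * np.asarray(self.spacing)

    # ------------------------------------------------------------------ I/O
    def _affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        return aff

    def save(self, stem: str | Path) -> None:
        """Write HU and any masks as NIfTI files ``<stem>_hu.nii.gz`` etc."""
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        aff = self._affine()
        nib.save(nib.Nifti1Image(self.hu.astype(np.float32), aff), f"{stem}_hu.nii.gz")
        for name, arr in (
            ("lung", self.lung_mask),
            ("airway", self.airway_mask),
            ("vessel", self.vessel_mask),
        ):
            if arr is not None:
                nib.save(nib.Nifti1Image(arr.astype(np.uint8), aff), f"{stem}_{name}.nii.gz")
        if self.labels is not None:
            nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff), f"{stem}_labels.nii.gz")

    @classmethod
    def load(cls, hu_path: str | Path, lung_mask: str | Path | None = None,
             airway_mask: str | Path | None = None, vessel_mask: str | Path | None = None,
             labels: str | Path | None = None) -> "VolumeGrid":
        img = nib.load(str(hu_path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])

        def _read_mask(p):
            if p is None:
                return None
            return np.asanyarray(nib.load(str(p)).dataobj) > 0

        lab = None
        if labels is not None:
            lab = np.asanyarray(nib.load(str(labels)).dataobj).astype(np.int16)
        return cls(
            hu=np.asanyarray(img.dataobj).astype(np.float32),
            spacing=spacing,
            lung_mask=_read_mask(lung_mask),
            airway_mask=_read_mask(airway_mask),
            vessel_mask=_read_mask(vessel_mask),
            labels=lab,
        )


def resample_isotropic(volume: VolumeGrid, target: float | None = None) -> VolumeGrid:
    """Resample an anisotropic volume to isotropic spacing.

    HU are interpolated linearly; masks and labels by nearest neighbour.
    ``target`` defaults to the minimum in-plane spacing, appropriate for
    thick-slice acquisitions where the z spacing is the coarse axis.
    """
    from scipy import ndimage

    sp = np.asarray(volume.spacing)
    if target is None:
        target = float(min(sp[0], sp[1]))
    if np.allclose(sp, target):
        return volume
    zoom = sp / target
    hu = ndimage.zoom(volume.hu, zoom, order=1, mode="nearest")

    def _zoom_mask(m):
        if m is None:
            return None
        out = ndimage.zoom(m.astype(np.uint8), zoom, order=0, mode="nearest")
        return out.astype(bool)

    lab = None
    if volume.labels is not None:
        lab = ndimage.zoom(volume.labels, zoom, order=0, mode="nearest")
    return VolumeGrid(
        hu=hu,
        spacing=(target, target, target),
        lung_mask=_zoom_mask(volume.lung_mask),
        airway_mask=_zoom_mask(volume.airway_mask),
        vessel_mask=_zoom_mask(volume.vessel_mask),
        labels=lab,
        meta=dict(volume.meta, resampled_from=tuple(sp)),
    )
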