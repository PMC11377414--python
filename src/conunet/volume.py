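"""Volume container and standard-format I/O (NIfTI primary, DICOM read-only),
plus the preprocessing chain: resample in-plane to 512 x 512 at 1 mm, then
center-crop to 288 x 288 with recorded offsets so predictions can be mapped
back to the full grid."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["Volume", "load_volume", "save_volume", "resample_to_reference",
           "center_crop", "uncrop"]

MODALITIES = ("CT", "PET", "mask")


@dataclass
class Volume:
    """A 3-D scalar grid with voxel spacing and a modality tag.

    ``voxels`` is indexed (slice, row, col); ``spacing`` is mm per voxel on
    the same axes.  ``crop_offset`` records the (row, col) origin of a crop
    within its parent grid (None for uncropped volumes).
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    modality: str = "CT"
    affine: np.ndarray | None = None
    crop_offset: tuple | None = None
    parent_shape: tuple | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a (slices, rows, cols) array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.modality == "mask" and not np.isin(self.voxels, (0, 1)).all():
            raise ValueError("mask volumes must be binary")
        if self.affine is None:
            self.affine = np.diag([self.spacing[2], self.spacing[1],
                                   self.spacing[0], 1.0])


def save_volume(volume: Volume, path) -> None:
    """Write NIfTI; the modality tag goes into the header description."""
    path = Path(path)
    data = np.asarray(volume.voxels).transpose(2, 1, 0)  # (x, y, z) on disk
    img = nib.Nifti1Image(data.astype(np.float32), volume.affine)
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    img.header["descrip"] = f"modality={volume.modality}".encode()
    nib.save(img, str(path))


def _load_nifti(path: Path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    descrip = bytes(img.header["descrip"].tobytes()).decode(errors="ignore")
    modality = "CT"
    for m in MODALITIES:
        if f"modality={m}" in descrip:
            modality = m
            break
    else:
        vals = np.unique(data)
        if len(vals) <= 2 and np.isin(vals, (0, 1)).all():
            modality = "mask"
    if modality == "mask":
        data = np.rint(data).astype(np.uint8)
    return Volume(voxels=data, spacing=spacing, modality=modality,
                  affine=np.asarray(img.affine))


def _load_dicom_series(path: Path) -> Volume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(path))
    if not files:
        raise ValueError(f"no DICOM series found in {path}")
    reader.SetFileNames(files)
    img = reader.Execute()
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    sx, sy, sz = img.GetSpacing()
    return Volume(voxels=data.astype(np.float32),
                  spacing=(float(sz), float(sy), float(sx)), modality="CT")


def load_volume(path) -> Volume:
    """Read a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return _load_dicom_series(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _load_nifti(path)


def resample_to_reference(v: Volume, spacing_mm: float = 1.0,
                          plane_size: int = 512) -> Volume:
    """In-plane resample to `spacing_mm` and pad/crop to `plane_size`.

    The slice axis is preserved.  Interpolation is linear for intensities and
    nearest-neighbor for masks (so masks stay binary); physical extent is
    preserved by the zoom, then the grid is symmetrically cropped or
    zero-padded to the target size.
    """
    order = 0 if v.modality == "mask" else 1
    zr = v.spacing[1] / spacing_mm
    zc = v.spacing[2] / spacing_mm
    if np.isclose(zr, 1.0) and np.isclose(zc, 1.0):
        resampled = v.voxels.copy()
    else:
        resampled = ndimage.zoom(v.voxels, (1.0, zr, zc), order=order,
                                 grid_mode=True, mode="grid-constant")
    out = np.zeros((resampled.shape[0], plane_size, plane_size),
                   dtype=resampled.dtype)
    h, w = resampled.shape[1:]
    src_r = slice(max(0, (h - plane_size) // 2), max(0, (h - plane_size) // 2) + min(h, plane_size))
    src_c = slice(max(0, (w - plane_size) // 2), max(0, (w - plane_size) // 2) + min(w, plane_size))
    dst_r = slice(max(0, (plane_size - h) // 2), max(0, (plane_size - h) // 2) + min(h, plane_size))
    dst_c = slice(max(0, (plane_size - w) // 2), max(0, (plane_size - w) // 2) + min(w, plane_size))
    out[:, dst_r, dst_c] = resampled[:, src_r, src_c]
    if v.modality == "mask":
        out = np.rint(out).astype(np.uint8)
    return Volume(voxels=out, spacing=(v.spacing[0], spacing_mm, spacing_mm),
                  modality=v.modality)


def center_crop(v: Volume, size: int = 288) -> Volume:
    """Central size x size window per slice; offsets recorded for un-cropping."""
    _, h, w = v.voxels.shape
    if h < size or w < size:
        raise ValueError(f"plane {(h, w)} smaller than crop size {size}")
    top, left = (h - size) // 2, (w - size) // 2
    return Volume(voxels=v.voxels[:, top:top + size, left:left + size].copy(),
                  spacing=v.spacing, modality=v.modality,
                  crop_offset=(top, left), parent_shape=(h, w))


def uncrop(v: Volume, fill: float = 0.0) -> Volume:
    """Embed a cropped volume back into its parent grid (zero-padded)."""
    if v.crop_offset is None or v.parent_shape is None:
        return v
    top, left = v.crop_offset
    h, w = v.parent_shape
    out = np.full((v.voxels.shape[0], h, w), fill, dtype=v.voxels.dtype)
    out[:, top:top + v.voxels.shape[1], left:left + v.voxels.shape[2]] = v.voxels
    return Volume(voxels=out, spacing=v.spacing, modality=v.modality)
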