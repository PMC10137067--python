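"""Volumes of interest: grids, resampling, peritumoral dilation, discretization.

A VOI is a boolean voxel mask on the same grid as its image volume.  Four
view types are analysed per lesion: tumor and 10 mm peritumoral shell, each
in the arterial and portal venous contrast phase.  All physical distances
are in millimetres; voxel indices are 0-based (z, y, x) array order with
``spacing`` giving the physical edge lengths per axis.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

VIEW_TYPES = ("type1", "type2", "type3", "type4")
#: type1 = tumor/arterial, type2 = tumor/venous,
#: type3 = peritumor/arterial, type4 = peritumor/venous
VIEW_ANNOTATIONS = {
    "type1": {"phase": "artery", "region": "tumor"},
    "type2": {"phase": "venous", "region": "tumor"},
    "type3": {"phase": "artery", "region": "peritumor"},
    "type4": {"phase": "venous", "region": "peritumor"},
}


class GridError(ValueError):
    """Raised for degenerate spacings or mismatched grids."""


class MaskError(ValueError):
    """Raised when an operation requires a non-empty mask."""


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    values : (nz, ny, nx) float array
    spacing : physical voxel size per axis in mm, same axis order as values.
    origin : physical coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GridError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be three positive reals, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise GridError("volume contains non-finite values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclasses.dataclass
class VOIMask:
    """Boolean voxel mask aligned with an :class:`ImageVolume` grid."""

    indicator: np.ndarray
    view_type: str | None = None

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator).astype(bool)
        if self.indicator.ndim != 3:
            raise GridError("mask must be a 3D array")
        if self.view_type is not None and self.view_type not in VIEW_TYPES:
            raise ValueError(f"unknown view_type {self.view_type!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise MaskError("mask is empty")


@dataclasses.dataclass
class DiscretizationParams:
    """Fixed-bin-width discretization and isotropic resampling settings.

    ``bin_width`` defaults to 25 intensity units and ``resample_spacing``
    to 1 x 1 x 1 mm, the registry defaults for CE-CT.
    """

    bin_width: float = 25.0
    resample_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.resample_spacing = tuple(float(s) for s in self.resample_spacing)
        if any(s <= 0 for s in self.resample_spacing):
            raise GridError("resample_spacing must be positive")


def _check_same_grid(volume: ImageVolume, mask: VOIMask) -> None:
    if volume.shape != mask.indicator.shape:
        raise GridError(
            f"volume shape {volume.shape} != mask shape {mask.indicator.shape}"
        )


def resample_isotropic(
    volume: ImageVolume,
    mask: VOIMask,
    params: DiscretizationParams | None = None,
) -> tuple[ImageVolume, VOIMask]:
    """Resample a volume/mask pair onto an isotropic grid.

    Intensities are interpolated trilinearly; the mask with nearest
    neighbours, so it stays a crisp indicator.  The target spacing is
    ``params.resample_spacing`` (default 1 mm isotropic).
    """
    params = params or DiscretizationParams()
    _check_same_grid(volume, mask)
    target = params.resample_spacing
    if volume.spacing == target:
        return volume, mask

    zoom = [s / t for s, t in zip(volume.spacing, target)]
    new_shape = [max(1, int(round(n * z))) for n, z in zip(volume.shape, zoom)]
    # sample at physical positions of the new grid expressed in old voxel units
    coords = np.meshgrid(
        *[
            (np.arange(m) * t) / s
            for m, t, s in zip(new_shape, target, volume.spacing)
        ],
        indexing="ij",
    )
    coords = np.stack(coords)
    values = ndimage.map_coordinates(volume.values, coords, order=1, mode="nearest")
    ind = ndimage.map_coordinates(
        mask.indicator.astype(np.uint8), coords, order=0, mode="nearest"
    ).astype(bool)
    out_vol = ImageVolume(values, spacing=target, origin=volume.origin)
    out_mask = VOIMask(ind, view_type=mask.view_type)
    return out_vol, out_mask


def dilate_peritumor(
    tumor: VOIMask,
    spacing: Sequence[float],
    radius_mm: float = 10.0,
    exclusion: VOIMask | None = None,
) -> VOIMask:
    """Peritumoral shell: voxels within ``radius_mm`` of the tumor, outside it.

    The shell is ``{v : 0 < dist(v, tumor) <= radius_mm}`` with Euclidean
    distance in physical mm, minus the tumor itself and minus the optional
    exclusion mask (e.g. voxels outside the liver parenchyma, vessels, air).
    A radius of 0 yields an empty shell.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be non-negative")
    tumor.require_nonempty()
    spacing = tuple(float(s) for s in spacing)
    dist = ndimage.distance_transform_edt(~tumor.indicator, sampling=spacing)
    shell = (dist > 0) & (dist <= radius_mm)
    if exclusion is not None:
        if exclusion.indicator.shape != tumor.indicator.shape:
            raise GridError("exclusion mask shape mismatch")
        shell &= ~exclusion.indicator
    return VOIMask(shell)


def discretize(
    volume: ImageVolume,
    mask: VOIMask,
    params: DiscretizationParams | None = None,
) -> np.ndarray:
    """Fixed-bin-width gray-level discretization inside the mask.

    ``level(v) = floor((I(v) - min_mask I) / bin_width) + 1``; voxels
    outside the mask get level 0.  The number of gray levels Ng is the
    maximum level inside the mask.  Anchoring bins at the in-mask minimum
    makes the levels invariant to adding a constant to the intensities.
    """
    params = params or DiscretizationParams()
    _check_same_grid(volume, mask)
    mask.require_nonempty()
    inside = mask.indicator
    vmin = volume.values[inside].min()
    levels = np.zeros(volume.shape, dtype=np.int64)
    levels[inside] = (
        np.floor((volume.values[inside] - vmin) / params.bin_width).astype(np.int64) + 1
    )
    return levels


def threshold_segment(volume: ImageVolume, lower: float, upper: float = np.inf) -> VOIMask:
    """Simple global-threshold segmentation helper.

    Provided for convenience only — curated masks are authoritative inputs
    to the feature extractor.
    """
    return VOIMask((volume.values >= lower) & (volume.values <= upper))


# ---------------------------------------------------------------------------
# volume/mask I/O: NIfTI via nibabel, NRRD via SimpleITK
# ---------------------------------------------------------------------------

def _is_nrrd(path) -> bool:
    return str(path).lower().endswith((".nrrd", ".nhdr"))


def read_volume(path) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD volume with its voxel spacing."""
    if _is_nrrd(path):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).astype(float)
        spacing = tuple(reversed(img.GetSpacing()))  # sitk is (x, y, z)
        return ImageVolume(values, spacing=spacing)
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(values, spacing=tuple(float(z) for z in zooms))


def write_volume(volume: ImageVolume, path) -> None:
    if _is_nrrd(path):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(volume.values.astype(np.float32))
        img.SetSpacing(tuple(reversed(volume.spacing)))
        sitk.WriteImage(img, str(path))
        return
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(path))


def read_mask(path, view_type: str | None = None) -> VOIMask:
    if _is_nrrd(path):
        import SimpleITK as sitk

        arr = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
        return VOIMask(arr > 0.5, view_type=view_type)
    import nibabel as nib

    img = nib.load(str(path))
    return VOIMask(np.asanyarray(img.dataobj) > 0.5, view_type=view_type)


def write_mask(mask: VOIMask, path, spacing=(1.0, 1.0, 1.0)) -> None:
    if _is_nrrd(path):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(mask.indicator.astype(np.uint8))
        img.SetSpacing(tuple(reversed(tuple(float(s) for s in spacing))))
        sitk.WriteImage(img, str(path))
        return
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(
        nib.Nifti1Image(mask.indicator.astype(np.uint8), affine), str(path)
    )
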