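"""CT volume normalization: isotropic resampling, HU windowing, cube cropping.

The pipeline order is fixed: resample to 1 mm isotropic (cubic B-spline for
intensities, nearest-neighbour for masks), clip/scale the HU window
[-1200, 600] to [0, 255], crop a 40 mm cube centered on the mask centroid,
then min-max normalize each cube to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

HU_WINDOW = (-1200.0, 600.0)
CUBE_SIZE = 40  # mm == voxels at 1 mm isotropic


@dataclass
class Volume3D:
    """A 3D intensity grid with per-axis mm spacing, axis order (z, y, x)."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities must be finite")


@dataclass
class Cube:
    """A 40^3 unit-spacing cube with intensities in [0, 1]."""

    intensities: np.ndarray
    lesion_id: str = ""
    phase: str = "pre"
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.intensities.shape != (CUBE_SIZE, CUBE_SIZE, CUBE_SIZE):
            raise ValueError(f"Cube must be {CUBE_SIZE}^3, got {self.intensities.shape}")
        if self.intensities.min() < 0 or self.intensities.max() > 1:
            raise ValueError("Cube intensities must lie in [0, 1]")


def resample_isotropic(
    vol: Volume3D, target_spacing: float = 1.0, is_mask: bool = False
) -> Volume3D:
    """Resample to isotropic ``target_spacing`` mm.

    Cubic B-spline interpolation for intensities (order 3, edge replication);
    nearest-neighbour for masks. Output spacing is exactly isotropic and the
    physical extent is preserved to within one voxel.
    """
    if any(s <= 0 for s in vol.spacing):
        raise ValueError("non-positive spacing")
    spacing = np.asarray(vol.spacing, dtype=float)
    if np.allclose(spacing, target_spacing):
        return Volume3D(vol.intensities.copy(), (target_spacing,) * 3, vol.origin)
    shape = np.asarray(vol.intensities.shape)
    out_shape = np.maximum(np.floor((shape - 1) * spacing / target_spacing).astype(int) + 1, 1)
    grids = np.meshgrid(
        *(np.arange(n) * target_spacing / s for n, s in zip(out_shape, spacing)),
        indexing="ij",
    )
    order = 0 if is_mask else 3
    data = vol.intensities.astype(float)
    out = ndimage.map_coordinates(data, np.stack(grids), order=order, mode="nearest")
    if is_mask:
        out = (out > 0.5).astype(vol.intensities.dtype)
    return Volume3D(out, (target_spacing,) * 3, vol.origin)


def window_scale(vol: Volume3D, window: tuple[float, float] = HU_WINDOW) -> Volume3D:
    """Clip HU to ``window`` and scale affinely to [0, 255]."""
    lo, hi = window
    clipped = np.clip(vol.intensities.astype(float), lo, hi)
    scaled = 255.0 * (clipped - lo) / (hi - lo)
    return Volume3D(scaled, vol.spacing, vol.origin)


def crop_cube(
    vol: Volume3D,
    mask: Volume3D,
    size: int = CUBE_SIZE,
    pad_value: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Crop a ``size``^3 block centered on the mask centroid.

    The anchor is the intensity-unweighted centroid of all in-mask voxels,
    rounded to the nearest voxel (disjoint blobs: centroid of the union).
    Out-of-grid regions are padded with ``pad_value`` for the image and 0 for
    the mask. Returns (cube_array, mask_array).
    """
    m = np.asarray(mask.intensities) > 0
    if not m.any():
        raise ValueError("crop_cube: empty mask")
    center = np.rint(np.argwhere(m).mean(axis=0)).astype(int)
    half = size // 2
    lo = center - half
    hi = lo + size
    out = np.full((size, size, size), pad_value, dtype=float)
    out_mask = np.zeros((size, size, size), dtype=np.uint8)
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, vol.intensities.shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    dst = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
    out[dst] = vol.intensities[src]
    out_mask[dst] = m[src]
    return out, out_mask


def normalize_unit(cube: np.ndarray) -> np.ndarray:
    """Min-max rescale a cube to [0, 1]; constant cubes map to all zeros."""
    cube = np.asarray(cube, dtype=float)
    lo, hi = cube.min(), cube.max()
    if hi <= lo:
        log.warning("normalize_unit: constant cube, returning zeros")
        return np.zeros_like(cube)
    return (cube - lo) / (hi - lo)


def preprocess_volume(
    vol: Volume3D,
    mask: Volume3D,
    lesion_id: str = "",
    phase: str = "pre",
    size: int = CUBE_SIZE,
) -> Cube:
    """Full chain: resample -> window/scale -> crop -> per-cube min-max."""
    vol_iso = resample_isotropic(vol)
    mask_iso = resample_isotropic(mask, is_mask=True)
    windowed = window_scale(vol_iso)
    cube_arr, cube_mask = crop_cube(windowed, mask_iso, size=size)
    return Cube(
        intensities=normalize_unit(cube_arr),
        lesion_id=lesion_id,
        phase=phase,
        mask=cube_mask,
    )


def cube_preprocessor(vol: Volume3D, mask: Volume3D):
    """Adapter for feature extraction: (volume, mask) -> (cube, mask, spacing)."""
    cube = preprocess_volume(vol, mask)
    return cube.intensities, cube.mask.astype(bool), (1.0, 1.0, 1.0)
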