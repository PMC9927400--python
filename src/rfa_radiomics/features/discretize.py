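"""Gray-level discretization of intensity cubes prior to texture analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizedVolume:
    """Integer-labelled volume: levels ``1..n_levels`` inside the mask, 0 outside.

    Attributes
    ----------
    labels : ndarray of int
        Same shape as the source cube; 0 marks out-of-mask voxels.
    n_levels : int
        Highest gray level present in the mask (``Ng``).
    mask : ndarray of bool
    """

    labels: np.ndarray
    n_levels: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        inside = self.labels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("labels inside mask must lie in [1, n_levels]")


def discretize(cube: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> DiscretizedVolume:
    """Equal-width binning of in-mask intensities into at most ``n_bins`` levels.

    A constant region collapses to a single level (``n_levels == 1``); texture
    features handle that degenerate case explicitly downstream.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("discretize: empty mask")
    cube = np.asarray(cube, dtype=float)
    vals = cube[mask]
    lo, hi = float(vals.min()), float(vals.max())
    labels = np.zeros(cube.shape, dtype=np.int32)
    if hi <= lo:
        labels[mask] = 1
        return DiscretizedVolume(labels=labels, n_levels=1, mask=mask)
    binned = np.floor((vals - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    np.clip(binned, 1, n_bins, out=binned)
    labels[mask] = binned
    return DiscretizedVolume(labels=labels, n_levels=int(binned.max()), mask=mask)
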