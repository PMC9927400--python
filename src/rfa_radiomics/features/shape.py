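"""Shape descriptors of a binary mask in physical (mm) coordinates."""

from __future__ import annotations

import numpy as np


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """Axis-length and surface descriptors from the voxel-center covariance.

    Elongation = sqrt(lambda2 / lambda1) and Flatness = sqrt(lambda3 / lambda1)
    with lambda1 >= lambda2 >= lambda3 the eigenvalues of the physical-coordinate
    covariance of in-mask voxel centers. A single voxel (zero covariance) gets
    Elongation = Flatness = 1 by convention.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("shape_features: empty mask")
    spacing = np.asarray(spacing, dtype=float)
    idx = np.argwhere(mask).astype(float)
    coords = idx * spacing  # physical voxel centers
    n = coords.shape[0]
    voxel_vol = float(np.prod(spacing))
    volume = n * voxel_vol

    if n > 1:
        cov = np.cov(coords, rowvar=False, bias=True)
        lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
        lam = np.clip(lam, 0.0, None)
    else:
        lam = np.zeros(3)

    if lam[0] > 0:
        elongation = float(np.sqrt(lam[1] / lam[0]))
        flatness = float(np.sqrt(lam[2] / lam[0]))
    else:
        elongation, flatness = 1.0, 1.0

    # surface area: exposed voxel faces
    area = 0.0
    face_area = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    for axis in range(3):
        pad = np.zeros((mask.ndim, 2), dtype=int)
        pad[axis] = (1, 1)
        padded = np.pad(mask, pad, constant_values=False)
        exposed = np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum()
        area += float(exposed) * face_area[axis]

    sphericity = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)
    return {
        "VoxelVolume": volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume,
        "Sphericity": sphericity,
        "Elongation": elongation,
        "Flatness": flatness,
        "MajorAxisLength": float(4.0 * np.sqrt(lam[0])),
        "MinorAxisLength": float(4.0 * np.sqrt(lam[1])),
        "LeastAxisLength": float(4.0 * np.sqrt(lam[2])),
    }
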