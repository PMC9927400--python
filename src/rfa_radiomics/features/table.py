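"""Per-lesion feature extraction into a phase-prefixed feature table."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .discretize import discretize
from .firstorder import firstorder_features
from .shape import shape_features
from .texture import (
    glcm_features,
    glcm_matrix,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

#: features whose consensus selection drives the radiomics model
SELECTED_FEATURES_PRE = (
    "pre_shape_Elongation",
    "pre_GLCM_Idmn",
    "pre_GLCM_Imc1",
    "pre_GLCM_InverseVariance",
    "pre_GLCM_ClusterShade",
    "pre_GLDM_DependenceEntropy",
)
SELECTED_FEATURES_POST = (
    "post_GLCM_Idmn",
    "post_GLRLM_RunEntropy",
    "post_GLCM_Imc2",
)
SELECTED_FEATURES = SELECTED_FEATURES_PRE + SELECTED_FEATURES_POST


def _bbox_crop(cube: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Crop both arrays to the mask bounding box (texture cost scales with it)."""
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return cube[sl], mask[sl]


def extract_features(
    cube: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_bins: int = 32,
    gldm_alpha: int = 0,
) -> dict[str, float]:
    """All implemented families on one cube/mask pair, family-prefixed names."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("extract_features: empty mask")
    feats: dict[str, float] = {}
    for name, value in shape_features(mask, spacing).items():
        feats[f"shape_{name}"] = value
    sub_cube, sub_mask = _bbox_crop(np.asarray(cube, dtype=float), mask)
    for name, value in firstorder_features(sub_cube, sub_mask, n_bins=n_bins).items():
        feats[f"firstorder_{name}"] = value
    dv = discretize(sub_cube, sub_mask, n_bins=n_bins)
    for name, value in glcm_features(glcm_matrix(dv), dv.n_levels).items():
        feats[f"GLCM_{name}"] = value
    for name, value in glrlm_features(dv).items():
        feats[f"GLRLM_{name}"] = value
    for name, value in glszm_features(dv).items():
        feats[f"GLSZM_{name}"] = value
    for name, value in gldm_features(dv, alpha=gldm_alpha).items():
        feats[f"GLDM_{name}"] = value
    for name, value in ngtdm_features(dv).items():
        feats[f"NGTDM_{name}"] = value
    return feats


def extract_feature_table(
    cases: Iterable,
    n_bins: int = 32,
    gldm_alpha: int = 0,
    preprocessor=None,
) -> pd.DataFrame:
    """One row per lesion: ``pre_*`` features from the lesion cube, ``post_*``
    from the ablation-zone cube.

    ``cases`` yields objects with ``lesion_id``, ``pre_volume``/``pre_mask``,
    ``post_volume``/``post_mask`` attributes (``LesionCase``). When
    ``preprocessor`` is given it maps (volume, mask) -> (cube, cube_mask,
    spacing); otherwise volumes are used as-is with their own spacing.
    """
    rows: list[dict[str, float]] = []
    ids: list[str] = []
    for case in cases:
        row: dict[str, float] = {}
        for phase in ("pre", "post"):
            vol = getattr(case, f"{phase}_volume")
            msk = getattr(case, f"{phase}_mask")
            if preprocessor is not None:
                cube, cube_mask, spacing = preprocessor(vol, msk)
            else:
                cube, cube_mask, spacing = vol.intensities, msk.intensities > 0, vol.spacing
            feats = extract_features(
                cube, cube_mask, spacing=spacing, n_bins=n_bins, gldm_alpha=gldm_alpha
            )
            for name, value in feats.items():
                if not np.isfinite(value):
                    raise ValueError(
                        f"non-finite feature {phase}_{name} for lesion {case.lesion_id}"
                    )
                row[f"{phase}_{name}"] = value
        rows.append(row)
        ids.append(case.lesion_id)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="lesion_id"))
    if table.columns.duplicated().any():
        raise ValueError("duplicate feature columns")
    return table


def extraction_settings(n_bins: int = 32, gldm_alpha: int = 0) -> Mapping[str, object]:
    """Sidecar metadata describing how a feature table was produced."""
    return {
        "n_bins": n_bins,
        "gldm_alpha": gldm_alpha,
        "glcm_distance": 1,
        "directions": 13,
        "aggregation": "merged",
        "log_base": 2,
    }
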