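"""Texture-matrix construction and features: GLCM, GLRLM, GLDM, GLSZM, NGTDM.

Matrices are built on the integer label grid of a :class:`DiscretizedVolume`.
Directional matrices (GLCM, GLRLM) aggregate counts over the 13 unique 3D
directions before normalization (merged strategy). All entropies use log2 with
the 0·log 0 := 0 convention.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVolume

# 13 unique directions: offsets in {-1,0,1}^3 whose first nonzero entry is +1.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13

def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with 0 log 0 = 0."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _offset_views(arr: np.ndarray, d: tuple[int, int, int]):
    """Return (view_at_x, view_at_x_plus_d) pairs of equal-shape slices."""
    src, dst = [], []
    for axis_len, step in zip(arr.shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, axis_len - step))
            dst.append(slice(step, axis_len))
        else:
            src.append(slice(-step, axis_len))
            dst.append(slice(0, axis_len + step))
    return arr[tuple(src)], arr[tuple(dst)]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(dv: DiscretizedVolume, distance: int = 1, directions=DIRECTIONS_13) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix, merged over ``directions``.

    Only voxel pairs with both endpoints inside the mask are counted; each
    pair contributes in both orders (symmetry).
    """
    ng = dv.n_levels
    labels = dv.labels
    counts = np.zeros((ng, ng), dtype=np.int64)
    for d in directions:
        off = tuple(distance * s for s in d)
        a, b = _offset_views(labels, off)
        valid = (a > 0) & (b > 0)
        ai = a[valid] - 1
        bi = b[valid] - 1
        flat = np.bincount(ai * ng + bi, minlength=ng * ng).reshape(ng, ng)
        counts += flat
        counts += flat.T
    total = counts.sum()
    if total == 0:
        # single in-mask voxel: no pairs at all; fall back to a delta matrix
        p = np.zeros((ng, ng))
        lev = int(labels[dv.mask][0]) - 1
        p[lev, lev] = 1.0
        return p
    return counts / total


def glcm_features(p: np.ndarray, ng: int | None = None) -> dict[str, float]:
    """Standard co-occurrence features from a normalized symmetric matrix."""
    if ng is None:
        ng = p.shape[0]
    i = np.arange(1, p.shape[0] + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - muy) ** 2 * py).sum()))
    diff = np.abs(ii - jj)

    feats: dict[str, float] = {}
    feats["Autocorrelation"] = float((ii * jj * p).sum())
    dev = ii + jj - mux - muy
    feats["ClusterTendency"] = float((dev**2 * p).sum())
    feats["ClusterShade"] = float((dev**3 * p).sum())
    feats["ClusterProminence"] = float((dev**4 * p).sum())
    feats["Contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sigx > 0 and sigy > 0:
        feats["Correlation"] = float((((ii - mux) * (jj - muy)) * p).sum() / (sigx * sigy))
    else:
        feats["Correlation"] = 1.0
    # difference-distribution features: p_{|i-j|}(k)
    kmax = p.shape[0]
    pd = np.array([p[diff == k].sum() for k in range(kmax)])
    kvals = np.arange(kmax, dtype=float)
    feats["DifferenceAverage"] = float((kvals * pd).sum())
    feats["DifferenceEntropy"] = float(-_xlog2(pd).sum())
    feats["DifferenceVariance"] = float(((kvals - feats["DifferenceAverage"]) ** 2 * pd).sum())
    feats["JointEnergy"] = float((p**2).sum())
    hxy = float(-_xlog2(p).sum())
    feats["JointEntropy"] = hxy
    # sum-distribution features: p_{i+j}(k), k = 2..2Ng
    ksum = (ii + jj).astype(int)
    ps = np.array([p[ksum == k].sum() for k in range(2, 2 * p.shape[0] + 1)])
    svals = np.arange(2, 2 * p.shape[0] + 1, dtype=float)
    feats["SumAverage"] = float((svals * ps).sum())
    feats["SumEntropy"] = float(-_xlog2(ps).sum())
    feats["SumSquares"] = float(((ii - mux) ** 2 * p).sum())
    feats["Idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    feats["Idmn"] = float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum())
    feats["Id"] = float((p / (1.0 + diff)).sum())
    feats["Idn"] = float((p / (1.0 + diff / ng)).sum())
    offdiag = diff > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        iv = p[offdiag] / (ii - jj)[offdiag] ** 2
    feats["InverseVariance"] = float(iv.sum())
    feats["MaximumProbability"] = float(p.max())
    # informational measures of correlation
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxy_outer = np.outer(px, py)
    valid = (p > 0) & (pxy_outer > 0)
    hxy1 = float(-(p[valid] * np.log2(pxy_outer[valid])).sum())
    hxy2 = float(-_xlog2(pxy_outer).sum())
    if max(hx, hy) <= 0:
        feats["Imc1"] = 0.0
        feats["Imc2"] = 0.0
    else:
        feats["Imc1"] = (hxy - hxy1) / max(hx, hy)
        feats["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return feats


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(dv: DiscretizedVolume, directions=DIRECTIONS_13) -> np.ndarray:
    """Run-length matrix ``R[level-1, length-1]`` summed over ``directions``.

    Run lengths are computed by iterated propagation of the "same level as the
    next voxel along d" indicator, which avoids per-line Python loops.
    """
    labels = dv.labels
    ng = dv.n_levels
    max_len = int(np.ceil(np.sqrt(sum(s**2 for s in labels.shape)))) + 1
    counts = np.zeros((ng, max_len), dtype=np.int64)
    inmask = labels > 0
    for d in directions:
        a_lab, b_lab = _offset_views(labels, d)
        # same_next[x] <=> x and x+d both in mask with equal level
        same_next = np.zeros(labels.shape, dtype=bool)
        sn_view, _ = _offset_views(same_next, d)
        sn_view[...] = (a_lab > 0) & (a_lab == b_lab)
        # f[x] = number of consecutive same-level steps forward from x
        f = np.zeros(labels.shape, dtype=np.int32)
        while True:
            shifted = np.zeros_like(f)
            a_f, b_f = _offset_views(f, d)
            a_f2, _ = _offset_views(shifted, d)
            a_f2[...] = b_f
            new = np.where(same_next, 1 + shifted, 0)
            if np.array_equal(new, f):
                break
            f = new
        # starts: in-mask voxels with no same-level predecessor along d
        same_prev = np.zeros(labels.shape, dtype=bool)
        _, dst_view = _offset_views(same_prev, d)
        src_sn, _ = _offset_views(same_next, d)
        dst_view[...] = src_sn
        starts = inmask & ~same_prev
        lev = labels[starts] - 1
        length = f[starts]  # run length - 1
        counts += np.bincount(lev * max_len + length, minlength=ng * max_len).reshape(
            ng, max_len
        )
    # trim trailing all-zero length columns
    last = np.max(np.nonzero(counts.sum(axis=0))[0]) if counts.any() else 0
    return counts[:, : last + 1]


def glrlm_features(dv: DiscretizedVolume, directions=DIRECTIONS_13) -> dict[str, float]:
    r_mat = glrlm_matrix(dv, directions=directions).astype(float)
    nr = r_mat.sum()
    np_vox = int(dv.mask.sum())
    i = np.arange(1, r_mat.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, r_mat.shape[1] + 1, dtype=float)[None, :]
    p = r_mat / nr
    feats = {
        "ShortRunEmphasis": float((r_mat / l**2).sum() / nr),
        "LongRunEmphasis": float((r_mat * l**2).sum() / nr),
        "GrayLevelNonUniformity": float((r_mat.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((r_mat.sum(axis=1) ** 2).sum() / nr**2),
        "RunLengthNonUniformity": float((r_mat.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((r_mat.sum(axis=0) ** 2).sum() / nr**2),
        "RunPercentage": float(nr / np_vox),
        "LowGrayLevelRunEmphasis": float((r_mat / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((r_mat * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((r_mat / (i**2 * l**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((r_mat * i**2 / l**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((r_mat * l**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((r_mat * i**2 * l**2).sum() / nr),
        "RunEntropy": float(-_xlog2(p).sum()),
    }
    mu_i = float((i * p).sum())
    mu_l = float((l * p).sum())
    feats["GrayLevelVariance"] = float(((i - mu_i) ** 2 * p).sum())
    feats["RunVariance"] = float(((l - mu_l) ** 2 * p).sum())
    return feats


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(dv: DiscretizedVolume, alpha: int = 0) -> np.ndarray:
    """Dependence matrix ``D[level-1, dependence-1]``.

    Dependence of a voxel = 1 + number of its 26-neighbours inside the mask
    whose gray level differs by at most ``alpha``.
    """
    labels = dv.labels
    ng = dv.n_levels
    dep = np.zeros(labels.shape, dtype=np.int32)
    for d in DIRECTIONS_13:
        a_lab, b_lab = _offset_views(labels, d)
        match = (a_lab > 0) & (b_lab > 0) & (np.abs(a_lab - b_lab) <= alpha)
        a_dep, b_dep = _offset_views(dep, d)
        a_dep += match
        b_dep += match
    dep = dep + 1
    inmask = dv.mask
    lev = labels[inmask] - 1
    dp = dep[inmask] - 1
    max_dep = 27
    counts = np.bincount(lev * max_dep + dp, minlength=ng * max_dep).reshape(ng, max_dep)
    last = np.max(np.nonzero(counts.sum(axis=0))[0])
    return counts[:, : last + 1]


def gldm_features(dv: DiscretizedVolume, alpha: int = 0) -> dict[str, float]:
    d_mat = gldm_matrix(dv, alpha=alpha).astype(float)
    nz = d_mat.sum()
    i = np.arange(1, d_mat.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, d_mat.shape[1] + 1, dtype=float)[None, :]
    p = d_mat / nz
    feats = {
        "SmallDependenceEmphasis": float((d_mat / j**2).sum() / nz),
        "LargeDependenceEmphasis": float((d_mat * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((d_mat.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((d_mat.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((d_mat.sum(axis=0) ** 2).sum() / nz**2),
        "LowGrayLevelEmphasis": float((d_mat / i**2).sum() / nz),
        "HighGrayLevelEmphasis": float((d_mat * i**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((d_mat / (i**2 * j**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((d_mat * i**2 / j**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((d_mat * j**2 / i**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((d_mat * i**2 * j**2).sum() / nz),
        "DependenceEntropy": float(-_xlog2(p).sum()),
    }
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    feats["GrayLevelVariance"] = float(((i - mu_i) ** 2 * p).sum())
    feats["DependenceVariance"] = float(((j - mu_j) ** 2 * p).sum())
    return feats


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(dv: DiscretizedVolume) -> np.ndarray:
    """Size-zone matrix ``S[level-1, size-1]`` with 26-connected zones."""
    labels = dv.labels
    ng = dv.n_levels
    zones: list[tuple[int, int]] = []
    for lev in range(1, ng + 1):
        comp, n_comp = ndimage.label(labels == lev, structure=_STRUCT_26)
        if n_comp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        zones.extend((lev, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    counts = np.zeros((ng, max_size), dtype=np.int64)
    for lev, s in zones:
        counts[lev - 1, s - 1] += 1
    return counts


def glszm_features(dv: DiscretizedVolume) -> dict[str, float]:
    s_mat = glszm_matrix(dv).astype(float)
    nz = s_mat.sum()
    np_vox = int(dv.mask.sum())
    i = np.arange(1, s_mat.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, s_mat.shape[1] + 1, dtype=float)[None, :]
    p = s_mat / nz
    feats = {
        "SmallAreaEmphasis": float((s_mat / s**2).sum() / nz),
        "LargeAreaEmphasis": float((s_mat * s**2).sum() / nz),
        "GrayLevelNonUniformity": float((s_mat.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((s_mat.sum(axis=1) ** 2).sum() / nz**2),
        "SizeZoneNonUniformity": float((s_mat.sum(axis=0) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((s_mat.sum(axis=0) ** 2).sum() / nz**2),
        "ZonePercentage": float(nz / np_vox),
        "LowGrayLevelZoneEmphasis": float((s_mat / i**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((s_mat * i**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((s_mat / (i**2 * s**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((s_mat * i**2 / s**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((s_mat * s**2 / i**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((s_mat * i**2 * s**2).sum() / nz),
        "ZoneEntropy": float(-_xlog2(p).sum()),
    }
    mu_i = float((i * p).sum())
    mu_s = float((s * p).sum())
    feats["GrayLevelVariance"] = float(((i - mu_i) ** 2 * p).sum())
    feats["ZoneVariance"] = float(((s - mu_s) ** 2 * p).sum())
    return feats


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(dv: DiscretizedVolume) -> dict[str, float]:
    labels = dv.labels
    ng = dv.n_levels
    neigh_sum = np.zeros(labels.shape, dtype=float)
    neigh_cnt = np.zeros(labels.shape, dtype=np.int32)
    for d in DIRECTIONS_13:
        a_lab, b_lab = _offset_views(labels, d)
        both = (a_lab > 0) & (b_lab > 0)
        a_s, b_s = _offset_views(neigh_sum, d)
        a_c, b_c = _offset_views(neigh_cnt, d)
        a_s += np.where(both, b_lab, 0)
        b_s += np.where(both, a_lab, 0)
        a_c += both
        b_c += both
    valid = dv.mask & (neigh_cnt > 0)
    nvp = int(valid.sum())
    if nvp == 0:
        return {k: 0.0 for k in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")}
    lev = labels[valid]
    avg = neigh_sum[valid] / neigh_cnt[valid]
    absdiff = np.abs(lev - avg)
    n_i = np.bincount(lev - 1, minlength=ng).astype(float)
    s_i = np.bincount(lev - 1, weights=absdiff, minlength=ng)
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    ivals = np.arange(1, ng + 1, dtype=float)

    coarse_denom = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_denom if coarse_denom > 0 else 1e6

    if ngp > 1:
        pi_p, pj_p = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        di = ivals[present][:, None] - ivals[present][None, :]
        contrast = float(
            (pi_p * pj_p * di**2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / nvp)
        )
    else:
        contrast = 0.0

    ip = ivals * p_i
    busy_denom = float(np.abs(ip[present][:, None] - ip[present][None, :]).sum())
    busyness = float((p_i * s_i).sum() / busy_denom) if busy_denom > 0 else 0.0

    pi_p = p_i[present][:, None]
    pj_p = p_i[present][None, :]
    iv = ivals[present][:, None]
    jv = ivals[present][None, :]
    si_p = s_i[present][:, None]
    sj_p = s_i[present][None, :]
    complexity = float(
        (np.abs(iv - jv) * (pi_p * si_p + pj_p * sj_p) / (pi_p + pj_p)).sum() / nvp
    )

    s_sum = float(s_i.sum())
    strength = float(((pi_p + pj_p) * (iv - jv) ** 2).sum() / s_sum) if s_sum > 0 else 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
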