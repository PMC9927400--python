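"""Independent brute-force oracles for texture matrices.

These deliberately use naive per-voxel Python loops so they share no code
path with the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np

ALL_DIRECTIONS_13 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
]


def _in_grid(pos, shape) -> bool:
    return all(0 <= p < s for p, s in zip(pos, shape))


def glcm_bruteforce(labels: np.ndarray, directions=ALL_DIRECTIONS_13, distance: int = 1):
    """Count every ordered in-mask voxel pair at +/-d, then normalize."""
    ng = int(labels.max())
    counts = np.zeros((ng, ng), dtype=float)
    shape = labels.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if labels[z, y, x] == 0:
                    continue
                for d in directions:
                    for sign in (1, -1):
                        q = (z + sign * distance * d[0],
                             y + sign * distance * d[1],
                             x + sign * distance * d[2])
                        if _in_grid(q, shape) and labels[q] > 0:
                            counts[labels[z, y, x] - 1, labels[q] - 1] += 1
    total = counts.sum()
    if total == 0:
        lev = int(labels[labels > 0][0]) - 1
        counts[lev, lev] = 1.0
        return counts
    return counts / total


def glrlm_bruteforce(labels: np.ndarray, directions=ALL_DIRECTIONS_13):
    """Scan maximal same-level runs along each direction by walking voxels."""
    ng = int(labels.max())
    shape = labels.shape
    runs: list[tuple[int, int]] = []
    for d in directions:
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    lev = labels[z, y, x]
                    if lev == 0:
                        continue
                    prev = (z - d[0], y - d[1], x - d[2])
                    if _in_grid(prev, shape) and labels[prev] == lev:
                        continue  # not a run start
                    length = 1
                    cur = (z + d[0], y + d[1], x + d[2])
                    while _in_grid(cur, shape) and labels[cur] == lev:
                        length += 1
                        cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                    runs.append((int(lev), length))
    max_len = max(length for _, length in runs)
    mat = np.zeros((ng, max_len), dtype=float)
    for lev, length in runs:
        mat[lev - 1, length - 1] += 1
    return mat


def gldm_bruteforce(labels: np.ndarray, alpha: int = 0):
    """Per-voxel 26-neighbourhood dependence counts."""
    ng = int(labels.max())
    shape = labels.shape
    cells: list[tuple[int, int]] = []
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                lev = labels[z, y, x]
                if lev == 0:
                    continue
                dep = 1
                for d in offsets:
                    q = (z + d[0], y + d[1], x + d[2])
                    if _in_grid(q, shape) and labels[q] > 0 and abs(int(labels[q]) - int(lev)) <= alpha:
                        dep += 1
                cells.append((int(lev), dep))
    max_dep = max(dep for _, dep in cells)
    mat = np.zeros((ng, max_dep), dtype=float)
    for lev, dep in cells:
        mat[lev - 1, dep - 1] += 1
    return mat


def random_discrete_volume(rng: np.random.Generator, shape=(4, 4, 4), n_levels=4,
                           mask_p: float = 0.8):
    """Random labelled volume with a random nonempty mask."""
    labels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.uniform(size=shape) < mask_p
    if not mask.any():
        mask.flat[0] = True
    labels[~mask] = 0
    return labels, mask
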