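"""Independent brute-force oracles for texture matrices and agreement stats.

Everything here is deliberately written as plain Python loops / recursion,
sharing no code with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np

DIRS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]

DIRS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def brute_glcm(levels, mask, ng):
    shape = levels.shape
    out = np.zeros((13, ng, ng), dtype=np.int64)
    for k, d in enumerate(DIRS_13):
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if not mask[x, y, z]:
                        continue
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and mask[q]:
                        a = levels[x, y, z] - 1
                        b = levels[q] - 1
                        out[k, a, b] += 1
                        out[k, b, a] += 1
    return out


def brute_glrlm(levels, mask, ng):
    shape = levels.shape
    rmax = max(shape)
    out = np.zeros((13, ng, rmax), dtype=np.int64)
    for k, d in enumerate(DIRS_13):
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _inside(shape, prev):
                        continue  # not a line start
                    # walk the full line, splitting runs at mask boundaries
                    p = (x, y, z)
                    run_level, run_len = None, 0
                    while _inside(shape, p):
                        lv = levels[p] if mask[p] else None
                        if lv == run_level and lv is not None:
                            run_len += 1
                        else:
                            if run_level is not None:
                                out[k, run_level - 1, run_len - 1] += 1
                            run_level, run_len = lv, 1
                        p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                    if run_level is not None:
                        out[k, run_level - 1, run_len - 1] += 1
    return out


def brute_glszm(levels, mask, ng):
    shape = levels.shape
    smax = int(mask.sum())
    out = np.zeros((ng, smax), dtype=np.int64)
    visited = np.zeros(shape, dtype=bool)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or visited[x, y, z]:
                    continue
                g = levels[x, y, z]
                stack = [(x, y, z)]
                visited[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in DIRS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if (
                            _inside(shape, q)
                            and mask[q]
                            and not visited[q]
                            and levels[q] == g
                        ):
                            visited[q] = True
                            stack.append(q)
                out[g - 1, size - 1] += 1
    return out


def brute_ngtdm(levels, mask, ng):
    shape = levels.shape
    n_i = np.zeros(ng, dtype=np.int64)
    s_i = np.zeros(ng, dtype=np.float64)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                neigh = []
                for d in DIRS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and mask[q]:
                        neigh.append(levels[q])
                if not neigh:
                    continue
                g = levels[x, y, z]
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - sum(neigh) / len(neigh))
    return n_i, s_i


def brute_gldm(levels, mask, ng, alpha=0):
    shape = levels.shape
    out = np.zeros((ng, 27), dtype=np.int64)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                g = levels[x, y, z]
                dep = 0
                for d in DIRS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and mask[q] and abs(levels[q] - g) <= alpha:
                        dep += 1
                out[g - 1, dep] += 1
    return out


def random_fixture(rng, ng=4, max_side=6):
    """A random small level volume + mask with at least two in-mask voxels."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    levels = rng.integers(1, ng + 1, size=shape)
    while True:
        mask = rng.random(shape) < 0.7
        if mask.sum() >= 2:
            return levels, mask


def icc21_oracle(table):
    """ICC(2,1) via an explicit two-way ANOVA table, written independently."""
    t = np.asarray(table, dtype=float)
    n, k = t.shape
    mean_all = t.mean()
    ms_rows = k * ((t.mean(axis=1) - mean_all) ** 2).sum() / (n - 1)
    ms_cols = n * ((t.mean(axis=0) - mean_all) ** 2).sum() / (k - 1)
    resid = t - t.mean(axis=1, keepdims=True) - t.mean(axis=0, keepdims=True) + mean_all
    ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err)
    )


def ccc_oracle(x, y):
    """Lin's concordance with population moments, written independently."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxy = np.mean(x * y) - x.mean() * y.mean()
    return 2 * sxy / (np.mean(x**2) - x.mean() ** 2 + np.mean(y**2) - y.mean() ** 2
                      + (x.mean() - y.mean()) ** 2)
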