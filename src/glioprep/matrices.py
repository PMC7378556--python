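"""Texture matrices from a discretized 3D ROI.

All builders take a 3D integer level volume (levels >= 1 inside the mask,
anything outside the mask is ignored) plus the boolean ROI mask, and work
in 3D at Chebyshev distance 1:

* GLCM  — symmetric grey-level co-occurrence counts, one matrix per each
  of the 13 unique 3D directions;
* GLRLM — grey-level run lengths per direction, runs truncated at the
  mask boundary;
* GLSZM — grey-level size zones: 26-connected components of equal level;
* NGTDM — per-level neighbourhood grey-tone difference (n_i, s_i) using
  the 26-neighbourhood mean of in-mask neighbours;
* GLDM  — grey-level dependence: for each centre voxel the number of
  26-neighbours whose level differs by at most alpha.

Builders return raw integer counts; probability normalization happens in
the feature formulas.  Each builder is checked in the test-suite against
an independent brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = [
    "DIRECTIONS_13",
    "TextureMatrices",
    "levels_volume",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "ngtdm_matrix",
    "gldm_matrix",
    "compute_texture_matrices",
]

# one representative of each +/- direction pair in the 26-neighbourhood
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def levels_volume(mask: np.ndarray, disc: DiscretizedROI) -> np.ndarray:
    """Embed per-ROI-voxel levels back into a 3D volume (0 outside mask)."""
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) != disc.levels.size:
        raise ValueError(
            f"mask has {int(mask.sum())} voxels but {disc.levels.size} levels were given"
        )
    vol = np.zeros(mask.shape, dtype=np.int64)
    vol[mask] = disc.levels
    return vol


def _offset_slices(shape, offset):
    """Slices (src, dst) so that arr[src] and arr[dst] pair p with p + offset."""
    src, dst = [], []
    for s, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, s - o))
            dst.append(slice(o, s))
        else:
            src.append(slice(-o, s))
            dst.append(slice(0, s + o))
    return tuple(src), tuple(dst)


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    return mask


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Symmetric co-occurrence counts, shape (13, Ng, Ng)."""
    mask = _check_mask(mask)
    lv = np.asarray(levels, dtype=np.int64)
    ng = int(n_levels if n_levels is not None else lv[mask].max())
    out = np.zeros((len(DIRECTIONS_13), ng, ng), dtype=np.int64)
    any_pair = False
    for k, d in enumerate(DIRECTIONS_13):
        src, dst = _offset_slices(lv.shape, d)
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        any_pair = True
        a = lv[src][valid] - 1
        b = lv[dst][valid] - 1
        counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
        out[k] = counts + counts.T
    if not any_pair:
        raise ValueError("mask contains no valid voxel pair in any direction")
    return out


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Run-length counts, shape (13, Ng, Rmax) with Rmax = max axis length."""
    mask = _check_mask(mask)
    lv = np.asarray(levels, dtype=np.int64)
    ng = int(n_levels if n_levels is not None else lv[mask].max())
    shape = lv.shape
    rmax = max(shape)
    lv_flat = np.where(mask, lv, 0).ravel()
    coords = np.indices(shape).reshape(3, -1)
    out = np.zeros((len(DIRECTIONS_13), ng, rmax), dtype=np.int64)
    for k, d in enumerate(DIRECTIONS_13):
        # steps from the first in-grid voxel of this voxel's line
        t = np.full(coords.shape[1], np.iinfo(np.int64).max)
        for a, o in enumerate(d):
            if o > 0:
                t = np.minimum(t, coords[a])
            elif o < 0:
                t = np.minimum(t, shape[a] - 1 - coords[a])
        start = coords - np.asarray(d)[:, None] * t
        line_id = np.ravel_multi_index(start, shape)
        order = np.lexsort((t, line_id))
        vals = lv_flat[order]
        lid = line_id[order]
        brk = (vals[1:] != vals[:-1]) | (lid[1:] != lid[:-1])
        run_starts = np.concatenate(([0], np.nonzero(brk)[0] + 1))
        run_levels = vals[run_starts]
        run_lengths = np.diff(np.concatenate((run_starts, [vals.size])))
        keep = run_levels > 0
        g = run_levels[keep] - 1
        j = run_lengths[keep] - 1
        out[k] = np.bincount(g * rmax + j, minlength=ng * rmax).reshape(ng, rmax)
    return out


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Size-zone counts, shape (Ng, Smax): 26-connected equal-level zones."""
    mask = _check_mask(mask)
    lv = np.asarray(levels, dtype=np.int64)
    ng = int(n_levels if n_levels is not None else lv[mask].max())
    smax = int(mask.sum())
    zones: list[tuple[int, int]] = []
    for g in np.unique(lv[mask]):
        lab, n_lab = ndimage.label((lv == g) & mask, structure=_STRUCT_26)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    out = np.zeros((ng, smax), dtype=np.int64)
    for g, s in zones:
        out[g - 1, s - 1] += 1
    return out


def ngtdm_matrix(
    levels: np.ndarray, mask: np.ndarray, n_levels: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i): counts of valid centre voxels and summed
    absolute differences from the 26-neighbourhood mean of in-mask
    neighbours.  Centre voxels without any in-mask neighbour are excluded."""
    mask = _check_mask(mask)
    lv = np.asarray(levels, dtype=np.int64)
    ng = int(n_levels if n_levels is not None else lv[mask].max())
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    lv_masked = np.where(mask, lv, 0).astype(np.float64)
    neigh_sum = ndimage.correlate(lv_masked, kernel, mode="constant", cval=0.0)
    neigh_cnt = ndimage.correlate(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = mask & (neigh_cnt > 0.5)
    i_lv = lv[valid]
    diff = np.abs(i_lv - neigh_sum[valid] / neigh_cnt[valid])
    n_i = np.bincount(i_lv - 1, minlength=ng).astype(np.int64)
    s_i = np.bincount(i_lv - 1, weights=diff, minlength=ng)
    return n_i, s_i


def gldm_matrix(
    levels: np.ndarray, mask: np.ndarray, alpha: int = 0, n_levels: int | None = None
) -> np.ndarray:
    """Dependence counts, shape (Ng, 27): column k = number of centre voxels
    with exactly k of their 26 in-mask neighbours within +/-alpha levels."""
    mask = _check_mask(mask)
    lv = np.asarray(levels, dtype=np.int64)
    ng = int(n_levels if n_levels is not None else lv[mask].max())
    dep = np.zeros(lv.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        for off in (d, tuple(-o for o in d)):
            src, dst = _offset_slices(lv.shape, off)
            hit = mask[src] & mask[dst] & (np.abs(lv[src] - lv[dst]) <= alpha)
            dep[src] += hit
    g = lv[mask] - 1
    k = dep[mask]
    return np.bincount(g * 27 + k, minlength=ng * 27).reshape(ng, 27)


@dataclass(frozen=True)
class TextureMatrices:
    """All five texture matrices of one discretized ROI (raw counts)."""

    glcm: np.ndarray          # (13, Ng, Ng)
    glrlm: np.ndarray         # (13, Ng, Rmax)
    glszm: np.ndarray         # (Ng, Smax)
    ngtdm_n: np.ndarray       # (Ng,)
    ngtdm_s: np.ndarray       # (Ng,)
    gldm: np.ndarray          # (Ng, 27)
    n_levels: int
    n_roi_voxels: int
    directions: tuple = DIRECTIONS_13


def compute_texture_matrices(
    levels: np.ndarray, mask: np.ndarray, n_levels: int | None = None, alpha: int = 0
) -> TextureMatrices:
    """Build all five matrices on a (preferably bbox-cropped) level volume."""
    mask = _check_mask(mask)
    lv = np.asarray(levels, dtype=np.int64)
    ng = int(n_levels if n_levels is not None else lv[mask].max())
    n_i, s_i = ngtdm_matrix(lv, mask, ng)
    return TextureMatrices(
        glcm=glcm_matrix(lv, mask, ng),
        glrlm=glrlm_matrix(lv, mask, ng),
        glszm=glszm_matrix(lv, mask, ng),
        ngtdm_n=n_i,
        ngtdm_s=s_i,
        gldm=gldm_matrix(lv, mask, alpha, ng),
        n_levels=ng,
        n_roi_voxels=int(mask.sum()),
    )
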