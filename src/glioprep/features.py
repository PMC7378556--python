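"""Radiomics feature extraction: 18 first-order + 73 texture features.

First-order statistics are computed on the raw (possibly normalized) ROI
intensities; Entropy and Uniformity alone are computed on the
experiment's discretized grey levels, so they inherit the active
discretization scheme.  Texture features follow IBSI-style definitions:
22 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM and 14 GLDM features, with
direction-dependent classes computed per direction (3D, distance 1,
13 unique directions; GLCM symmetric) and averaged over directions.

Conventions fixed repository-wide:

* population (divide-by-N) variance and standard deviation;
* Pearson (non-excess) kurtosis; skewness and kurtosis of a constant
  ROI fall back to 0;
* logarithms base 2 with 0*log(0) := 0;
* NGTDM coarseness with a zero denominator returns the sentinel 1e6;
* GLDM dependence is the raw neighbour count k in 0..26; the feature
  formulas use the column index j = k + 1 so small-dependence emphases
  stay finite.

Every emitted feature vector is finite by construction (degenerate
fallbacks above); extraction aborts naming the case otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .discretize import DiscretizationSpec, DiscretizedROI, discretize_roi, mean_roi_range
from .matrices import TextureMatrices, compute_texture_matrices, levels_volume
from .normalize import StandardHistogram, normalize_image
from .volume import BinaryMask, VolumeImage

__all__ = [
    "FIRST_ORDER_NAMES",
    "TEXTURE_NAMES",
    "FEATURE_NAMES",
    "first_order_features",
    "texture_features",
    "case_feature_vector",
    "extract_feature_table",
    "METADATA_COLUMNS",
]

COARSENESS_SENTINEL = 1e6

FIRST_ORDER_NAMES = tuple(
    f"firstorder/{n}"
    for n in (
        "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
        "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
        "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
        "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
    )
)

_GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
)
_GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
_GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
_NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
_GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

TEXTURE_NAMES = tuple(
    [f"glcm/{n}" for n in _GLCM_NAMES]
    + [f"glrlm/{n}" for n in _GLRLM_NAMES]
    + [f"glszm/{n}" for n in _GLSZM_NAMES]
    + [f"ngtdm/{n}" for n in _NGTDM_NAMES]
    + [f"gldm/{n}" for n in _GLDM_NAMES]
)
FEATURE_NAMES = FIRST_ORDER_NAMES + TEXTURE_NAMES

METADATA_COLUMNS = ("case_id", "grade", "scanner_id", "normalization", "mode", "bins")


def _plog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log(0) := 0 convention."""
    out = np.zeros_like(p, dtype=np.float64)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


def first_order_features(
    roi_values: np.ndarray, voxel_volume: float, disc: DiscretizationSpec
) -> dict[str, float]:
    """The 18 first-order statistics of the ROI intensity distribution."""
    x = np.asarray(roi_values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        m2 = var
        m3 = float(np.mean((x - mean) ** 3))
        m4 = float(np.mean((x - mean) ** 4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2  # Pearson, non-excess
    else:
        skew = 0.0
        kurt = 0.0

    lv = discretize_roi(x, disc).levels
    p = np.bincount(lv)[1:] / n
    entropy = float(-_plog2(p).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "firstorder/Energy": energy,
        "firstorder/TotalEnergy": float(voxel_volume) * energy,
        "firstorder/Entropy": entropy,
        "firstorder/Minimum": float(x.min()),
        "firstorder/Percentile10": float(p10),
        "firstorder/Percentile90": float(p90),
        "firstorder/Maximum": float(x.max()),
        "firstorder/Mean": mean,
        "firstorder/Median": float(median),
        "firstorder/InterquartileRange": float(p75 - p25),
        "firstorder/Range": float(x.max() - x.min()),
        "firstorder/MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "firstorder/RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean()
        ),
        "firstorder/RootMeanSquared": float(np.sqrt((x**2).mean())),
        "firstorder/Skewness": float(skew),
        "firstorder/Kurtosis": float(kurt),
        "firstorder/Variance": var,
        "firstorder/Uniformity": uniformity,
    }


# ---------------------------------------------------------------- texture


def _glcm_features_one(counts: np.ndarray, ng: int) -> dict[str, float] | None:
    total = counts.sum()
    if total == 0:
        return None
    p = counts / total
    iv = np.arange(1, ng + 1, dtype=np.float64)
    ii = iv[:, None] * np.ones(ng)[None, :]
    jj = ii.T
    px = p.sum(axis=1)
    mu = float((iv * px).sum())  # symmetric: mu_x == mu_y
    sigma2 = float(((iv - mu) ** 2 * px).sum())
    # diagonal (difference) and cross-diagonal (sum) marginals
    k_diff = np.abs(ii - jj).astype(int)
    pd_ = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=ng)
    kd = np.arange(ng, dtype=np.float64)
    k_sum = (ii + jj).astype(int)
    ps = np.bincount(k_sum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    diff_avg = float((kd * pd_).sum())

    hxy = float(-_plog2(p).sum())
    pxpy = px[:, None] * px[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-_plog2(pxpy).sum())
    hx = float(-_plog2(px).sum())
    if sigma2 > 0:
        corr = float(((ii * jj * p).sum() - mu * mu) / sigma2)
    else:
        corr = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off_diag = k_diff > 0
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu,
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-_plog2(pd_).sum()),
        "DifferenceVariance": float(((kd - diff_avg) ** 2 * pd_).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-_plog2(ps).sum()),
        "SumSquares": float(((ii - mu) ** 2 * p).sum()),
    }


def _run_type_features(mat: np.ndarray, n_voxels: int) -> dict[str, float] | None:
    """Shared formulas of the GLRLM and GLSZM families (counts matrix (Ng, J))."""
    nr = mat.sum()
    if nr == 0:
        return None
    ng, jmax = mat.shape
    iv = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    jv = np.arange(1, jmax + 1, dtype=np.float64)[None, :]
    p = mat / nr
    mu_i = float((iv * p).sum())
    mu_j = float((jv * p).sum())
    return {
        "ShortEmphasis": float((mat / jv**2).sum() / nr),
        "LongEmphasis": float((mat * jv**2).sum() / nr),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((mat.sum(axis=1) ** 2).sum() / nr**2),
        "LengthNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nr),
        "LengthNonUniformityNormalized": float((mat.sum(axis=0) ** 2).sum() / nr**2),
        "Percentage": float(nr / n_voxels),
        "GrayLevelVariance": float(((iv - mu_i) ** 2 * p).sum()),
        "LengthVariance": float(((jv - mu_j) ** 2 * p).sum()),
        "Entropy": float(-_plog2(p).sum()),
        "LowGrayLevelEmphasis": float((mat / iv**2).sum() / nr),
        "HighGrayLevelEmphasis": float((mat * iv**2).sum() / nr),
        "ShortLowGrayLevelEmphasis": float((mat / (iv**2 * jv**2)).sum() / nr),
        "ShortHighGrayLevelEmphasis": float((mat * iv**2 / jv**2).sum() / nr),
        "LongLowGrayLevelEmphasis": float((mat * jv**2 / iv**2).sum() / nr),
        "LongHighGrayLevelEmphasis": float((mat * iv**2 * jv**2).sum() / nr),
    }


_RUN_KEYS = (
    "ShortEmphasis", "LongEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "LengthNonUniformity",
    "LengthNonUniformityNormalized", "Percentage", "GrayLevelVariance",
    "LengthVariance", "Entropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "ShortLowGrayLevelEmphasis",
    "ShortHighGrayLevelEmphasis", "LongLowGrayLevelEmphasis",
    "LongHighGrayLevelEmphasis",
)


def _ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    nv = n_i.sum()
    if nv == 0:
        raise ValueError("NGTDM has no valid centre voxel")
    p = n_i / nv
    iv = np.arange(1, p.size + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())
    pi, si, li = p[present], s_i[present], iv[present]
    denom_coarse = float((pi * si).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_SENTINEL

    if ngp > 1:
        dij2 = (li[:, None] - li[None, :]) ** 2
        contrast = float(
            (pi[:, None] * pi[None, :] * dij2).sum() / (ngp * (ngp - 1)) * (si.sum() / nv)
        )
        ipi = li * pi
        busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = denom_coarse / busy_den if busy_den > 0 else 0.0
        absd = np.abs(li[:, None] - li[None, :])
        pisi = pi * si
        complexity = float(
            (absd * (pisi[:, None] + pisi[None, :]) / (pi[:, None] + pi[None, :])).sum() / nv
        )
        s_sum = float(si.sum())
        strength = (
            float(((pi[:, None] + pi[None, :]) * dij2).sum()) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": float(busyness),
        "Complexity": complexity,
        "Strength": float(strength),
    }


def _gldm_features(mat: np.ndarray) -> dict[str, float]:
    nz = mat.sum()
    if nz == 0:
        raise ValueError("empty dependence matrix")
    ng, ndep = mat.shape
    iv = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    jv = np.arange(1, ndep + 1, dtype=np.float64)[None, :]  # dependence k -> column j = k+1
    p = mat / nz
    mu_i = float((iv * p).sum())
    mu_j = float((jv * p).sum())
    return {
        "SmallDependenceEmphasis": float((mat / jv**2).sum() / nz),
        "LargeDependenceEmphasis": float((mat * jv**2).sum() / nz),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((mat.sum(axis=0) ** 2).sum() / nz**2),
        "GrayLevelVariance": float(((iv - mu_i) ** 2 * p).sum()),
        "DependenceVariance": float(((jv - mu_j) ** 2 * p).sum()),
        "DependenceEntropy": float(-_plog2(p).sum()),
        "LowGrayLevelEmphasis": float((mat / iv**2).sum() / nz),
        "HighGrayLevelEmphasis": float((mat * iv**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((mat / (iv**2 * jv**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((mat * iv**2 / jv**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((mat * jv**2 / iv**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((mat * iv**2 * jv**2).sum() / nz),
    }


def texture_features(mats: TextureMatrices) -> dict[str, float]:
    """The 73 texture features, direction-dependent classes averaged
    over the 13 directions (directions without any valid pair are skipped)."""
    ng = mats.n_levels
    out: dict[str, float] = {}

    glcm_dir = [f for f in (_glcm_features_one(c, ng) for c in mats.glcm) if f is not None]
    if not glcm_dir:
        raise ValueError("no GLCM direction with a valid pair")
    for name in _GLCM_NAMES:
        out[f"glcm/{name}"] = float(np.mean([f[name] for f in glcm_dir]))

    glrlm_dir = [
        f for f in (_run_type_features(m, mats.n_roi_voxels) for m in mats.glrlm)
        if f is not None
    ]
    for name, key in zip(_GLRLM_NAMES, _RUN_KEYS, strict=True):
        out[f"glrlm/{name}"] = float(np.mean([f[key] for f in glrlm_dir]))

    szm = _run_type_features(mats.glszm, mats.n_roi_voxels)
    if szm is None:
        raise ValueError("empty size-zone matrix")
    for name, key in zip(_GLSZM_NAMES, _RUN_KEYS, strict=True):
        out[f"glszm/{name}"] = float(szm[key])

    for name, val in _ngtdm_features(mats.ngtdm_n, mats.ngtdm_s).items():
        out[f"ngtdm/{name}"] = val

    for name, val in _gldm_features(mats.gldm).items():
        out[f"gldm/{name}"] = val

    return out


def case_feature_vector(
    img: VolumeImage, brain: BinaryMask, tumour: BinaryMask, disc: DiscretizationSpec
) -> dict[str, float]:
    """All 91 features of one (already normalized) case."""
    tumour.require_nonempty("tumour ROI")
    vals = tumour.values_in(img)
    fo = first_order_features(vals, img.voxel_volume, disc)
    droi = discretize_roi(vals, disc)
    # texture on the ROI bounding box only (boolean-index order is preserved
    # under C-order cropping)
    bbox = ndimage.find_objects(tumour.voxels.astype(np.int8))[0]
    sub_mask = tumour.voxels[bbox]
    lv = levels_volume(sub_mask, droi)
    mats = compute_texture_matrices(lv, sub_mask, n_levels=droi.n_levels)
    tex = texture_features(mats)
    vec = {**fo, **tex}
    bad = [k for k, v in vec.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features {bad}")
    return vec


def extract_feature_table(
    cases,
    norm_method: str,
    disc: DiscretizationSpec | None = None,
    *,
    mode: str | None = None,
    bins: int | None = None,
    standard: StandardHistogram | None = None,
) -> pd.DataFrame:
    """One row of 91 features + condition metadata per case.

    Either pass an explicit DiscretizationSpec, or (mode, bins): for FBS
    the bin width is then derived from this cohort's mean ROI intensity
    range *after* normalization (the cohort-level scaling rule), so the
    nominal bin count is comparable across normalization conditions.
    """
    if disc is None:
        if mode is None or bins is None:
            raise ValueError("provide either disc or (mode, bins)")
    normalized = []
    for case in cases:
        try:
            img, _ = normalize_image(case.image, case.brain, norm_method, standard=standard)
        except Exception as exc:  # noqa: BLE001 - annotate with the case id
            raise RuntimeError(f"normalization failed for case {case.case_id}: {exc}") from exc
        normalized.append(img)
    if disc is None:
        if mode == "FBS":
            mrange = mean_roi_range(
                [c.tumour.values_in(img) for c, img in zip(cases, normalized, strict=True)]
            )
            disc = DiscretizationSpec.fbs_from_cohort(bins, mrange)
        else:
            disc = DiscretizationSpec.fbn(bins)
    rows = []
    for case, img in zip(cases, normalized, strict=True):
        try:
            vec = case_feature_vector(img, case.brain, case.tumour, disc)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"feature extraction failed for case {case.case_id}: {exc}") from exc
        rows.append(
            {
                "case_id": case.case_id,
                "grade": case.grade,
                "scanner_id": case.scanner_id,
                "normalization": norm_method,
                "mode": disc.mode,
                "bins": disc.nominal_bins,
                **vec,
            }
        )
    table = pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(FEATURE_NAMES))
    if table.isna().any().any():
        raise RuntimeError("feature table contains missing values")
    return table
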