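"""Grey-level discretization of ROI intensities.

Two schemes used throughout radiomics:

* **FBS** (fixed bin size, absolute): level = floor(X / w_b) -
  floor(X_min / w_b) + 1.  The number of realized levels varies with the
  ROI intensity range.
* **FBN** (fixed bin number, relative): level = floor(N_g (X - X_min) /
  (X_max - X_min)) + 1 for X < X_max and N_g at the maximum.  FBN is
  invariant under positive affine intensity maps, which is why relative
  discretization makes texture features insensitive to affine scanner
  effects and to affine normalizations.

To compare FBS across pre-processing conditions whose intensity ranges
differ, the bin width is derived from a cohort-level scaling:
w_b = mean_Range / N_g where mean_Range is the mean ROI intensity range
over all cases of one condition.

Floor evaluations use a small relative epsilon guard so that values
sitting on a bin boundary up to floating round-off land in the upper bin
reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BIN_GRID",
    "DiscretizationSpec",
    "DiscretizedROI",
    "mean_roi_range",
    "fbs_bin_width",
    "discretize_fbs",
    "discretize_fbn",
    "discretize_roi",
]

BIN_GRID: tuple[int, ...] = (8, 16, 32, 64, 128, 256, 512, 1024)

_EPS = 1e-12


def _guarded_floor(y: np.ndarray) -> np.ndarray:
    """floor with a relative epsilon guard against boundary round-off."""
    y = np.asarray(y, dtype=np.float64)
    return np.floor(y + _EPS * (1.0 + np.abs(y)))


@dataclass(frozen=True)
class DiscretizationSpec:
    """FBS/FBN parameters for one experimental condition."""

    mode: str  # "FBS" or "FBN"
    nominal_bins: int
    bin_width: float | None = None  # FBS only
    mean_range: float | None = None  # FBS only, cohort quantity behind bin_width

    def __post_init__(self) -> None:
        if self.mode not in ("FBS", "FBN"):
            raise ValueError(f"mode must be 'FBS' or 'FBN', got {self.mode!r}")
        if self.nominal_bins < 2:
            raise ValueError(f"nominal_bins must be >= 2, got {self.nominal_bins}")
        if self.mode == "FBS":
            if self.bin_width is None or not self.bin_width > 0:
                raise ValueError(f"FBS requires bin_width > 0, got {self.bin_width}")

    @classmethod
    def fbn(cls, nominal_bins: int) -> "DiscretizationSpec":
        return cls(mode="FBN", nominal_bins=nominal_bins)

    @classmethod
    def fbs_from_cohort(cls, nominal_bins: int, mean_range: float) -> "DiscretizationSpec":
        w_b = fbs_bin_width(nominal_bins, mean_range)
        return cls(mode="FBS", nominal_bins=nominal_bins, bin_width=w_b, mean_range=mean_range)


@dataclass(frozen=True)
class DiscretizedROI:
    """Integer grey levels of ROI voxels plus the intensity extrema used."""

    levels: np.ndarray  # 1D int array, one entry per ROI voxel
    gl_min: float
    gl_max: float
    n_levels: int  # realized maximum level

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.size == 0:
            raise ValueError("empty level array")
        if lv.min() < 1:
            raise ValueError("all levels must be >= 1")
        object.__setattr__(self, "levels", lv.astype(np.int64))
        object.__setattr__(self, "n_levels", int(lv.max()))


def mean_roi_range(cohort_roi_intensities: list[np.ndarray]) -> float:
    """Mean over cases of (max - min) of ROI intensities for one condition."""
    if len(cohort_roi_intensities) == 0:
        raise ValueError("empty cohort")
    ranges = []
    for i, vals in enumerate(cohort_roi_intensities):
        vals = np.asarray(vals, dtype=np.float64)
        if vals.size < 2:
            raise ValueError(f"case {i}: ROI needs at least 2 values")
        r = float(vals.max() - vals.min())
        if r == 0:
            raise ValueError(f"case {i}: constant ROI (zero intensity range)")
        ranges.append(r)
    return float(np.mean(ranges))


def fbs_bin_width(nominal_bins: int, mean_range: float) -> float:
    """Cohort-level FBS bin width: mean_range / nominal_bins."""
    if nominal_bins < 2:
        raise ValueError(f"nominal_bins must be >= 2, got {nominal_bins}")
    if not mean_range > 0:
        raise ValueError(f"mean_range must be > 0, got {mean_range}")
    return float(mean_range) / float(nominal_bins)


def discretize_fbs(roi_values: np.ndarray, w_b: float) -> DiscretizedROI:
    """Fixed-bin-size levels: floor(X/w_b) - floor(X_min/w_b) + 1."""
    if not w_b > 0:
        raise ValueError(f"bin width must be > 0, got {w_b}")
    vals = np.asarray(roi_values, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("empty ROI")
    gl_min = float(vals.min())
    gl_max = float(vals.max())
    levels = _guarded_floor(vals / w_b) - _guarded_floor(np.array(gl_min / w_b)) + 1
    return DiscretizedROI(levels=levels, gl_min=gl_min, gl_max=gl_max, n_levels=int(levels.max()))


def discretize_fbn(roi_values: np.ndarray, n_g: int) -> DiscretizedROI:
    """Fixed-bin-number levels spanning 1..N_g; both extremes attained."""
    if n_g < 2:
        raise ValueError(f"N_g must be >= 2, got {n_g}")
    vals = np.asarray(roi_values, dtype=np.float64).ravel()
    if vals.size < 2:
        raise ValueError("ROI needs at least 2 values")
    gl_min = float(vals.min())
    gl_max = float(vals.max())
    if gl_max == gl_min:
        raise ValueError("constant ROI: fixed-bin-number discretization is undefined")
    levels = _guarded_floor(n_g * (vals - gl_min) / (gl_max - gl_min)) + 1
    levels = np.minimum(levels, n_g)
    levels[vals == gl_max] = n_g
    return DiscretizedROI(levels=levels, gl_min=gl_min, gl_max=gl_max, n_levels=int(levels.max()))


def discretize_roi(roi_values: np.ndarray, spec: DiscretizationSpec) -> DiscretizedROI:
    """Apply a DiscretizationSpec to ROI intensities."""
    if spec.mode == "FBN":
        return discretize_fbn(roi_values, spec.nominal_bins)
    return discretize_fbs(roi_values, spec.bin_width)
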