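"""Paired-acquisition robustness analysis.

Compares the two acquisitions of each subject in a paired cohort:

* **JSD** — Jensen-Shannon divergence (base-2 logarithm, hence bounded by
  [0, 1]) between brain-mask intensity histograms on a shared support;
* **ICC** — two-way random-effects, absolute-agreement, single-measurement
  intraclass correlation, ICC(2,1), from the classic mean-squares
  decomposition;
* **CCC** — Lin's concordance correlation coefficient with population
  moments;
* the robustness rule: a feature is *robust* iff both ICC and CCC are
  strictly greater than the threshold (0.8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FIRST_ORDER_NAMES, TEXTURE_NAMES
from .volume import BinaryMask, VolumeImage

__all__ = [
    "IntensityHistogram",
    "histogram_of",
    "shared_edges",
    "jensen_shannon_divergence",
    "icc",
    "ccc",
    "RobustnessReport",
    "robustness_report",
]

DEFAULT_JSD_BINS = 256


@dataclass(frozen=True)
class IntensityHistogram:
    """Probability-normalized intensity histogram on explicit bin edges."""

    edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.float64)
        prob = np.asarray(self.probabilities, dtype=np.float64)
        if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be 1D strictly increasing")
        if prob.size != edges.size - 1:
            raise ValueError("need len(probabilities) == len(edges) - 1")
        if np.any(prob < 0) or abs(prob.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be >= 0 and sum to 1")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "probabilities", prob)


def histogram_of(img: VolumeImage, mask: BinaryMask, edges: np.ndarray) -> IntensityHistogram:
    """Probability histogram of in-mask voxels; out-of-range values are
    clipped into the end bins."""
    mask.require_nonempty("histogram mask")
    edges = np.asarray(edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be 1D strictly increasing with >= 2 entries")
    vals = np.clip(mask.values_in(img), edges[0], edges[-1])
    counts, _ = np.histogram(vals, bins=edges)
    return IntensityHistogram(edges=edges, probabilities=counts / counts.sum())


def shared_edges(
    img_a: VolumeImage, img_b: VolumeImage, mask: BinaryMask, n_bins: int = DEFAULT_JSD_BINS
) -> np.ndarray:
    """Equal-width edges spanning the union of the two brain intensity ranges."""
    va = mask.values_in(img_a)
    vb = mask.values_in(img_b)
    lo = min(va.min(), vb.min())
    hi = max(va.max(), vb.max())
    if hi == lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def jensen_shannon_divergence(p: IntensityHistogram, q: IntensityHistogram) -> float:
    """JSD(p, q) = 0.5 KL(p||m) + 0.5 KL(q||m), m = (p+q)/2, base-2 logs."""
    if p.edges.shape != q.edges.shape or not np.array_equal(p.edges, q.edges):
        raise ValueError("histograms must share identical bin edges")
    pp = p.probabilities
    qq = q.probabilities
    m = 0.5 * (pp + qq)

    def _kl(a: np.ndarray, b: np.ndarray) -> float:
        pos = a > 0
        return float(np.sum(a[pos] * np.log2(a[pos] / b[pos])))

    jsd = 0.5 * _kl(pp, m) + 0.5 * _kl(qq, m)
    return float(min(max(jsd, 0.0), 1.0))


def icc(pairs: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    `pairs` is an n x 2 table (n subjects, 2 acquisitions).  Zero total
    variance (all entries equal) returns 1 by convention.
    """
    x = np.asarray(pairs, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError(f"expected an n x 2 table, got shape {x.shape}")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    grand = x.mean()
    if np.all(x == x.flat[0]):
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def ccc(pairs: np.ndarray) -> float:
    """Lin's concordance: 2 s_xy / (s_x^2 + s_y^2 + (mu_x - mu_y)^2),
    population moments.  Two identical constant columns give 1."""
    t = np.asarray(pairs, dtype=np.float64)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError(f"expected an n x 2 table, got shape {t.shape}")
    if t.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    x, y = t[:, 0], t[:, 1]
    mx, my = x.mean(), y.mean()
    sx2 = x.var()
    sy2 = y.var()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        return 1.0
    return float(2.0 * sxy / denom)


@dataclass(frozen=True)
class RobustnessReport:
    """Per-feature agreement statistics across the two acquisitions."""

    table: pd.DataFrame  # columns: feature, family, icc, ccc, robust
    threshold: float

    @property
    def robust_features(self) -> list[str]:
        return list(self.table.loc[self.table["robust"], "feature"])

    @property
    def counts(self) -> dict[str, dict[str, int]]:
        """Robust / total counts per feature family and overall."""
        out: dict[str, dict[str, int]] = {}
        fo = self.table["feature"].isin(FIRST_ORDER_NAMES)
        tex = self.table["feature"].isin(TEXTURE_NAMES)
        out["first_order"] = {
            "robust": int(self.table.loc[fo, "robust"].sum()),
            "total": int(fo.sum()),
        }
        out["texture"] = {
            "robust": int(self.table.loc[tex, "robust"].sum()),
            "total": int(tex.sum()),
        }
        for family in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
            sel = self.table["family"] == family
            out[family] = {
                "robust": int(self.table.loc[sel, "robust"].sum()),
                "total": int(sel.sum()),
            }
        out["all"] = {
            "robust": int(self.table["robust"].sum()),
            "total": int(len(self.table)),
        }
        return out


def robustness_report(
    table_a: pd.DataFrame, table_b: pd.DataFrame, threshold: float = 0.8
) -> RobustnessReport:
    """ICC/CCC per feature across two feature tables paired by case id.

    A feature is robust iff ICC > threshold AND CCC > threshold (strict)."""
    a = table_a.set_index("case_id").sort_index()
    b = table_b.set_index("case_id").sort_index()
    if list(a.index) != list(b.index):
        raise ValueError("tables contain different case ids; cannot pair acquisitions")
    rows = []
    for feat in FEATURE_NAMES:
        if feat not in a.columns or feat not in b.columns:
            raise ValueError(f"feature column {feat!r} missing from a table")
        pairs = np.column_stack([a[feat].to_numpy(float), b[feat].to_numpy(float)])
        i = icc(pairs)
        c = ccc(pairs)
        rows.append(
            {
                "feature": feat,
                "family": feat.split("/", 1)[0],
                "icc": i,
                "ccc": c,
                "robust": bool(i > threshold and c > threshold),
            }
        )
    return RobustnessReport(table=pd.DataFrame(rows), threshold=float(threshold))
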