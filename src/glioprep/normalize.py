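"""Intensity normalization for brain MR volumes.

Three methods, all computed from brain-mask statistics and applied to every
voxel of the image:

* **Z-Score** — subtract the brain mean and divide by the brain standard
  deviation (population convention), so the brain histogram becomes
  zero-mean / unit-sd.
* **WhiteStripe** — same affine form, but the reference statistics come
  from the "white stripe": voxels within +/-5% (on the intensity axis) of
  the automatically detected normal-appearing-white-matter mode of the
  brain histogram.
* **Nyul** — piecewise-linear histogram matching: a standard histogram is
  learned by averaging landmark percentiles (default
  C_L = [1,10,20,30,40,50,60,70,80,90,99]) over a training set, and each
  image's landmarks are then mapped exactly onto the standard ones, with
  the end segments' slopes extended beyond the outer landmarks.

No tumour exclusion is applied: brain-mask statistics include tumour
voxels (the tumour is a small fraction of the brain).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .volume import BinaryMask, VolumeImage

__all__ = [
    "NormalizationParams",
    "StandardHistogram",
    "zscore_normalize",
    "estimate_white_stripe",
    "whitestripe_normalize",
    "learn_standard_histogram",
    "nyul_transform",
    "normalize_image",
    "DEFAULT_LANDMARKS",
    "DEFAULT_SCALE",
]

DEFAULT_LANDMARKS: tuple[float, ...] = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)
DEFAULT_SCALE: tuple[float, float] = (0.0, 100.0)


@dataclass(frozen=True)
class StandardHistogram:
    """Learned landmark model for piecewise-linear histogram matching."""

    landmarks_pct: tuple[float, ...]
    landmarks_std: tuple[float, ...]
    scale: tuple[float, float] = DEFAULT_SCALE

    def __post_init__(self) -> None:
        pct = tuple(float(p) for p in self.landmarks_pct)
        std = tuple(float(v) for v in self.landmarks_std)
        if len(pct) != len(std):
            raise ValueError("landmarks_pct and landmarks_std must have equal length")
        if len(pct) < 2:
            raise ValueError("need at least two landmarks")
        if not all(0 < a < b <= 100 for a, b in zip(pct, pct[1:], strict=False)):
            raise ValueError(f"landmark percentiles must be strictly increasing in (0,100], got {pct}")
        if not all(a < b for a, b in zip(std, std[1:], strict=False)):
            raise ValueError(f"standard landmarks must be strictly increasing, got {std}")
        object.__setattr__(self, "landmarks_pct", pct)
        object.__setattr__(self, "landmarks_std", std)
        object.__setattr__(self, "scale", (float(self.scale[0]), float(self.scale[1])))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "landmarks_pct": list(self.landmarks_pct),
                    "landmarks_std": list(self.landmarks_std),
                    "scale": list(self.scale),
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "StandardHistogram":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            landmarks_pct=tuple(d["landmarks_pct"]),
            landmarks_std=tuple(d["landmarks_std"]),
            scale=tuple(d["scale"]),
        )


@dataclass(frozen=True)
class NormalizationParams:
    """Record of the fitted transform.

    mu/sigma hold the brain (Z-Score) or stripe (WhiteStripe) statistics;
    `standard` is present only for the Nyul method.
    """

    method: str
    mu: float | None = None
    sigma: float | None = None
    standard: StandardHistogram | None = None

    def __post_init__(self) -> None:
        if self.method not in ("none", "zscore", "whitestripe", "nyul"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method in ("zscore", "whitestripe") and not (self.sigma and self.sigma > 0):
            raise ValueError(f"{self.method} requires sigma > 0, got {self.sigma}")
        if (self.method == "nyul") != (self.standard is not None):
            raise ValueError("standard histogram present iff method is 'nyul'")


def zscore_normalize(img: VolumeImage, brain: BinaryMask) -> tuple[VolumeImage, NormalizationParams]:
    """(I - mu_brain) / sigma_brain, statistics over brain voxels only."""
    brain.require_nonempty("brain mask")
    vals = brain.values_in(img)
    mu = float(vals.mean())
    sigma = float(vals.std())  # population (divide by N)
    if sigma == 0:
        raise ValueError("constant image inside the brain mask: sigma is zero")
    out = img.with_voxels((img.voxels - mu) / sigma)
    return out, NormalizationParams(method="zscore", mu=mu, sigma=sigma)


def estimate_white_stripe(
    img: VolumeImage,
    brain: BinaryMask,
    *,
    smooth_sigma_bins: float = 2.0,
    prominence_frac: float = 0.05,
    contrast: str = "t1",
) -> tuple[float, float, BinaryMask]:
    """Locate the NAWM mode and the +/-5% white stripe around it.

    The brain histogram is binned with a Freedman-Diaconis-like width,
    smoothed with a Gaussian, and its prominent local maxima are found.
    For a T1-like contrast the *last* (highest-intensity) prominent mode is
    taken as white matter; for ``contrast='t2'`` the largest mode is used.
    The stripe is the set of brain voxels with intensity within +/-5% of
    the mode on the intensity axis (for a non-positive mode: a symmetric
    band of half-width 0.05 x the p1-p99 brain intensity spread).

    Returns (mu_ws, sigma_ws, stripe_mask).
    """
    brain.require_nonempty("brain mask")
    vals = brain.values_in(img)
    n = vals.size
    iqr = np.subtract(*np.percentile(vals, [75, 25]))
    span = vals.max() - vals.min()
    if span == 0:
        # constant image: the mode is the constant itself
        mu_mode = float(vals[0])
        width = 1.0
    else:
        width = 2.0 * iqr / n ** (1.0 / 3.0)
        if width <= 0:
            width = span / 256.0
        n_bins = int(np.clip(np.ceil(span / width), 32, 2048))
        counts, edges = np.histogram(vals, bins=n_bins)
        smooth = ndimage.gaussian_filter1d(counts.astype(float), smooth_sigma_bins)
        peaks, _ = signal.find_peaks(smooth, prominence=prominence_frac * smooth.max())
        if peaks.size == 0:
            # fall back to the global maximum of the smoothed histogram
            peaks = np.array([int(np.argmax(smooth))])
        if contrast == "t2":
            peak = peaks[np.argmax(smooth[peaks])]
        else:
            peak = peaks[-1]
        mu_mode = float(0.5 * (edges[peak] + edges[peak + 1]))

    if mu_mode > 0:
        lo, hi = 0.95 * mu_mode, 1.05 * mu_mode
    else:
        half = 0.05 * float(np.subtract(*np.percentile(vals, [99, 1])))
        half = half if half > 0 else 0.5
        lo, hi = mu_mode - half, mu_mode + half
    stripe_vox = brain.voxels & (img.voxels >= lo) & (img.voxels <= hi)
    if not stripe_vox.any():
        raise ValueError(
            f"white stripe is empty: no brain voxel in [{lo:.3g}, {hi:.3g}] around mode {mu_mode:.3g}"
        )
    stripe = BinaryMask(voxels=stripe_vox, spacing=brain.spacing)
    svals = img.voxels[stripe_vox]
    mu_ws = float(svals.mean())
    sigma_ws = float(svals.std())
    return mu_ws, sigma_ws, stripe


def whitestripe_normalize(
    img: VolumeImage, brain: BinaryMask, **kwargs
) -> tuple[VolumeImage, NormalizationParams]:
    """(I - mu_ws) / sigma_ws using the detected white-stripe statistics."""
    mu_ws, sigma_ws, _stripe = estimate_white_stripe(img, brain, **kwargs)
    if sigma_ws == 0:
        raise ValueError("white-stripe standard deviation is zero")
    out = img.with_voxels((img.voxels - mu_ws) / sigma_ws)
    return out, NormalizationParams(method="whitestripe", mu=mu_ws, sigma=sigma_ws)


def _image_landmarks(img: VolumeImage, brain: BinaryMask, landmarks_pct) -> np.ndarray:
    vals = brain.values_in(img)
    lm = np.percentile(vals, landmarks_pct)  # linear interpolation convention
    return np.asarray(lm, dtype=np.float64)


def learn_standard_histogram(
    images: list[VolumeImage],
    brains: list[BinaryMask],
    landmarks_pct=DEFAULT_LANDMARKS,
    scale: tuple[float, float] = DEFAULT_SCALE,
) -> StandardHistogram:
    """Average affinely rescaled landmark percentiles over a training set.

    Per image the landmark percentiles over brain voxels are computed and
    the [first, last] landmark interval is mapped affinely onto `scale`;
    the mapped landmarks are then averaged across images.
    """
    if len(images) == 0:
        raise ValueError("need at least one training image")
    if len(images) != len(brains):
        raise ValueError("images and brains must have equal length")
    s_min, s_max = float(scale[0]), float(scale[1])
    if not s_min < s_max:
        raise ValueError(f"scale must be increasing, got {scale}")
    acc = np.zeros(len(landmarks_pct), dtype=np.float64)
    for img, brain in zip(images, brains, strict=True):
        lm = _image_landmarks(img, brain, landmarks_pct)
        if lm[-1] <= lm[0]:
            raise ValueError("degenerate image: first and last landmark percentiles coincide")
        mapped = s_min + (lm - lm[0]) * (s_max - s_min) / (lm[-1] - lm[0])
        acc += mapped
    landmarks_std = acc / len(images)
    return StandardHistogram(
        landmarks_pct=tuple(landmarks_pct),
        landmarks_std=tuple(landmarks_std),
        scale=(s_min, s_max),
    )


def nyul_transform(
    img: VolumeImage, brain: BinaryMask, std: StandardHistogram
) -> tuple[VolumeImage, NormalizationParams]:
    """Piecewise-linear map sending the image's landmarks onto the standard ones.

    Monotone non-decreasing; intensities beyond the outer landmarks are
    extended with the end segments' slopes.
    """
    lm = _image_landmarks(img, brain, std.landmarks_pct)
    if not np.all(np.diff(lm) > 0):
        raise ValueError(
            "image landmark percentiles are not strictly increasing (intensity ties); "
            f"landmarks={lm.tolist()}"
        )
    std_lm = np.asarray(std.landmarks_std)
    x = img.voxels
    out = np.interp(x, lm, std_lm)
    lo_slope = (std_lm[1] - std_lm[0]) / (lm[1] - lm[0])
    hi_slope = (std_lm[-1] - std_lm[-2]) / (lm[-1] - lm[-2])
    below = x < lm[0]
    above = x > lm[-1]
    out[below] = std_lm[0] + (x[below] - lm[0]) * lo_slope
    out[above] = std_lm[-1] + (x[above] - lm[-1]) * hi_slope
    return img.with_voxels(out), NormalizationParams(method="nyul", standard=std)


def normalize_image(
    img: VolumeImage,
    brain: BinaryMask,
    method: str,
    standard: StandardHistogram | None = None,
) -> tuple[VolumeImage, NormalizationParams]:
    """Dispatch a normalization method by name ('none' is the identity)."""
    if method == "none":
        return img, NormalizationParams(method="none")
    if method == "zscore":
        return zscore_normalize(img, brain)
    if method == "whitestripe":
        return whitestripe_normalize(img, brain)
    if method == "nyul":
        if standard is None:
            raise ValueError("nyul normalization requires a learned StandardHistogram")
        return nyul_transform(img, brain, standard)
    raise ValueError(f"unknown normalization method {method!r}")
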