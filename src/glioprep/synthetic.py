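"""Synthetic brain phantoms with paired-scanner and two-grade cohorts.

The generator stands in for two kinds of real acquisitions:

* a *paired* cohort — one anatomy per subject imaged under two simulated
  scanners that differ by an intensity gain/offset, an optional smooth
  multiplicative bias field, an optional gamma non-linearity, and additive
  Gaussian noise (test-retest / inter-device setting);
* a *graded* cohort — low- and high-grade tumours whose grades differ in
  tumour intensity statistics (mean shift above white matter) and texture
  heterogeneity (variance and correlation length of a stationary Gaussian
  random field inside the ROI), each case acquired under its own
  heterogeneous scanner effect (multi-site setting).

Anatomy is a three-compartment ellipsoidal brain (CSF < GM < WM mean
intensity, WM the largest compartment so a white-matter mode is detectable
in the histogram) with a spherical tumour occupying on average 7.5% of the
brain volume (sd 3.7%).  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage, stats

from .volume import BinaryMask, VolumeImage

__all__ = [
    "ScannerEffect",
    "PhantomCase",
    "CohortConfig",
    "make_brain_phantom",
    "apply_scanner_effect",
    "generate_paired_cohort",
    "generate_graded_cohort",
    "case_seed",
    "write_case",
]


@dataclass(frozen=True)
class ScannerEffect:
    """Parameters of a simulated acquisition: out = gain * I^gamma * bias + offset + noise."""

    gain: float = 1.0
    offset: float = 0.0
    bias_amplitude: float = 0.0
    noise_sd: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.bias_amplitude < 0:
            raise ValueError(f"bias_amplitude must be >= 0, got {self.bias_amplitude}")

    @property
    def is_identity(self) -> bool:
        return (
            self.gain == 1.0
            and self.offset == 0.0
            and self.bias_amplitude == 0.0
            and self.noise_sd == 0.0
            and self.gamma == 1.0
        )


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic acquisition: image + brain/tumour masks + labels."""

    case_id: str
    image: VolumeImage
    brain: BinaryMask
    tumour: BinaryMask
    grade: str
    scanner_id: str
    seed: int
    effect: ScannerEffect | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grade not in ("low", "high"):
            raise ValueError(f"grade must be 'low' or 'high', got {self.grade!r}")
        self.tumour.require_nonempty("tumour mask")
        self.brain.require_nonempty("brain mask")
        if not self.tumour.is_subset_of(self.brain):
            raise ValueError("tumour mask must be a subset of the brain mask")

    @property
    def tumour_fraction(self) -> float:
        return self.tumour.n_voxels / self.brain.n_voxels


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohorts.

    The defaults are the conditions the analysis assumes: 20 paired
    subjects, 108 low-grade + 135 high-grade cases, a 64^3 grid at 1 mm,
    tumour fraction ~ 7.5 +/- 3.7 % of brain.  Paired-cohort scanner
    effects are affine (gain U[0.6, 1.8], offset U[-20, 20], noise 2% of
    the WM mean); graded-cohort effects are wider and, by default, the
    gain is anti-correlated with grade so that raw intensities actively
    mislead a grade classifier while normalization removes the confound.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    # tissue intensity model (T1-like contrast)
    csf_mean: float = 30.0
    gm_mean: float = 80.0
    wm_mean: float = 120.0
    tissue_sd: float = 4.0

    # tumour geometry
    tumour_fraction_mean: float = 0.075
    tumour_fraction_sd: float = 0.037
    tumour_fraction_bounds: tuple[float, float] = (0.02, 0.16)

    # grade effect sizes
    tumour_mean_shift: tuple[float, float] = (15.0, 30.0)   # (low, high) above WM mean
    tumour_field_sd: tuple[float, float] = (6.0, 12.0)      # (low, high)
    tumour_corr_length: tuple[float, float] = (2.5, 1.2)    # (low, high), voxels
    tumour_mean_jitter_sd: float = 8.0
    tumour_sd_jitter_frac: float = 0.2

    # cohort sizes
    n_paired: int = 20
    n_low_grade: int = 108
    n_high_grade: int = 135

    # paired-cohort scanner effect ranges (affine by default)
    paired_gain_range: tuple[float, float] = (0.6, 1.8)
    paired_offset_range: tuple[float, float] = (-20.0, 20.0)
    paired_bias_amplitude_range: tuple[float, float] = (0.0, 0.0)
    paired_gamma_range: tuple[float, float] = (1.0, 1.0)
    paired_noise_sd: float = 2.4

    # graded-cohort scanner effect ranges (multi-site emulation)
    graded_gain_range: tuple[float, float] = (0.5, 2.0)
    graded_offset_range: tuple[float, float] = (-30.0, 30.0)
    graded_bias_amplitude_range: tuple[float, float] = (0.0, 0.0)
    graded_gamma_range: tuple[float, float] = (1.0, 1.0)
    graded_noise_sd: float = 2.4
    gain_grade_confounding: float = 0.25

    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.shape):
            raise ValueError(f"grid axes must be >= 8, got {self.shape}")
        if self.n_paired < 2:
            raise ValueError("n_paired must be >= 2")
        if self.n_low_grade < 2 or self.n_high_grade < 2:
            raise ValueError("grade counts must be >= 2")
        if not (self.csf_mean < self.gm_mean < self.wm_mean):
            raise ValueError("tissue means must satisfy CSF < GM < WM")
        lo, hi = self.tumour_fraction_bounds
        if not (0 < lo < hi < 1):
            raise ValueError("tumour fraction bounds must satisfy 0 < lo < hi < 1")
        if not (0 <= self.gain_grade_confounding < 1):
            raise ValueError("gain_grade_confounding must be in [0, 1)")

    def shift_for(self, grade: str) -> float:
        return self.tumour_mean_shift[0 if grade == "low" else 1]

    def field_sd_for(self, grade: str) -> float:
        return self.tumour_field_sd[0 if grade == "low" else 1]

    def corr_length_for(self, grade: str) -> float:
        return self.tumour_corr_length[0 if grade == "low" else 1]


def case_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-case 31-bit seed spawned from the master seed."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def _ellipsoid_radius(shape: tuple[int, int, int], semiaxes: np.ndarray) -> np.ndarray:
    """Normalized ellipsoidal radius (1 at the brain surface) on the grid."""
    grids = np.ogrid[[slice(0, s) for s in shape]]
    centre = [(s - 1) / 2.0 for s in shape]
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semiaxes))
    return np.sqrt(rho2)


def make_brain_phantom(config: CohortConfig, grade: str, seed: int) -> PhantomCase:
    """Generate one noiseless anatomy: ellipsoidal brain, 3 tissue shells, tumour.

    Tumour texture is a stationary correlated Gaussian field whose variance
    and correlation length depend on grade (high grade: larger variance,
    shorter correlation length).  Deterministic given (config, grade, seed).
    """
    if grade not in ("low", "high"):
        raise ValueError(f"grade must be 'low' or 'high', got {grade!r}")
    rng = np.random.default_rng(seed)
    shape = config.shape

    # brain geometry: ellipsoid with mild per-case jitter
    base_axes = 0.42 * np.asarray(shape, dtype=float)
    semiaxes = base_axes * rng.uniform(0.95, 1.05, size=3)
    rho = _ellipsoid_radius(shape, semiaxes)
    brain = rho <= 1.0

    # tissue shells: central CSF, cortical GM rim, WM bulk (largest)
    csf = brain & (rho < 0.25)
    gm = brain & (rho > 0.82)
    wm = brain & ~csf & ~gm

    voxels = np.zeros(shape, dtype=np.float64)
    for mask, mean in ((csf, config.csf_mean), (gm, config.gm_mean), (wm, config.wm_mean)):
        voxels[mask] = mean + config.tissue_sd * rng.standard_normal(int(mask.sum()))

    # tumour geometry: sphere fully inside the brain
    lo, hi = config.tumour_fraction_bounds
    a = (lo - config.tumour_fraction_mean) / config.tumour_fraction_sd
    b = (hi - config.tumour_fraction_mean) / config.tumour_fraction_sd
    fraction = float(
        stats.truncnorm.rvs(
            a, b, loc=config.tumour_fraction_mean, scale=config.tumour_fraction_sd,
            random_state=rng,
        )
    )
    brain_volume = int(brain.sum())
    radius = (3.0 * fraction * brain_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    if radius < 2.0 or radius >= 0.9 * semiaxes.min():
        raise ValueError(
            f"grid {shape} too small to fit brain plus tumour of radius {radius:.1f}"
        )
    centre_grid = np.asarray([(s - 1) / 2.0 for s in shape])
    tumour = None
    for _ in range(200):
        # candidate centre inside normalized radius 0.4, conservatively away
        # from the brain surface so the whole sphere fits
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.linalg.norm(u) > 1.0:
            continue
        centre = centre_grid + 0.4 * u * semiaxes
        if radius >= (1.0 - np.sqrt(sum((0.4 * u) ** 2))) * semiaxes.min() - 1.0:
            continue
        grids = np.ogrid[[slice(0, s) for s in shape]]
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
        cand = dist2 <= radius**2
        if cand.any() and np.all(brain[cand]):
            tumour = cand
            break
    if tumour is None:
        raise ValueError(f"could not place a tumour of radius {radius:.1f} inside the brain")

    # tumour texture: correlated Gaussian random field, grade-dependent
    mean_jitter = config.tumour_mean_jitter_sd * rng.standard_normal()
    sd_jitter = 1.0 + config.tumour_sd_jitter_frac * rng.standard_normal()
    sd_jitter = max(sd_jitter, 0.2)
    target_mean = config.wm_mean + config.shift_for(grade) + mean_jitter
    target_sd = config.field_sd_for(grade) * sd_jitter
    white = rng.standard_normal(shape)
    fld = ndimage.gaussian_filter(white, sigma=config.corr_length_for(grade), mode="wrap")
    fld_in = fld[tumour]
    fld_sd = float(fld_in.std())
    if fld_sd <= 0:
        raise ValueError("degenerate tumour texture field")
    voxels[tumour] = target_mean + (fld[tumour] - fld_in.mean()) * (target_sd / fld_sd)

    spacing = config.spacing
    case = PhantomCase(
        case_id=f"case-{seed}",
        image=VolumeImage(voxels=voxels, spacing=spacing),
        brain=BinaryMask(voxels=brain, spacing=spacing),
        tumour=BinaryMask(voxels=tumour, spacing=spacing),
        grade=grade,
        scanner_id="anatomy",
        seed=int(seed),
        meta={
            "tumour_fraction_target": fraction,
            "tumour_fraction": float(tumour.sum() / brain.sum()),
            "tissue_means": {
                "csf": config.csf_mean, "gm": config.gm_mean, "wm": config.wm_mean,
            },
            "compartment_voxels": {
                "csf": int(csf.sum()), "gm": int(gm.sum()), "wm": int(wm.sum()),
            },
            "tumour_mean": float(target_mean),
            "tumour_sd": float(target_sd),
        },
    )
    return case


def _bias_field(shape, brain: np.ndarray, amplitude: float, rng) -> np.ndarray:
    """Smooth multiplicative field: low-order separable polynomials, mean 1 over brain."""
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    # Legendre-like terms up to order 2 per axis, constant term excluded
    basis_1d = [
        [np.ones_like(c), c, 0.5 * (3 * c**2 - 1)] for c in coords
    ]
    fld = np.zeros(shape, dtype=np.float64)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                if i == j == k == 0:
                    continue
                c = rng.uniform(-1.0, 1.0)
                fld += c * np.multiply.outer(
                    np.multiply.outer(basis_1d[0][i], basis_1d[1][j]), basis_1d[2][k]
                )
    peak = np.abs(fld[brain]).max()
    if peak == 0:
        return np.ones(shape)
    fld = 1.0 + amplitude * fld / peak
    fld /= fld[brain].mean()
    return fld


def apply_scanner_effect(
    img: VolumeImage, brain: BinaryMask, eff: ScannerEffect, seed: int
) -> VolumeImage:
    """Simulate an acquisition: gain * I^gamma * bias(x) + offset + noise.

    The bias field is a smooth low-order polynomial field renormalized to
    mean 1 over the brain.  With gamma=1, bias_amplitude=0 and noise_sd=0
    the map is exactly affine.  Deterministic given seed.
    """
    if img.shape != brain.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs brain {brain.shape}")
    rng = np.random.default_rng(seed)
    out = img.voxels
    if eff.gamma != 1.0:
        out = np.power(np.clip(out, 0.0, None), eff.gamma)
    if eff.bias_amplitude > 0:
        out = out * _bias_field(img.shape, brain.voxels, eff.bias_amplitude, rng)
    out = eff.gain * out + eff.offset
    if eff.noise_sd > 0:
        out = out + rng.normal(0.0, eff.noise_sd, size=img.shape)
    return img.with_voxels(out)


def _draw_effect(rng, gain_range, offset_range, bias_range, gamma_range, noise_sd,
                 gain_scale: float = 1.0) -> ScannerEffect:
    return ScannerEffect(
        gain=float(rng.uniform(*gain_range)) * gain_scale,
        offset=float(rng.uniform(*offset_range)),
        bias_amplitude=float(rng.uniform(*bias_range)),
        gamma=float(rng.uniform(*gamma_range)),
        noise_sd=float(noise_sd),
    )


def generate_paired_cohort(config: CohortConfig) -> list[tuple[PhantomCase, PhantomCase]]:
    """n_paired subjects, each with one anatomy acquired under two scanners.

    Masks are shared between the two members of a pair (the analysis
    intersects the two acquisitions' masks, which for a common anatomy is
    the anatomy's own mask).
    """
    pairs = []
    for i in range(config.n_paired):
        anat_seed = case_seed(config.master_seed, 1, i)
        anatomy = make_brain_phantom(config, grade="low", seed=anat_seed)
        members = []
        for s, scanner in enumerate(("A", "B")):
            eff_seed = case_seed(config.master_seed, 2, i, s)
            eff_rng = np.random.default_rng(eff_seed)
            eff = _draw_effect(
                eff_rng,
                config.paired_gain_range,
                config.paired_offset_range,
                config.paired_bias_amplitude_range,
                config.paired_gamma_range,
                config.paired_noise_sd,
            )
            acq = apply_scanner_effect(anatomy.image, anatomy.brain, eff, seed=eff_seed)
            members.append(
                replace(
                    anatomy,
                    case_id=f"pair{i:03d}",
                    image=acq,
                    scanner_id=scanner,
                    effect=eff,
                    meta={**anatomy.meta, "effect_seed": eff_seed},
                )
            )
        pairs.append(tuple(members))
    return pairs


def generate_graded_cohort(config: CohortConfig) -> list[PhantomCase]:
    """n_low + n_high cases, each under its own heterogeneous scanner effect.

    With gain_grade_confounding = r, low-grade gains are scaled by (1 + r)
    and high-grade gains by (1 - r): the scanner gain is anti-correlated
    with the (brighter-tumour) high grade, so raw intensity statistics
    mislead the classifier unless the images are normalized.
    """
    cases = []
    labels = [("low", i) for i in range(config.n_low_grade)] + [
        ("high", i) for i in range(config.n_high_grade)
    ]
    for idx, (grade, i) in enumerate(labels):
        anat_seed = case_seed(config.master_seed, 3, idx)
        anatomy = make_brain_phantom(config, grade=grade, seed=anat_seed)
        eff_seed = case_seed(config.master_seed, 4, idx)
        eff_rng = np.random.default_rng(eff_seed)
        r = config.gain_grade_confounding
        gain_scale = (1.0 + r) if grade == "low" else (1.0 - r)
        eff = _draw_effect(
            eff_rng,
            config.graded_gain_range,
            config.graded_offset_range,
            config.graded_bias_amplitude_range,
            config.graded_gamma_range,
            config.graded_noise_sd,
            gain_scale=gain_scale,
        )
        acq = apply_scanner_effect(anatomy.image, anatomy.brain, eff, seed=eff_seed)
        cases.append(
            replace(
                anatomy,
                case_id=f"{grade}{i:03d}",
                image=acq,
                scanner_id=f"site{idx % 7}",
                effect=eff,
                meta={**anatomy.meta, "effect_seed": eff_seed},
            )
        )
    return cases


def write_case(case: PhantomCase, out_dir) -> None:
    """Persist one case as NIfTI volumes plus a JSON manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    case.image.save(out / f"{case.case_id}_{case.scanner_id}_image.nii.gz")
    case.brain.save(out / f"{case.case_id}_brain.nii.gz")
    case.tumour.save(out / f"{case.case_id}_tumour.nii.gz")
    manifest = {
        "case_id": case.case_id,
        "grade": case.grade,
        "scanner_id": case.scanner_id,
        "seed": case.seed,
        "effect": asdict(case.effect) if case.effect is not None else None,
        "meta": case.meta,
    }
    with open(out / f"{case.case_id}_{case.scanner_id}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
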