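"""Synthetic fat-fraction phantoms and cohorts.

The generator produces what the analysis assumes, not anatomy: each ROI is a
smoothed Gaussian random field with controllable mean, SD, skewness and
spatial correlation length, clipped to the physical 0-100 % range. A subject
phantom contains two tube-like erector-spinae ROIs and two tube-like psoas
ROIs of deliberately unequal left/right volume plus four ellipsoidal
vertebral bodies. Compartments of one subject share a latent factor with
loading lambda, so cross-compartment correlations of heterogeneity
(variance of the within-ROI distribution) are controllable; demographics are
drawn from truncated normals with sex-specific moments.

Default texture targets (per-sex mean PDFF, within-ROI SD = sqrt of the
global variance, skewness) and demographic moments follow the reference
healthy-cohort values the package is designed to emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .io_maps import PDFFVolume, ROIMask, write_mask, write_volume

#: Shared-factor loading calibrated (by ``calibrate_shared_loading``) so the
#: partial correlation of Variance(global) between lumbar spine and muscles
#: lands near 0.6 in default cohorts.
DEFAULT_SHARED_LOADING = 0.93

LABEL_TABLE = {
    1: "ES_left", 2: "ES_right", 3: "PS_left", 4: "PS_right",
    5: "L1", 6: "L2", 7: "L3", 8: "L4",
}


@dataclass
class TextureSpec:
    """Target first/second-order structure of one compartment's voxel field."""

    mean: float                    # target mean PDFF, percent (pre-clip)
    sd: float                      # target within-ROI SD, percent (pre-clip)
    skew: float = 0.0              # target skewness of the voxel distribution
    corr_length_mm: float = 1.2    # Gaussian kernel sigma of spatial smoothing
    shared_loading: float = DEFAULT_SHARED_LOADING  # lambda in [0, 1]
    sd_rel_jitter: float = 0.2     # between-subject relative SD variation
    mean_sd: float = 0.0           # between-subject SD of the compartment mean
    anchored: bool = False         # gamma anchored at 0 %: skew follows 2*SD/mean

    def __post_init__(self) -> None:
        if self.sd < 0 or self.corr_length_mm < 0 or self.mean_sd < 0:
            raise ValueError("sd, mean_sd and corr_length_mm must be >= 0")
        if not 0.0 <= self.shared_loading <= 1.0:
            raise ValueError("shared_loading must be in [0, 1]")


# Per-sex defaults. Means and SDs (= sqrt of the global variance) follow the
# reference cohort. Muscle voxel distributions are modeled as gamma-like,
# anchored at 0 % PDFF: skew = 2*SD/mean, the minimum skewness a nonnegative
# gamma with that mean and SD can have. (The reference cohort's printed
# near-zero muscle skewness is infeasible for any [0,100]-supported
# distribution with CV > 1, so feasible anchored values are used instead.)
# Vertebral marrow sits mid-range, where the printed skewness is feasible.
DEFAULT_SPECS: dict[str, dict[str, TextureSpec]] = {
    "male": {
        "ES": TextureSpec(mean=7.79, sd=11.80, skew=3.03, mean_sd=6.88, anchored=True),
        "PS": TextureSpec(mean=3.63, sd=9.78, skew=5.39, mean_sd=5.38, anchored=True),
        "LS": TextureSpec(mean=33.40, sd=6.40, skew=-0.38, mean_sd=6.77),
    },
    "female": {
        "ES": TextureSpec(mean=16.11, sd=10.85, skew=1.35, mean_sd=9.27, anchored=True),
        "PS": TextureSpec(mean=5.39, sd=8.14, skew=3.02, mean_sd=4.17, anchored=True),
        "LS": TextureSpec(mean=33.08, sd=5.93, skew=-0.06, mean_sd=10.30),
    },
}

DEFAULT_DEMOGRAPHICS = {
    "male": {"age": (54.79, 29.53), "bmi": (26.94, 4.62)},
    "female": {"age": (38.74, 16.73), "bmi": (24.87, 4.12)},
}


@dataclass
class CohortSpec:
    n_male: int = 13
    n_female: int = 31
    specs: dict[str, dict[str, TextureSpec]] = field(
        default_factory=lambda: {s: dict(d) for s, d in DEFAULT_SPECS.items()})
    demographics: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {s: dict(d) for s, d in DEFAULT_DEMOGRAPHICS.items()})
    age_slope: float = 0.0         # optional confounding: d(mean PDFF)/d(age-45)
    shape: tuple[int, int, int] = (40, 40, 32)
    spacing: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_male + self.n_female < 4:
            raise ValueError("cohort needs at least 4 subjects")
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("group sizes must be non-negative")


# ---------------------------------------------------------------------------
# skewness warp: gamma-quantile (Gaussian-copula) transform

def skew_warp(z: np.ndarray, target_skew: float) -> np.ndarray:
    """Monotone warp of a standard-normal field to the given skewness.

    Maps z through the standard-normal CDF onto the quantiles of a gamma
    distribution with shape k = (2/skew)^2 (whose skewness is exactly
    2/sqrt(k)), standardized to zero mean and unit variance; negative target
    skewness mirrors the transform. Monotonicity preserves the field's
    spatial rank structure.
    """
    if abs(target_skew) < 1e-12:
        return z
    k = (2.0 / abs(target_skew)) ** 2
    u = np.clip(sps.norm.cdf(z), 1e-15, 1.0 - 1e-15)
    y = (sps.gamma.ppf(u, a=k) - k) / np.sqrt(k)
    return y if target_skew > 0 else -y


_SMOOTH_SD_CACHE: dict[float, float] = {}


def _smoothing_sd(sigma_vox: float) -> float:
    """SD of unit white noise after 3D Gaussian smoothing (analytic, so the
    field is standardized in population rather than per-sample — essential
    for heavy-tailed warps, where empirical standardization is spike-driven).
    """
    key = round(float(sigma_vox), 9)
    if key not in _SMOOTH_SD_CACHE:
        r = max(1, int(np.ceil(4 * sigma_vox)))
        x = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * (x / sigma_vox) ** 2)
        k1 = k1 / k1.sum()
        _SMOOTH_SD_CACHE[key] = float(np.sqrt(np.sum(k1**2)) ** 3)
    return _SMOOTH_SD_CACHE[key]


def textured_field(
    shape: tuple[int, int, int],
    spacing: float,
    spec: TextureSpec,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Smoothed, skew-warped Gaussian random field with the spec's moments.

    White noise is convolved with a Gaussian kernel of sigma
    ``corr_length_mm`` (in mm) and standardized analytically, skew-warped
    with the monotone gamma-quantile transform (standardized by the gamma's
    own moments), scaled to the target mean/SD, and clipped to [0, 100].
    The targets are population moments, defined pre-clip; clipping is
    negligible when the implied distribution respects the physical bounds
    (e.g. anchored gamma shapes for low-mean, high-SD muscle).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    z = rng.standard_normal(shape)
    sigma_vox = spec.corr_length_mm / spacing
    if sigma_vox > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma_vox, mode="constant")
        z = z / _smoothing_sd(sigma_vox)
    if spec.skew != 0.0:
        z = skew_warp(z, spec.skew)
    return np.clip(spec.mean + spec.sd * z, 0.0, 100.0)


# ---------------------------------------------------------------------------
# phantom geometry

_MASK_CACHE: dict[tuple, np.ndarray] = {}


def phantom_labels(shape: tuple[int, int, int] = (40, 40, 32)) -> np.ndarray:
    """Label grid with two unequal ES tubes, two unequal PS tubes, and four
    ellipsoidal vertebral bodies (labels per LABEL_TABLE)."""
    key = tuple(shape)
    if key in _MASK_CACHE:
        return _MASK_CACHE[key]
    nx, ny, nz = shape
    lab = np.zeros(shape, dtype=np.int16)
    sx, sy, sz = nx / 40.0, ny / 40.0, nz / 32.0

    def box(label, x0, x1, y0, y1, z0, z1):
        lab[int(x0 * sx):int(x1 * sx), int(y0 * sy):int(y1 * sy),
            int(z0 * sz):int(z1 * sz)] = label

    box(1, 3, 9, 22, 30, 2, 30)    # ES_left  (6 x 8 x 28 voxels at ref shape)
    box(2, 31, 38, 22, 30, 2, 30)  # ES_right (7 wide: unequal by construction)
    box(3, 12, 16, 17, 23, 4, 28)  # PS_left
    box(4, 24, 29, 17, 23, 4, 28)  # PS_right (5 wide vs 4)
    xi, yi, zi = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    for k, zc in enumerate((4.5, 12.0, 19.5, 27.0)):
        e = (((xi - 20 * sx) / (5.5 * sx)) ** 2
             + ((yi - 9 * sy) / (4.5 * sy)) ** 2
             + ((zi - zc * sz) / (3.2 * sz)) ** 2)
        lab[(e <= 1.0) & (lab == 0)] = 5 + k
    _MASK_CACHE[key] = lab
    return lab


ROI_COMPARTMENT = {
    "ES_left": "ES", "ES_right": "ES", "PS_left": "PS", "PS_right": "PS",
    "L1": "LS", "L2": "LS", "L3": "LS", "L4": "LS",
}


def subject_phantom(
    specs: dict[str, TextureSpec],
    rng: np.random.Generator | int,
    shape: tuple[int, int, int] = (40, 40, 32),
    spacing: float = 1.5,
) -> tuple[PDFFVolume, ROIMask]:
    """One phantom volume with eight filled ROIs.

    ``specs`` maps compartment (ES/PS/LS) to its TextureSpec. All ROIs of a
    compartment share one per-subject SD multiplier 1 + jitter * X_c where
    X_c = lambda * u + sqrt(1 - lambda^2) * e_c mixes a subject-level latent
    factor u with compartment noise — the knob behind cross-compartment
    heterogeneity correlations. Compartment means get an independent
    per-subject offset of SD ``mean_sd`` (so mean PDFF varies between
    subjects but does not correlate across compartments); anchored
    compartments re-derive their skewness per subject so the distribution
    stays pinned at 0 % PDFF.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lab = phantom_labels(shape)
    u = rng.standard_normal()
    subj_spec: dict[str, TextureSpec] = {}
    for comp in ("ES", "PS", "LS"):
        spec = specs[comp]
        lam = spec.shared_loading
        x_c = lam * u + np.sqrt(max(0.0, 1.0 - lam * lam)) * rng.standard_normal()
        mult = max(0.2, 1.0 + spec.sd_rel_jitter * x_c)
        # per-subject compartment mean, independent across compartments
        mean_c = float(np.clip(spec.mean + spec.mean_sd * rng.standard_normal(), 1.0, 99.0))
        sd_c = spec.sd * mult
        # anchored compartments keep their lower bound pinned at 0 % PDFF
        skew_c = max(spec.skew, 2.0 * sd_c / mean_c) if spec.anchored else spec.skew
        subj_spec[comp] = replace(spec, mean=mean_c, sd=sd_c, skew=skew_c)
    data = np.zeros(shape, dtype=np.float64)
    # background: smooth mid-range field so the volume is not pathological
    data[:] = textured_field(shape, spacing, TextureSpec(mean=50.0, sd=5.0), rng)
    for label, roi in LABEL_TABLE.items():
        comp = ROI_COMPARTMENT[roi]
        spec = subj_spec[comp]
        where = lab == label
        idx = np.argwhere(where)
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        pad = 3  # margin so smoothing statistics are unaffected by the crop
        lo_p = np.maximum(lo - pad, 0)
        box_shape = tuple(int(h - l + pad) for l, h in zip(lo_p, hi))
        fld = textured_field(box_shape, spacing, spec, rng)
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        sub_box = tuple(slice(l - lp, h - lp) for l, lp, h in zip(lo, lo_p, hi))
        region = where[sub]
        data[sub][region] = fld[sub_box][region]
    spacing3 = (spacing, spacing, spacing)
    vol = PDFFVolume(data=data, spacing=spacing3)
    mask = ROIMask(labels=lab, label_table=dict(LABEL_TABLE), spacing=spacing3)
    return vol, mask


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class SyntheticSubject:
    subject_id: str
    sex: str
    age: float
    bmi: float
    volume: PDFFVolume
    mask: ROIMask


def _truncnorm(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """In-memory cohort; fully reproducible from ``spec.seed``.

    Per-subject random streams are spawned from a single seed sequence, so
    any subset of subjects is reproducible independently of the others.
    """
    ss = np.random.SeedSequence(spec.seed)
    n = spec.n_male + spec.n_female
    children = ss.spawn(n)
    sexes = ["male"] * spec.n_male + ["female"] * spec.n_female
    subjects = []
    for i, (sex, child) in enumerate(zip(sexes, children)):
        rng = np.random.default_rng(child)
        demo = spec.demographics[sex]
        age = _truncnorm(rng, *demo["age"], 18.0, 100.0)
        bmi = _truncnorm(rng, *demo["bmi"], 15.0, 45.0)
        specs = spec.specs[sex]
        if spec.age_slope != 0.0:
            specs = {c: replace(s, mean=float(np.clip(s.mean + spec.age_slope * (age - 45.0), 0.0, 100.0)))
                     for c, s in specs.items()}
        vol, mask = subject_phantom(specs, rng, shape=spec.shape, spacing=spec.spacing)
        subjects.append(SyntheticSubject(
            subject_id=f"S{i + 1:03d}", sex=sex, age=age, bmi=bmi,
            volume=vol, mask=mask))
    return subjects


def generate_cohort(spec: CohortSpec, outdir) -> pd.DataFrame:
    """Write a cohort to disk: NIfTI volumes and masks, a demographics CSV
    with relative file paths, and the label table as JSON."""
    outdir = Path(outdir)
    (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in simulate_cohort(spec):
        vpath = f"volumes/{sub.subject_id}_pdff.nii.gz"
        mpath = f"masks/{sub.subject_id}_mask.nii.gz"
        write_volume(sub.volume, outdir / vpath)
        write_mask(sub.mask, outdir / mpath)
        rows.append({"subject_id": sub.subject_id, "sex": sub.sex,
                     "age": sub.age, "bmi": sub.bmi,
                     "volume": vpath, "mask": mpath})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "demographics.csv", index=False)
    (outdir / "labels.json").write_text(
        json.dumps({str(k): v for k, v in LABEL_TABLE.items()}, indent=2))
    return df


# ---------------------------------------------------------------------------
# calibration of the shared-factor loading

def cohort_variance_partial_r(spec: CohortSpec, muscle: str = "ES") -> tuple[float, float]:
    """Partial correlation (and its p) of Variance(global), lumbar spine vs one
    muscle group, adjusted for age and BMI, over one simulated cohort.
    Uses the first-order-only extraction path."""
    from .pipeline import ExtractionConfig, extract_compartment_features
    from .stats import partial_correlation

    config = ExtractionConfig(feature_set="firstorder")
    xs, ys, cov = [], [], []
    for sub in simulate_cohort(spec):
        comp = extract_compartment_features(sub.volume, sub.mask, config)
        xs.append(comp["LS"].features["variance_global"])
        ys.append(comp[muscle].features["variance_global"])
        cov.append((sub.age, sub.bmi))
    res = partial_correlation(np.array(xs), np.array(ys), np.array(cov))
    return res.statistic, res.p_value


def calibrate_shared_loading(
    lambdas=(0.0, 0.3, 0.5, 0.66, 0.8, 0.95),
    n_cohorts: int = 10,
    seed: int = 0,
    base_spec: CohortSpec | None = None,
) -> dict[float, float]:
    """Sweep the shared loading and report the mean realized partial
    correlation of Variance(global) (LS vs ES) per lambda."""
    out: dict[float, float] = {}
    for lam in lambdas:
        rs = []
        for rep in range(n_cohorts):
            spec = base_spec or CohortSpec()
            spec = replace(
                spec,
                seed=int(np.random.SeedSequence([seed, rep, int(lam * 1000)]).generate_state(1)[0] % (2**31)),
                specs={s: {c: replace(t, shared_loading=lam) for c, t in d.items()}
                       for s, d in spec.specs.items()},
            )
            r, _ = cohort_variance_partial_r(spec)
            rs.append(r)
        out[float(lam)] = float(np.mean(rs))
    return out
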