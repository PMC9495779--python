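"""3D gray-level co-occurrence matrices and second-order texture features.

Co-occurrence is evaluated over the 26-neighborhood, i.e. the 13 unique
displacement directions of {-1,0,1}^3 modulo sign. Each direction yields a
symmetric joint-probability matrix over the quantized gray levels; the eight
second-order features (Energy, Entropy, Contrast, Homogeneity, Correlation,
Variance, Sum Average, Dissimilarity) are computed per direction and then
averaged over directions to obtain rotation-invariant values. The direction
average can compensate for the unequal physical length of axial, planar-
diagonal and space-diagonal offsets by weighting each direction with the
inverse of its Euclidean length (1, 1/sqrt(2), 1/sqrt(3)).

Entropy is reported in bits (base-2 logarithm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import QuantizedROI


def _canonical_directions() -> tuple[tuple[int, int, int], ...]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                # keep one of each +/- pair: first nonzero component positive
                first = next(c for c in d if c != 0)
                if first > 0:
                    dirs.append(d)
    assert len(dirs) == 13
    return tuple(dirs)


#: The 13 canonical displacement directions (no two are negations of each other).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = _canonical_directions()

FEATURE_FIELDS = (
    "energy",
    "entropy",
    "contrast",
    "homogeneity",
    "correlation",
    "variance",
    "sum_average",
    "dissimilarity",
)


@dataclass
class GLCMConfig:
    n_levels: int = 200
    distance: int = 1
    direction_weighting: str = "inverse_length"  # or "uniform"
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.direction_weighting not in ("inverse_length", "uniform"):
            raise ValueError("direction_weighting must be 'inverse_length' or 'uniform'")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")


@dataclass
class GLCM:
    """Symmetric joint co-occurrence probability matrix for one direction."""

    P: np.ndarray
    n_pairs: int
    direction: tuple[int, int, int]

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


@dataclass
class SecondOrderFeatures:
    energy: float
    entropy: float
    contrast: float
    homogeneity: float
    correlation: float
    variance: float
    sum_average: float
    dissimilarity: float
    flags: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, float]:
        return {
            "energy": self.energy,
            "entropy": self.entropy,
            "contrast": self.contrast,
            "homogeneity": self.homogeneity,
            "correlation": self.correlation,
            "variance_glcm": self.variance,
            "sum_average": self.sum_average,
            "dissimilarity": self.dissimilarity,
        }


# cached |i-j| and (i-j)^2 matrices keyed by n_levels
_DIFF_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _diff_matrices(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _DIFF_CACHE:
        i = np.arange(1, n + 1)
        d = i[:, None] - i[None, :]
        _DIFF_CACHE[n] = (np.abs(d).astype(np.float64), (d * d).astype(np.float64))
    return _DIFF_CACHE[n]


def _offset_slices(shape, off):
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def build_glcm(qroi: QuantizedROI, direction: tuple[int, int, int], config: GLCMConfig) -> GLCM:
    """Count in-ROI voxel pairs at ``direction * distance``, symmetrize, normalize.

    Only pairs whose BOTH endpoints carry the ROI label contribute; pairs
    reaching outside the ROI or the grid are dropped (no padding). The matrix
    is symmetrized by adding its transpose before normalization to unit sum.
    A direction with zero valid pairs yields an empty-flagged GLCM.
    """
    if tuple(direction) not in DIRECTIONS_13:
        raise ValueError(f"direction {direction} is not one of the 13 canonical offsets")
    n = config.n_levels
    off = tuple(int(c) * config.distance for c in direction)
    lev = qroi.level_volume()
    if any(abs(o) >= s for o, s in zip(off, lev.shape)):
        return GLCM(P=np.zeros((n, n)), n_pairs=0, direction=tuple(direction))
    sl_src, sl_dst = _offset_slices(lev.shape, off)
    a = lev[sl_src]
    b = lev[sl_dst]
    valid = (a > 0) & (b > 0)
    n_pairs = int(valid.sum())
    if n_pairs == 0:
        return GLCM(P=np.zeros((n, n)), n_pairs=0, direction=tuple(direction))
    flat = (a[valid].astype(np.int64) - 1) * n + (b[valid].astype(np.int64) - 1)
    counts = np.bincount(flat, minlength=n * n).reshape(n, n).astype(np.float64)
    counts = counts + counts.T
    return GLCM(P=counts / counts.sum(), n_pairs=n_pairs, direction=tuple(direction))


def glcm_features(glcm: GLCM) -> SecondOrderFeatures:
    """The eight second-order features of one co-occurrence matrix.

    With p(i,j) the joint probability, p_x its row marginal, and mu_x /
    sigma_x the marginal mean and SD of the gray level (equal for both axes
    by symmetry): Energy = sum p^2; Entropy = -sum p log2 p; Contrast =
    sum (i-j)^2 p; Homogeneity = sum p / (1 + |i-j|); Correlation =
    sum (i-mu_x)(j-mu_y) p / (sigma_x sigma_y); Variance = sum (i-mu_x)^2 p;
    Sum Average = sum_k k p_{x+y}(k). A constant ROI has sigma_x = 0 and its
    Correlation is reported as 0 with a flag.
    """
    if glcm.empty:
        raise ValueError("cannot compute features of an empty GLCM")
    P = glcm.P
    n = P.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    px = P.sum(axis=1)
    mu = float(i @ px)
    d = i - mu
    var = float(d**2 @ px)
    absdiff, sqdiff = _diff_matrices(n)
    energy = float(np.sum(P * P))
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    contrast = float(np.sum(sqdiff * P))
    homogeneity = float(np.sum(P / (1.0 + absdiff)))
    dissimilarity = float(np.sum(absdiff * P))
    sum_average = float(np.sum((i[:, None] + i[None, :]) * P))
    flags: set[str] = set()
    if var <= 1e-300:
        correlation = 0.0
        flags.add("correlation_undefined")
    else:
        correlation = float(d @ P @ d) / var
    return SecondOrderFeatures(
        energy=energy,
        entropy=entropy,
        contrast=contrast,
        homogeneity=homogeneity,
        correlation=correlation,
        variance=var,
        sum_average=sum_average,
        dissimilarity=dissimilarity,
        flags=flags,
    )


def direction_weight(direction: tuple[int, int, int], scheme: str) -> float:
    if scheme == "uniform":
        return 1.0
    return 1.0 / float(np.linalg.norm(direction))


def rotation_invariant_features(qroi: QuantizedROI, config: GLCMConfig | None = None) -> SecondOrderFeatures:
    """Direction-averaged second-order features.

    Features are computed per direction and averaged over the non-empty
    directions with weights given by ``config.direction_weighting``
    (normalized to sum 1 over the included directions). All 13 directions
    empty is a hard error: the ROI is too small for co-occurrence analysis.
    """
    config = config or GLCMConfig()
    per_dir: list[SecondOrderFeatures] = []
    weights: list[float] = []
    for direction in DIRECTIONS_13:
        g = build_glcm(qroi, direction, config)
        if g.empty:
            continue
        per_dir.append(glcm_features(g))
        weights.append(direction_weight(direction, config.direction_weighting))
    if not per_dir:
        raise ValueError("ROI too small for GLCM: no direction has a valid voxel pair")
    w = np.asarray(weights)
    w = w / w.sum()
    flags = set().union(*(f.flags for f in per_dir))
    vals = {
        name: float(np.dot(w, [getattr(f, name) for f in per_dir]))
        for name in FEATURE_FIELDS
    }
    return SecondOrderFeatures(flags=flags, **vals)
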