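"""NIfTI volume / ROI-mask I/O, geometric validation, and the feature table.

Fat-fraction volumes are scalar 3D grids carrying voxel spacing (mm) and an
affine that is passed through opaquely. ROI masks are integer label grids on
the same geometry, with a label table naming each compartment (ES_left,
ES_right, PS_left, PS_right, L1..L4).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Canonical base ROI names and the compartments they roll up into.
COMPARTMENT_ROIS: dict[str, tuple[str, ...]] = {
    "ES": ("ES_left", "ES_right"),
    "PS": ("PS_left", "PS_right"),
    "LS": ("L1", "L2", "L3", "L4"),
}

#: The 12 per-compartment quantities, in output-table order.
FEATURE_NAMES: tuple[str, ...] = (
    "pdff_mean",
    "variance_global",
    "skewness_global",
    "kurtosis_global",
    "energy",
    "entropy",
    "contrast",
    "homogeneity",
    "correlation",
    "variance_glcm",
    "sum_average",
    "dissimilarity",
)

_SPACING_RTOL = 1e-4


@dataclass
class PDFFVolume:
    """3D proton-density fat-fraction map in percent with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValueError("spacing must have three components")
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive and finite, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ROIMask:
    """Integer label grid (0 = background) aligned to a :class:`PDFFVolume`."""

    labels: np.ndarray
    label_table: dict[int, str]
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = np.round(self.labels)
            if not np.allclose(self.labels, as_int, atol=1e-8):
                raise ValueError("mask values must be integer labels")
            self.labels = as_int.astype(np.int32)
        self.label_table = {int(k): str(v) for k, v in self.label_table.items()}
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(self.label_table.values())

    def label_of(self, name: str) -> int:
        for lab, nm in self.label_table.items():
            if nm == name:
                return lab
        raise KeyError(f"compartment {name!r} not in label table")


def validate_geometry(vol: PDFFVolume, mask: ROIMask) -> None:
    """Reject any volume/mask pair whose grid shape or spacing disagree."""
    if vol.shape != mask.shape:
        raise ValueError(f"volume/mask shape mismatch: {vol.shape} vs {mask.shape}")
    if not np.allclose(vol.spacing, mask.spacing, rtol=_SPACING_RTOL):
        raise ValueError(f"volume/mask spacing mismatch: {vol.spacing} vs {mask.spacing}")


def _load_3d(path) -> tuple[np.ndarray, tuple[float, ...], np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    # A trailing degenerate dimension (e.g. a size-1 time axis) is squeezed away.
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: volume must be 3D, got shape {data.shape}")
    return data, tuple(float(z) for z in zooms), np.asarray(img.affine)


def read_volume(path) -> PDFFVolume:
    """Read a scalar NIfTI fat-fraction volume; spacing comes from the header."""
    data, zooms, affine = _load_3d(path)
    if not all(np.isfinite(z) and z > 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    return PDFFVolume(data=np.asarray(data, dtype=np.float64), spacing=zooms, affine=affine)


def read_mask(path, label_table: dict[int, str], volume: PDFFVolume | None = None) -> ROIMask:
    """Read an integer NIfTI label mask and pair it with ``label_table``.

    Labels present in the file but absent from the table trigger a warning and
    are ignored downstream; a geometry mismatch with ``volume`` is a hard error.
    """
    data, zooms, affine = _load_3d(path)
    mask = ROIMask(labels=data, label_table=label_table, spacing=zooms, affine=affine)
    present = set(int(v) for v in np.unique(mask.labels)) - {0}
    unknown = present - set(mask.label_table)
    if unknown:
        warnings.warn(
            f"{path}: labels {sorted(unknown)} not in label table; they will be ignored",
            stacklevel=2,
        )
    if volume is not None:
        validate_geometry(volume, mask)
    return mask


def write_feature_table(records, path) -> pd.DataFrame:
    """Write one CSV row per subject per compartment.

    ``records`` is an iterable of objects with ``subject_id``, ``sex``, ``age``,
    ``bmi`` and a ``features`` mapping of compartment name -> FeatureVector.
    Column order is fixed; floats round-trip at full precision.
    """
    rows = []
    for rec in records:
        for comp, fv in rec.features.items():
            row = {
                "subject_id": rec.subject_id,
                "compartment": comp,
                "sex": rec.sex,
                "age": rec.age,
                "bmi": rec.bmi,
            }
            for name in FEATURE_NAMES:
                row[name] = fv.features.get(name, np.nan)
            rows.append(row)
    cols = ["subject_id", "compartment", "sex", "age", "bmi", *FEATURE_NAMES]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False)
    return df


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_volume(vol: PDFFVolume, path) -> None:
    affine = vol.affine if vol.affine is not None else np.diag([*vol.spacing, 1.0])
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: ROIMask, path) -> None:
    affine = mask.affine if mask.affine is not None else np.diag([*mask.spacing, 1.0])
    img = nib.Nifti1Image(mask.labels.astype(np.int16), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
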