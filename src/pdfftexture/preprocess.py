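"""Preprocessing: unit normalization, clipping, isotropic resampling,
ROI value extraction, and the fixed-domain gray-level quantization that
feeds the co-occurrence analysis.

Fat fractions are analyzed in percent on a fixed [0, 100] domain so that
gray levels are comparable across subjects and compartments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_maps import PDFFVolume, ROIMask, validate_geometry

log = logging.getLogger(__name__)

PDFF_MIN = 0.0
PDFF_MAX = 100.0


@dataclass
class QuantizedROI:
    """ROI voxels mapped to integer gray levels 1..n_levels.

    Spatial indices are retained (voxel index space of the resampled grid) so
    co-occurrence pairs can be formed; ``level_edges`` span the fixed 0-100 %
    domain regardless of the ROI's own min/max.
    """

    levels: np.ndarray           # (N,) int, values in 1..n_levels
    indices: np.ndarray          # (N, 3) int voxel indices, lexicographic order
    n_levels: int
    level_edges: np.ndarray      # (n_levels + 1,) edges in percent
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]  # grid shape the indices live on

    def level_volume(self) -> np.ndarray:
        """Dense int32 grid with gray levels in the ROI and 0 outside."""
        vol = np.zeros(self.shape, dtype=np.int32)
        vol[tuple(self.indices.T)] = self.levels
        return vol


def prepare_volume(vol: PDFFVolume, mask: ROIMask | None = None) -> PDFFVolume:
    """Normalize units to percent and clip to [0, 100].

    Files storing fat fractions in [0, 1] are detected (in-ROI max <= 1.5, or
    global max if no mask is given) and rescaled by 100 with a warning.
    Values outside [0, 100] — e.g. water-fat swap artifacts — are clipped,
    with the affected voxel count logged.
    """
    data = vol.data
    if mask is not None:
        validate_geometry(vol, mask)
        probe = data[mask.labels > 0]
        if probe.size == 0:
            probe = data
    else:
        probe = data
    if probe.size and np.nanmax(probe) <= 1.5:
        log.warning("volume appears to store fractions in [0,1]; rescaling by 100")
        data = data * 100.0
    n_out = int(np.count_nonzero((data < PDFF_MIN) | (data > PDFF_MAX)))
    if n_out:
        log.info("clipping %d voxels outside [0, 100]%%", n_out)
    data = np.clip(data, PDFF_MIN, PDFF_MAX)
    return PDFFVolume(data=data, spacing=vol.spacing, affine=vol.affine)


def _resampled_axis(n: int, spacing: float, target: float) -> np.ndarray:
    """Sample positions (in source voxel index units) for one axis.

    Voxel 0 is the anchor; samples are placed every ``target`` mm without
    extrapolating beyond the last source voxel center.
    """
    n_new = int(np.floor((n - 1) * spacing / target)) + 1
    return np.arange(n_new) * (target / spacing)


def resample_isotropic(
    vol: PDFFVolume, mask: ROIMask, target_mm: float | None = None
) -> tuple[PDFFVolume, ROIMask]:
    """Resample volume (trilinear) and mask (nearest-neighbor) to an
    isotropic grid of edge ``target_mm`` (default: the smallest input spacing).
    """
    validate_geometry(vol, mask)
    if target_mm is None:
        target_mm = min(vol.spacing)
    target_mm = float(target_mm)
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    if np.allclose(vol.spacing, target_mm, rtol=1e-6):
        return vol, mask  # already isotropic at the target: identity
    axes = [_resampled_axis(n, s, target_mm) for n, s in zip(vol.shape, vol.spacing)]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    new_shape = tuple(len(a) for a in axes)
    new_data = ndimage.map_coordinates(vol.data, coords, order=1, mode="nearest").reshape(new_shape)
    new_labels = ndimage.map_coordinates(mask.labels, coords, order=0, mode="nearest").reshape(new_shape)
    spacing3 = (target_mm, target_mm, target_mm)
    return (
        PDFFVolume(data=new_data, spacing=spacing3, affine=vol.affine),
        ROIMask(labels=new_labels, label_table=mask.label_table, spacing=spacing3, affine=mask.affine),
    )


def extract_roi_values(
    vol: PDFFVolume, mask: ROIMask, compartment: str
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Values and voxel indices of one labeled compartment.

    Returns ``(values, indices, count, volume_mm3)``; indices are in
    lexicographic (C) order so extraction is deterministic. Raises on an
    empty ROI.
    """
    validate_geometry(vol, mask)
    label = mask.label_of(compartment)
    idx = np.argwhere(mask.labels == label)
    if idx.shape[0] == 0:
        raise ValueError(f"empty ROI: compartment {compartment!r} has no voxels")
    values = vol.data[tuple(idx.T)]
    count = idx.shape[0]
    return values, idx, count, count * vol.voxel_volume_mm3


def quantize(
    values: np.ndarray,
    indices: np.ndarray,
    n_levels: int = 200,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    shape: tuple[int, int, int] | None = None,
) -> QuantizedROI:
    """Map percent values onto ``n_levels`` equal bins over the fixed 0-100 % domain.

    level = floor(v / (100 / n_levels)) + 1, with v = 100 assigned the top
    level (half-open bins, last bin closed). The edges are fixed at 0 and 100
    regardless of the ROI's own range.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    values = np.asarray(values, dtype=np.float64)
    if values.size and (values.min() < PDFF_MIN - 1e-9 or values.max() > PDFF_MAX + 1e-9):
        raise ValueError("values must be clipped to [0, 100] before quantization")
    width = (PDFF_MAX - PDFF_MIN) / n_levels
    levels = np.floor((values - PDFF_MIN) / width).astype(np.int64) + 1
    np.clip(levels, 1, n_levels, out=levels)
    indices = np.asarray(indices, dtype=np.int64)
    if shape is None:
        shape = tuple(int(m) + 1 for m in indices.max(axis=0))
    edges = PDFF_MIN + width * np.arange(n_levels + 1)
    return QuantizedROI(
        levels=levels,
        indices=indices,
        n_levels=int(n_levels),
        level_edges=edges,
        spacing=tuple(float(s) for s in spacing),
        shape=tuple(int(s) for s in shape),
    )
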