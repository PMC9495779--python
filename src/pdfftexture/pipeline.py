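"""End-to-end feature extraction for one subject: prepare -> resample ->
per-ROI first- and second-order features -> compartment aggregation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import firstorder, glcm, preprocess
from .aggregate import FeatureVector, average_vertebrae, bilateral_weighted_mean
from .io_maps import COMPARTMENT_ROIS, FEATURE_NAMES, PDFFVolume, ROIMask

log = logging.getLogger(__name__)


@dataclass
class ExtractionConfig:
    n_levels: int = 200
    iso_mm: float | None = None          # None: resample to the smallest input spacing
    kurtosis: str = "excess"             # or "pearson"
    direction_weighting: str = "inverse_length"
    feature_set: str = "all"             # "all" | "firstorder"
    keep_parts: bool = False

    def glcm_config(self) -> glcm.GLCMConfig:
        return glcm.GLCMConfig(n_levels=self.n_levels,
                               direction_weighting=self.direction_weighting)


def extract_roi_features(
    vol: PDFFVolume, mask: ROIMask, roi: str, config: ExtractionConfig
) -> FeatureVector:
    """The 12-quantity feature vector of a single labeled ROI.

    Mean PDFF and the three global features come from the raw percent values;
    the eight second-order features come from the 200-level quantization and
    the 13-direction co-occurrence analysis.
    """
    values, idx, count, volume_mm3 = preprocess.extract_roi_values(vol, mask, roi)
    gf = firstorder.global_features(values, kurtosis=config.kurtosis)
    feats: dict[str, float] = gf.as_dict()
    flags = set(gf.flags)
    aux = {"n_bins": float(gf.n_bins_used), "n_voxels": float(count),
           "volume_mm3": volume_mm3}
    if config.feature_set == "all":
        qroi = preprocess.quantize(values, idx, n_levels=config.n_levels,
                                   spacing=vol.spacing, shape=vol.shape)
        sof = glcm.rotation_invariant_features(qroi, config.glcm_config())
        feats.update(sof.as_dict())
        flags |= sof.flags
    else:
        feats.update({k: np.nan for k in FEATURE_NAMES if k not in feats})
    return FeatureVector(features=feats, provenance=[(roi, volume_mm3)],
                         flags=flags, aux=aux)


def extract_compartment_features(
    vol: PDFFVolume, mask: ROIMask, config: ExtractionConfig | None = None
) -> dict[str, FeatureVector]:
    """Per-compartment (ES, PS, LS) feature vectors for one subject.

    Bilateral muscles are volume-weighted over sides; the lumbar-spine value
    is the unweighted mean over the available vertebrae. With
    ``config.keep_parts`` the per-ROI vectors are returned as well.
    """
    config = config or ExtractionConfig()
    vol = preprocess.prepare_volume(vol, mask)
    vol, mask = preprocess.resample_isotropic(vol, mask, config.iso_mm)
    parts: dict[str, FeatureVector] = {}
    for roi in mask.compartments:
        if not any(roi in rois for rois in COMPARTMENT_ROIS.values()):
            log.warning("ignoring unrecognized ROI %r", roi)
            continue
        try:
            parts[roi] = extract_roi_features(vol, mask, roi, config)
        except ValueError as exc:
            log.warning("skipping ROI %r: %s", roi, exc)
    out: dict[str, FeatureVector] = {}
    for side_group in ("ES", "PS"):
        l_name, r_name = COMPARTMENT_ROIS[side_group]
        left, right = parts.get(l_name), parts.get(r_name)
        if left is None and right is None:
            continue
        vl = left.aux["volume_mm3"] if left else 0.0
        vr = right.aux["volume_mm3"] if right else 0.0
        out[side_group] = bilateral_weighted_mean(left, vl, right, vr)
    verts = [parts[v] for v in COMPARTMENT_ROIS["LS"] if v in parts]
    if verts:
        out["LS"] = average_vertebrae(verts)
    if config.keep_parts:
        out.update(parts)
    return out
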