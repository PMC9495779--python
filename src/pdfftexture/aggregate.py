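"""Roll per-ROI feature vectors up to the three analyzed compartments.

Bilateral muscles (erector spinae, psoas) are combined as a volume-weighted
mean of left and right; the four lumbar vertebrae are combined as an
unweighted mean. The asymmetry is deliberate: muscle sides can differ
substantially in volume, vertebral levels are treated as equal replicates.
Features are always computed per ROI first and then averaged — never on a
pooled voxel set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


@dataclass
class FeatureVector:
    """The 12 per-compartment quantities plus provenance.

    ``features`` maps feature name -> value (see io_maps.FEATURE_NAMES);
    ``provenance`` lists the contributing ROI names with their volumes in mm3;
    ``aux`` carries non-averaged metadata such as the histogram bin count.
    """

    features: dict[str, float]
    provenance: list[tuple[str, float]] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    aux: dict[str, float] = field(default_factory=dict)


def bilateral_weighted_mean(
    left: FeatureVector | None,
    vol_left: float,
    right: FeatureVector | None,
    vol_right: float,
) -> FeatureVector:
    """Volume-weighted mean of the left and right side of a muscle group.

    Every field f becomes (V_L f_L + V_R f_R) / (V_L + V_R). A missing or
    empty side returns the other side unchanged, with a warning.
    """
    left_ok = left is not None and vol_left > 0
    right_ok = right is not None and vol_right > 0
    if not left_ok and not right_ok:
        raise ValueError("both sides empty: cannot aggregate")
    if not left_ok or not right_ok:
        warnings.warn("one side empty; using the other side alone", stacklevel=2)
        fv = right if left_ok is False else left
        assert fv is not None
        return FeatureVector(
            features=dict(fv.features),
            provenance=list(fv.provenance),
            flags=set(fv.flags) | {"one_side_empty"},
            aux=dict(fv.aux),
        )
    assert left is not None and right is not None
    total = vol_left + vol_right
    wl, wr = vol_left / total, vol_right / total
    feats = {
        k: wl * left.features[k] + wr * right.features[k]
        for k in left.features
    }
    return FeatureVector(
        features=feats,
        provenance=list(left.provenance) + list(right.provenance),
        flags=set(left.flags) | set(right.flags),
    )


def average_vertebrae(vertebrae: list[FeatureVector]) -> FeatureVector:
    """Unweighted per-field mean across the available vertebral levels."""
    vertebrae = [v for v in vertebrae if v is not None]
    if not vertebrae:
        raise ValueError("no vertebrae to average")
    if len(vertebrae) < 4:
        warnings.warn(
            f"averaging only {len(vertebrae)} vertebrae (expected 4)", stacklevel=2
        )
    n = len(vertebrae)
    keys = vertebrae[0].features.keys()
    feats = {k: sum(v.features[k] for v in vertebrae) / n for k in keys}
    prov: list[tuple[str, float]] = []
    flags: set[str] = set()
    for v in vertebrae:
        prov.extend(v.provenance)
        flags |= v.flags
    if len(vertebrae) < 4:
        flags.add("missing_vertebra")
    return FeatureVector(features=feats, provenance=prov, flags=flags)
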