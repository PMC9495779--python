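"""First-order (global) features from ROI intensity histograms.

The histogram bin count is the median of Sturges', Scott's and the
Freedman-Diaconis rules; variance, skewness and kurtosis are then moments of
the normalized histogram (bin centers weighted by normalized counts), which
is how global texture heterogeneity is summarized for fat-fraction maps.
Mean PDFF is always computed on the raw, unbinned values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class GlobalFeatures:
    mean_pdff: float
    variance_global: float
    skewness_global: float
    kurtosis_global: float
    n_bins_used: int
    flags: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, float]:
        return {
            "pdff_mean": self.mean_pdff,
            "variance_global": self.variance_global,
            "skewness_global": self.skewness_global,
            "kurtosis_global": self.kurtosis_global,
        }


def sturges_bins(n: int) -> int:
    return int(np.ceil(np.log2(n))) + 1


def scott_bins(values: np.ndarray) -> int | None:
    """Scott's rule: width 3.49 * s * n^(-1/3); None when the width degenerates."""
    n = values.size
    s = float(np.std(values, ddof=1))
    rng = float(values.max() - values.min())
    if s <= 0 or rng <= 0:
        return None
    width = 3.49 * s * n ** (-1.0 / 3.0)
    return int(np.ceil(rng / width))


def freedman_diaconis_bins(values: np.ndarray) -> int | None:
    """Freedman-Diaconis rule: width 2 * IQR * n^(-1/3); None when IQR is zero."""
    n = values.size
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    rng = float(values.max() - values.min())
    if iqr <= 0 or rng <= 0:
        return None
    width = 2.0 * iqr * n ** (-1.0 / 3.0)
    return int(np.ceil(rng / width))


def select_bin_count(values: np.ndarray) -> int:
    """Median of the Sturges / Scott / Freedman-Diaconis bin counts.

    Zero spread returns 1 with a warning; a zero IQR drops the FD rule and
    the median degenerates to the mean of the remaining pair, rounded up.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values to select a bin count")
    if values.max() == values.min():
        warnings.warn("zero spread: falling back to a single histogram bin", stacklevel=2)
        return 1
    candidates = [sturges_bins(values.size), scott_bins(values), freedman_diaconis_bins(values)]
    ks = [k for k in candidates if k is not None]
    if len(ks) == 3:
        return int(np.sort(ks)[1])
    return int(np.ceil(np.mean(ks)))


def global_features(values: np.ndarray, kurtosis: str = "excess") -> GlobalFeatures:
    """Histogram-based variance, skewness and kurtosis of an ROI.

    ``kurtosis`` selects the convention: "excess" (normal = 0, default) or
    "pearson" (normal = 3). With zero histogram variance, skewness and
    kurtosis are undefined and reported as 0 with a flag.
    """
    if kurtosis not in ("excess", "pearson"):
        raise ValueError("kurtosis must be 'excess' or 'pearson'")
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    flags: set[str] = set()
    mean_raw = float(values.mean())
    k = select_bin_count(values)
    if k == 1:
        flags.add("zero_variance")
        return GlobalFeatures(mean_raw, 0.0, 0.0, 0.0, 1, flags)
    counts, edges = np.histogram(values, bins=k, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()
    mu = float(p @ centers)
    d = centers - mu
    var = float(p @ d**2)
    if var <= 0:
        flags.add("zero_variance")
        skew = 0.0
        kurt = 0.0 if kurtosis == "excess" else 3.0
    else:
        skew = float(p @ d**3) / var**1.5
        kurt = float(p @ d**4) / var**2
        if kurtosis == "excess":
            kurt -= 3.0
    return GlobalFeatures(mean_raw, var, skew, kurt, k, flags)


def raw_moments(values: np.ndarray) -> dict[str, float]:
    """Direct sample moments (no binning), for comparison with the
    histogram-based versions: variance_raw, skewness_raw, kurtosis_raw (excess)."""
    values = np.asarray(values, dtype=np.float64)
    mu = values.mean()
    d = values - mu
    var = float(np.mean(d**2))
    if var <= 0:
        return {"variance_raw": 0.0, "skewness_raw": 0.0, "kurtosis_raw": 0.0}
    return {
        "variance_raw": var,
        "skewness_raw": float(np.mean(d**3)) / var**1.5,
        "kurtosis_raw": float(np.mean(d**4)) / var**2 - 3.0,
    }
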