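"""First-order histogram heterogeneity measures of lipid composition.

For each lipid constituent (MUFA, PUFA, SFA) in each region the pipeline
reports five measures of the voxel-value distribution:

* mean and median of the fractions;
* skewness  m3 / m2**1.5  (population central moments; sign follows the
  usual convention, a long left tail gives a negative value);
* kurtosis  m4 / m2**2  (non-excess, Gaussian -> 3);
* Shannon entropy  -sum p_i log2 p_i  in bits over the occupied bins of a
  fixed histogram (default 256 equal-width bins spanning [0, 1], shared by
  all lipids so regions stay comparable).

Moment-based measures are unstable in tiny regions, so skewness, entropy
and kurtosis are withheld below a minimum voxel count (default 20).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HistogramSpec", "HeterogeneityProfile", "summarize", "profile_all"]

MEASURES = ("mean", "median", "skewness", "entropy", "kurtosis")
LIPIDS = ("MUFA", "PUFA", "SFA")


@dataclass(frozen=True)
class HistogramSpec:
    """Binning and sampling depth used for the entropy computation.

    ``rarefaction_depth`` controls the voxel-count correction of entropy:
    the plugin estimate -sum p log2 p rises with the number of voxels, so
    regions of very different size (a rim vs a whole breast) are not
    comparable on the raw value.  The reported entropy is therefore the
    expected plugin entropy of a ``rarefaction_depth``-voxel subsample
    (exact hypergeometric expectation, deterministic), which has the same
    expectation regardless of region size.  Regions at or below the depth
    are summarised in full (the raw formula); ``rarefaction_depth=None``
    disables the correction everywhere.
    """

    n_bins: int = 256
    value_range: tuple[float, float] = (0.0, 1.0)
    min_voxels: int = 20
    rarefaction_depth: int | None = 200

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("n_bins must be at least 1")
        if self.value_range[1] <= self.value_range[0]:
            raise ValueError("value range must have positive width")
        if self.rarefaction_depth is not None and self.rarefaction_depth < 2:
            raise ValueError("rarefaction depth must be at least 2")


@dataclass
class HeterogeneityProfile:
    lipid: str
    region: str
    n_voxels: int
    mean: float
    median: float
    skewness: float
    entropy: float
    kurtosis: float
    histogram_spec: HistogramSpec
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "lipid": self.lipid, "region": self.region,
            "n_voxels": self.n_voxels, "mean": self.mean,
            "median": self.median, "skewness": self.skewness,
            "entropy": self.entropy, "kurtosis": self.kurtosis,
            "flags": ";".join(self.flags),
        }


def _plugin_entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _rarefied_entropy(counts: np.ndarray, depth: int) -> float:
    """Expected plugin entropy of a ``depth``-voxel subsample.

    E[H_m] = -sum_i sum_x P(X_i = x) (x/m) log2(x/m) with X_i
    hypergeometric(n, c_i, m).  Subsampling m of n i.i.d. voxels is again
    an i.i.d. sample of size m, so this estimator's expectation depends on
    the underlying distribution only through m, not the region size n.
    """
    from scipy.special import gammaln

    c = counts[counts > 0].astype(np.int64)
    n, m = int(c.sum()), depth
    x = np.arange(1, m + 1)
    cc = c[:, None]
    with np.errstate(invalid="ignore"):
        logpmf = (gammaln(cc + 1) - gammaln(x + 1) - gammaln(cc - x + 1)
                  + gammaln(n - cc + 1) - gammaln(m - x + 1)
                  - gammaln(n - cc - (m - x) + 1)
                  - (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)))
    valid = (x <= cc) & ((m - x) <= (n - cc))
    pmf = np.where(valid, np.exp(np.where(valid, logpmf, -np.inf)), 0.0)
    frac = x / m
    return float(-(pmf * (frac * np.log2(frac))).sum())


def shannon_entropy(values: np.ndarray, spec: HistogramSpec) -> float:
    """Entropy in bits of the histogram of ``values`` under ``spec``."""
    counts, _ = np.histogram(values, bins=spec.n_bins, range=spec.value_range)
    n = int(counts.sum())
    if n == 0:
        return math.nan
    depth = spec.rarefaction_depth
    if depth is None or n <= depth:
        return _plugin_entropy(counts)
    return _rarefied_entropy(counts, depth)


def summarize(values, histogram_spec: HistogramSpec | None = None,
              lipid: str = "", region: str = "") -> HeterogeneityProfile:
    """Five histogram measures of one region's voxel values.

    Constant input leaves skewness and kurtosis undefined (NaN, flagged)
    with zero entropy.  Regions below ``min_voxels`` are flagged
    ``below-min-voxels`` so the statistics layer can exclude their
    higher-order measures; the values themselves are still computed.
    """
    spec = histogram_spec or HistogramSpec()
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty region: no finite values to summarise")

    mean = float(v.mean())
    median = float(np.median(v))
    entropy = shannon_entropy(v, spec)
    m2 = float(((v - mean) ** 2).mean())
    flags: list[str] = []
    if np.ptp(v) == 0.0:  # constant input; m2 may be nonzero round-off
        skew = kurt = math.nan
        entropy = 0.0
        flags.append("constant-input")
    else:
        m3 = float(((v - mean) ** 3).mean())
        m4 = float(((v - mean) ** 4).mean())
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    if v.size < spec.min_voxels:
        flags.append("below-min-voxels")
    return HeterogeneityProfile(lipid, region, int(v.size), mean, median,
                                skew, entropy, kurt, spec, tuple(flags))


def profile_all(maps, rois, histogram_spec: HistogramSpec | None = None,
                region_masks: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Profiles for each lipid constituent in each available region.

    ``region_masks`` defaults to the adipose-filtered rim (Peri-P) and
    whole-breast masks from ``rois``; the whole-breast region is labelled
    WB-P when a tumour is present and WB-C otherwise.  Regions below the
    minimum voxel count are flagged in the output rather than dropped.
    """
    spec = histogram_spec or HistogramSpec()
    if region_masks is None:
        wb_name = "WB-P" if rois.tumour.any() else "WB-C"
        region_masks = {}
        if rois.adipose_rim.any():
            region_masks["Peri-P"] = rois.adipose_rim
        region_masks[wb_name] = rois.adipose_whole_breast
    rows = []
    lipid_maps = {"MUFA": maps.mufa, "PUFA": maps.pufa, "SFA": maps.sfa}
    for region, mask in region_masks.items():
        for lipid, vol in lipid_maps.items():
            if vol.shape != mask.shape:
                raise ValueError("maps and ROI masks are on different grids")
            rows.append(summarize(vol[mask], spec, lipid, region).as_dict())
    return pd.DataFrame(rows)
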