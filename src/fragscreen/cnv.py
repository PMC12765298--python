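"""Copy-number (CNV) features: GC-corrected binned log2 depth ratios.

Per 1 Mb bin, fragment depth is tallied (midpoint rule, no size filter),
GC-corrected by robust local regression against per-bin GC fraction, and
expressed as a log2 ratio of the sample's median-normalized corrected
depth to a panel-of-normals baseline.  This reproduces the binned front
end of shallow-WGS copy-number callers; no segmentation or tumor-fraction
estimation is performed — the classifier consumes the raw per-bin log2
ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import BinSet
from .fsc import _tally, FragmentSizeClasses

__all__ = [
    "DepthProfile",
    "PanelOfNormals",
    "CnvProfile",
    "bin_depth",
    "gc_correct_depth",
    "build_panel_of_normals",
    "log2_ratio",
    "cnv_cohort_matrix",
]

LOWESS_SPAN = 0.75
LOWESS_ITER = 2
#: corrected/median depth ratios are floored here before log2, keeping
#: zero-count bins finite (log2 floor ~ -10 before baseline division)
RATIO_FLOOR = 1e-3


@dataclass
class DepthProfile:
    binset: BinSet
    raw_counts: np.ndarray  # per usable bin
    corrected: np.ndarray | None = None


@dataclass
class PanelOfNormals:
    """Per-usable-bin median baseline from designated normal samples."""

    binset: BinSet
    baseline: np.ndarray  # median of median-normalized corrected depths
    dispersion: np.ndarray  # per-bin MAD
    n_samples: int
    retained: np.ndarray  # bins kept for the CNV feature space

    def to_frame(self) -> pd.DataFrame:
        usable = self.binset.usable_indices
        return pd.DataFrame(
            {
                "chrom": self.binset.chrom[usable],
                "start": self.binset.start[usable],
                "end": self.binset.end[usable],
                "baseline": self.baseline,
                "dispersion": self.dispersion,
                "retained": self.retained,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class CnvProfile:
    binset: BinSet
    log2_ratio: np.ndarray  # over retained bins, finite
    retained: np.ndarray

    @property
    def feature_vector(self) -> np.ndarray:
        return self.log2_ratio


def bin_depth(fragments: pd.DataFrame, binset: BinSet) -> DepthProfile:
    """Fragments per usable bin by the midpoint rule; all lengths counted."""
    if binset.usable_count < 2:
        raise ValueError("need >= 2 usable bins")
    # reuse the vectorized tally with a size window covering everything
    wide = FragmentSizeClasses(1, 1, 2, 10**9)
    short_c, long_c, _, _ = _tally(fragments, binset, wide)
    return DepthProfile(binset, (short_c + long_c).astype(np.int64))


def gc_correct_depth(depth: DepthProfile, binset: BinSet) -> DepthProfile:
    """GC-correct raw bin counts by robust LOWESS (span 0.75, 2 iterations).

    corrected_i = raw_i * median(raw) / fitted_i with the fitted curve
    floored at a small positive epsilon.  If all usable bins share one GC
    value the correction is skipped with a warning.
    """
    usable = binset.usable_indices
    if len(usable) < 10:
        raise ValueError("need >= 10 usable bins for GC correction")
    gc = binset.gc[usable]
    if np.isnan(gc).any():
        raise ValueError("gc_fraction unset on usable bins")
    raw = depth.raw_counts.astype(float)
    if np.ptp(gc) == 0:
        warnings.warn("all bins share one GC value; GC correction skipped")
        return DepthProfile(binset, depth.raw_counts, raw.copy())
    fitted = lowess(raw, gc, frac=LOWESS_SPAN, it=LOWESS_ITER, return_sorted=False)
    med = np.median(raw)
    eps = max(1e-6, 1e-6 * med)
    corrected = raw * med / np.maximum(fitted, eps)
    return DepthProfile(binset, depth.raw_counts, np.maximum(corrected, 0.0))


def build_panel_of_normals(profiles: Sequence[DepthProfile]) -> PanelOfNormals:
    """Median/MAD baseline across >= 3 GC-corrected normal profiles.

    Each profile is normalized to its own median first; bins with baseline
    < 0.1 or MAD above the 99th percentile are flagged and later removed
    from the CNV feature space for every sample of a run.
    """
    if len(profiles) < 3:
        raise ValueError("need >= 3 normal samples for a panel")
    binset = profiles[0].binset
    mat = []
    for p in profiles:
        if p.corrected is None:
            raise ValueError("panel profiles must be GC-corrected")
        med = np.median(p.corrected)
        if med <= 0:
            raise ValueError("normal profile with non-positive median depth")
        mat.append(p.corrected / med)
    arr = np.vstack(mat)
    baseline = np.median(arr, axis=0)
    dispersion = np.median(np.abs(arr - baseline), axis=0)
    retained = baseline >= 0.1
    if len(dispersion) > 0:
        retained &= dispersion <= np.quantile(dispersion, 0.99)
    return PanelOfNormals(binset, baseline, dispersion, len(profiles), retained)


def log2_ratio(corrected: DepthProfile, pon: PanelOfNormals) -> CnvProfile:
    """log2 of median-normalized corrected depth over the panel baseline."""
    if corrected.corrected is None:
        raise ValueError("profile not GC-corrected")
    if len(corrected.corrected) != len(pon.baseline):
        raise ValueError("profile and panel use different bin sets")
    med = np.median(corrected.corrected)
    if med <= 0:
        raise ValueError("sample median corrected depth is zero")
    norm = np.maximum(corrected.corrected / med, RATIO_FLOOR)
    r = np.log2(norm[pon.retained] / pon.baseline[pon.retained])
    return CnvProfile(corrected.binset, r, pon.retained)


def cnv_cohort_matrix(
    fragments_by_sample: Mapping[str, pd.DataFrame],
    binset: BinSet,
    pon: PanelOfNormals,
) -> pd.DataFrame:
    """Samples x retained-bins matrix of log2 ratios, columns cnv__{chrom}_{start}."""
    labels = np.asarray(binset.labels("cnv__"), dtype=object)[pon.retained]
    rows = {}
    for sid, df in fragments_by_sample.items():
        prof = gc_correct_depth(bin_depth(df, binset), binset)
        rows[sid] = log2_ratio(prof, pon).feature_vector
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(labels))
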