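"""Fragment-size coverage (FSC) features.

Per 5 Mb bin, the coverages of short (100-150 bp) and long (151-220 bp)
cfDNA fragments are tallied and standardized within sample, yielding two
z-scored coverage tracks whose concatenation is the FSC feature vector
(length 2 x usable bins; 1082 on the canonical 541-bin autosomal tiling).
Within-sample standardization makes profiles invariant to sequencing
depth, which the cross-sample classifier requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .genome import BinSet

__all__ = [
    "FragmentSizeClasses",
    "FscProfile",
    "classify_fragment_length",
    "assign_fragment_to_bin",
    "compute_fsc",
    "short_long_ratio",
    "fsc_cohort_matrix",
]


@dataclass(frozen=True)
class FragmentSizeClasses:
    """Inclusive size-class bounds in bp."""

    short_min: int = 100
    short_max: int = 150
    long_min: int = 151
    long_max: int = 220

    def __post_init__(self) -> None:
        if not (0 < self.short_min <= self.short_max < self.long_min <= self.long_max):
            raise ValueError("size classes must be positive, ordered and disjoint")


@dataclass
class FscProfile:
    """Per-usable-bin short/long counts and their within-sample z-scores."""

    binset: BinSet
    short_counts: np.ndarray
    long_counts: np.ndarray
    short_z: np.ndarray
    long_z: np.ndarray
    n_excluded: int  # fragments outside both size classes
    n_unassigned: int  # in-class fragments with midpoint in no usable bin
    degenerate: bool = False  # zero-variance standardization fallback hit

    @property
    def feature_vector(self) -> np.ndarray:
        return np.concatenate([self.short_z, self.long_z])

    @property
    def n_fragments(self) -> int:
        return int(self.short_counts.sum() + self.long_counts.sum()
                   + self.n_excluded + self.n_unassigned)


def classify_fragment_length(
    length: int, classes: FragmentSizeClasses = FragmentSizeClasses()
) -> Literal["short", "long", "excluded"]:
    """Classify one fragment length into short / long / excluded."""
    if length <= 0:
        raise ValueError("fragment length must be positive")
    if classes.short_min <= length <= classes.short_max:
        return "short"
    if classes.long_min <= length <= classes.long_max:
        return "long"
    return "excluded"


def assign_fragment_to_bin(fragment: tuple[str, int, int], binset: BinSet) -> int | None:
    """Bin index containing the fragment midpoint, or None.

    The midpoint rule, floor((start+end)/2), is unambiguous for fragments
    straddling a bin boundary; fragments whose midpoint falls in no usable
    bin (dropped terminal regions, blacklisted bins, unknown chromosomes)
    get None.
    """
    chrom, start, end = fragment
    mid = (start + end) // 2
    idx = binset.bin_index(np.array([chrom], dtype=object), np.array([mid]))[0]
    if idx < 0 or not binset.usable[idx]:
        return None
    return int(idx)


def _zscore(x: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float), True
    return (x - x.mean()) / sd, False


def _tally(fragments: pd.DataFrame, binset: BinSet, classes: FragmentSizeClasses):
    """Vectorized short/long per-usable-bin tallies plus exclusion counts."""
    length = (fragments["end"] - fragments["start"]).to_numpy()
    if np.any(length <= 0):
        raise ValueError("fragment with non-positive length")
    is_short = (length >= classes.short_min) & (length <= classes.short_max)
    is_long = (length >= classes.long_min) & (length <= classes.long_max)
    n_excluded = int((~is_short & ~is_long).sum())

    mid = (fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2
    gidx = binset.bin_index(fragments["chrom"].to_numpy(dtype=object), mid)
    assigned = (gidx >= 0) & np.where(gidx >= 0, binset.usable[np.maximum(gidx, 0)], False)
    n_unassigned = int(((is_short | is_long) & ~assigned).sum())

    usable = binset.usable_indices
    pos = np.full(len(binset), -1, dtype=np.int64)
    pos[usable] = np.arange(len(usable))
    short_counts = np.bincount(pos[gidx[assigned & is_short]], minlength=len(usable))
    long_counts = np.bincount(pos[gidx[assigned & is_long]], minlength=len(usable))
    return short_counts, long_counts, n_excluded, n_unassigned


def compute_fsc(
    fragments: pd.DataFrame,
    binset: BinSet,
    classes: FragmentSizeClasses = FragmentSizeClasses(),
) -> FscProfile:
    """Tally and standardize short/long coverages over the usable bins.

    Zero-variance count vectors (e.g. an empty fragment table) standardize
    to all-zero z-scores with the profile flagged degenerate rather than
    failing.
    """
    if binset.usable_count < 2:
        raise ValueError("need >= 2 usable bins to standardize")
    short_counts, long_counts, n_excluded, n_unassigned = _tally(fragments, binset, classes)
    short_z, d1 = _zscore(short_counts.astype(float))
    long_z, d2 = _zscore(long_counts.astype(float))
    return FscProfile(binset, short_counts, long_counts, short_z, long_z,
                      n_excluded, n_unassigned, degenerate=d1 or d2)


def short_long_ratio(profile: FscProfile, pseudocount: float = 1.0) -> np.ndarray:
    """Per-bin (short + pc) / (long + pc) ratio."""
    return (profile.short_counts + pseudocount) / (profile.long_counts + pseudocount)


def fsc_cohort_matrix(
    fragments_by_sample: Mapping[str, pd.DataFrame],
    binset: BinSet,
    classes: FragmentSizeClasses = FragmentSizeClasses(),
) -> pd.DataFrame:
    """Samples x features FSC matrix, columns short__... then long__... in bin order."""
    cols = binset.labels("short__") + binset.labels("long__")
    rows = {sid: compute_fsc(df, binset, classes).feature_vector
            for sid, df in fragments_by_sample.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
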