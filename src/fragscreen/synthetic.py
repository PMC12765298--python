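"""Synthetic two-group cfDNA cohorts with planted fragmentomic structure.

The simulator produces per-sample fragment tables plus clinical covariates
(PSA, stage, Gleason/ISUP) with the statistical structure the screening
assay exploits:

* cancer samples carry a tumor fragment admixture at fraction ``tf`` whose
  genomic placement follows planted copy-number segments (a diploid
  background contributes ``2(1-tf)`` and the tumor ``tf * c`` copies, so a
  bin with tumor copy number ``c`` has expected depth ratio
  ``(2(1-tf) + c*tf)/2`` against a neutral genome);
* tumor-origin fragments are shorter: lengths are drawn from a truncated
  normal shifted left by ``size_shift`` bp, moving mass into the short
  (100-150 bp) size class;
* per-sample GC bias multiplies bin placement weights by
  ``exp(beta * (gc - 0.5))``, giving the GC-correction stage real bias to
  remove;
* PSA is log-normal per group, stage/grade are sampled labels.

Everything is deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .genome import MB, BinSet, GenomeBuild, HG19_AUTOSOMES

__all__ = [
    "CnvSegment",
    "CohortSpec",
    "SampleRecord",
    "Cohort",
    "DEFAULT_CNV_SEGMENTS",
    "sample_fragment_length",
    "simulate_sample",
    "simulate_cohort",
    "write_cohort",
    "synthetic_build",
    "annotate_gc_synthetic",
]

Label = Literal["cancer", "non-cancer"]


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int
    end: int
    copies: float  # tumor copy number c >= 0 (diploid neutral = 2)

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copy number must be >= 0")
        if self.start >= self.end:
            raise ValueError("segment start must be < end")


#: Arm-level default events echoing recurrent prostate-cancer aberrations
#: (gains on 2p/8q/9q/11q, losses on 6q/13q), hg19 coordinates.
DEFAULT_CNV_SEGMENTS: tuple[CnvSegment, ...] = (
    CnvSegment("chr2", 0, 90 * MB, 3.0),
    CnvSegment("chr8", 48 * MB, 146 * MB, 3.0),
    CnvSegment("chr9", 50 * MB, 141 * MB, 3.0),
    CnvSegment("chr11", 55 * MB, 135 * MB, 3.0),
    CnvSegment("chr6", 62 * MB, 171 * MB, 1.0),
    CnvSegment("chr13", 19 * MB, 115 * MB, 1.0),
)

GLEASON_LEVELS = ("3+3", "3+4", "4+3", "4+4", ">=9")
STAGES = ("I", "II", "III", "IV")


@dataclass
class CohortSpec:
    """Generating law of a synthetic cohort.

    PSA laws are (mu, sigma) of a log-normal in ng/mL; defaults reproduce
    the reported group means (cancer 19.34, non-cancer 3.43 ng/mL).  Stage
    probabilities follow the training-cohort stage composition
    (1, 56, 37, 12 of 106 staged cancers).  Tumor fraction defaults to
    Uniform[0.01, 0.15], echoing early-stage shallow-WGS signal levels;
    ``tf_by_stage`` optionally overrides the range per stage.
    """

    n_cancer: int = 40
    n_noncancer: int = 40
    fragments_per_sample: int = 100_000
    seed: int = 0
    tumor_fraction_range: tuple[float, float] = (0.01, 0.15)
    tf_by_stage: dict[str, tuple[float, float]] | None = None
    cnv_segments: tuple[CnvSegment, ...] = DEFAULT_CNV_SEGMENTS
    size_shift: float = 22.0
    length_mean: float = 167.0
    length_sd: float = 25.0
    length_range: tuple[int, int] = (50, 400)
    gc_bias_sd: float = 0.6
    psa_law_cancer: tuple[float, float] = (np.log(19.34) - 0.5, 1.0)
    psa_law_noncancer: tuple[float, float] = (np.log(3.43) - 0.125, 0.5)
    stage_probs: tuple[float, ...] = (0.01, 0.53, 0.35, 0.11)

    def __post_init__(self) -> None:
        if self.n_cancer <= 0 or self.n_noncancer <= 0 or self.fragments_per_sample <= 0:
            raise ValueError("cohort counts must be positive")
        lo, hi = self.tumor_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("tumor fraction range must lie in [0, 1]")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["cnv_segments"] = [dataclasses.asdict(s) for s in self.cnv_segments]
        return d


@dataclass
class SampleRecord:
    sample_id: str
    label: Label
    psa: float
    tumor_fraction: float = 0.0
    stage: str | None = None
    gleason: str | None = None
    isup: int | None = None

    def __post_init__(self) -> None:
        if self.psa <= 0:
            raise ValueError("psa must be positive")
        if self.label == "non-cancer" and (self.stage or self.gleason or self.isup):
            raise ValueError("non-cancer samples carry no stage/grade")


@dataclass
class Cohort:
    spec: CohortSpec
    samples: list[SampleRecord]
    fragments: dict[str, pd.DataFrame]  # sample_id -> (chrom, start, end)
    binset: BinSet

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "label": [s.label for s in self.samples],
                "psa_ng_ml": [s.psa for s in self.samples],
                "stage": [s.stage or "" for s in self.samples],
                "gleason": [s.gleason or "" for s in self.samples],
                "isup": [s.isup if s.isup is not None else "" for s in self.samples],
            }
        )


def synthetic_build(n_chrom: int = 22) -> GenomeBuild:
    """The hg19 autosome build (optionally truncated to the first n chromosomes)."""
    items = list(HG19_AUTOSOMES.items())[:n_chrom]
    return GenomeBuild(tuple(items))


def annotate_gc_synthetic(binset: BinSet, seed: int, mean: float = 0.41, sd: float = 0.06) -> BinSet:
    """Assign plausible per-bin GC fractions (clipped normal around 0.41).

    Synthetic stand-in for reference-sequence GC when no FASTA is in play;
    deterministic given the seed so simulation and correction see the same
    values.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6C]))
    gc = np.clip(rng.normal(mean, sd, size=len(binset)), 0.25, 0.65)
    return binset.replace(gc=gc)


def _truncnorm_lengths(rng: np.random.Generator, n: int, mean: float, sd: float,
                       lo: int, hi: int) -> np.ndarray:
    """Rounded truncated-normal fragment lengths in [lo, hi]."""
    from scipy.stats import truncnorm

    a, b = (lo - mean) / sd, (hi - mean) / sd
    x = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(x).astype(np.int64), lo, hi)


def sample_fragment_length(
    origin: Literal["background", "tumor"],
    spec: CohortSpec,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw fragment lengths for one origin.

    Background ~ Normal(167, 25) truncated to [50, 400]; tumor identical
    but location-shifted left by ``spec.size_shift`` bp.
    """
    lo, hi = spec.length_range
    mean = spec.length_mean - (spec.size_shift if origin == "tumor" else 0.0)
    return _truncnorm_lengths(rng, size, mean, spec.length_sd, lo, hi)


def _bin_copies(binset: BinSet, segments: tuple[CnvSegment, ...]) -> np.ndarray:
    """Tumor copy number per bin (by bin midpoint), neutral = 2."""
    c = np.full(len(binset), 2.0)
    mid = (binset.start + binset.end) // 2
    for seg in segments:
        m = (binset.chrom == seg.chrom) & (mid >= seg.start) & (mid < seg.end)
        c[m] = seg.copies
    return c


def simulate_sample(
    label: Label,
    tumor_fraction: float,
    spec: CohortSpec,
    binset: BinSet,
    rng: np.random.Generator,
    gc_beta: float = 0.0,
) -> pd.DataFrame:
    """Simulate one sample's fragment table over the usable bins of ``binset``.

    Bin placement probability is proportional to
    ``width * (2(1-tf) + tf*c_bin) * exp(gc_beta * (gc - 0.5))``; within the
    chosen bin the fragment start is uniform, and its length is drawn from
    the tumor or background law according to the bin-specific tumor-origin
    probability ``tf*c / (2(1-tf) + tf*c)``.
    """
    if label == "non-cancer" and tumor_fraction != 0:
        raise ValueError("non-cancer samples must have tumor_fraction 0")
    usable = binset.usable_indices
    if len(usable) == 0:
        raise ValueError("binset has no usable bins")
    tf = float(tumor_fraction)
    copies = _bin_copies(binset, spec.cnv_segments)[usable]
    intensity = 2.0 * (1.0 - tf) + tf * copies
    widths = (binset.end - binset.start)[usable].astype(float)
    gc = binset.gc[usable]
    gc_w = np.exp(gc_beta * (np.nan_to_num(gc, nan=0.5) - 0.5))
    w = widths * intensity * gc_w
    counts = rng.multinomial(spec.fragments_per_sample, w / w.sum())

    p_tumor = np.where(intensity > 0, tf * copies / intensity, 0.0)
    n_tumor = rng.binomial(counts, p_tumor)
    n_bg = counts - n_tumor

    # lengths drawn in bulk, then dealt out to bins by stable sort
    total_tumor, total_bg = int(n_tumor.sum()), int(n_bg.sum())
    len_tumor = sample_fragment_length("tumor", spec, rng, total_tumor)
    len_bg = sample_fragment_length("background", spec, rng, total_bg)

    # tumor fragments listed first within each bin; record order within a
    # sample is not meaningful downstream
    all_idx = np.concatenate([np.repeat(usable, n_tumor), np.repeat(usable, n_bg)])
    all_len = np.concatenate([len_tumor, len_bg])
    order = np.argsort(all_idx, kind="stable")
    all_idx = all_idx[order]
    all_len = all_len[order]

    bstart = binset.start[all_idx]
    bend = binset.end[all_idx]
    u = rng.random(len(all_idx))
    start = (bstart + np.floor(u * (bend - bstart))).astype(np.int64)
    end = start + all_len
    return pd.DataFrame(
        {
            "chrom": binset.chrom[all_idx],
            "start": start,
            "end": end,
        }
    )


def _draw_grade(rng: np.random.Generator) -> tuple[str, int]:
    # grades uncorrelated with fragmentomic signal by construction
    k = int(rng.choice(len(GLEASON_LEVELS), p=[0.15, 0.37, 0.2, 0.13, 0.15]))
    return GLEASON_LEVELS[k], k + 1


def simulate_cohort(spec: CohortSpec, binset: BinSet | None = None) -> Cohort:
    """Simulate a full two-group cohort; deterministic given ``spec.seed``.

    If no binset is given, the hg19 autosomes are tiled at 1 Mb and given
    synthetic GC fractions seeded from ``spec.seed`` (fragment placement
    needs only some tiling; downstream featurization may use its own).
    """
    from .genome import tile_genome

    if binset is None:
        binset = annotate_gc_synthetic(tile_genome(synthetic_build(), MB), spec.seed)
    root = np.random.SeedSequence(int(spec.seed))
    n_total = spec.n_cancer + spec.n_noncancer
    children = root.spawn(n_total)

    samples: list[SampleRecord] = []
    fragments: dict[str, pd.DataFrame] = {}
    for j in range(n_total):
        rng = np.random.default_rng(children[j])
        cancer = j < spec.n_cancer
        sid = f"C{j + 1:03d}" if cancer else f"N{j - spec.n_cancer + 1:03d}"
        if cancer:
            stage = STAGES[int(rng.choice(4, p=list(spec.stage_probs)))]
            lo, hi = (spec.tf_by_stage or {}).get(stage, spec.tumor_fraction_range)
            tf = float(rng.uniform(lo, hi))
            mu, sigma = spec.psa_law_cancer
            gleason, isup = _draw_grade(rng)
        else:
            stage, tf, gleason, isup = None, 0.0, None, None
            mu, sigma = spec.psa_law_noncancer
        psa = float(rng.lognormal(mu, sigma))
        beta = float(rng.normal(0.0, spec.gc_bias_sd))
        label: Label = "cancer" if cancer else "non-cancer"
        frags = simulate_sample(label, tf, spec, binset, rng, gc_beta=beta)
        samples.append(SampleRecord(sid, label, psa, tf, stage, gleason, isup))
        fragments[sid] = frags
    return Cohort(spec, samples, fragments, binset)


def write_cohort(cohort: Cohort, out_dir, overwrite: bool = False) -> Path:
    """Write fragment BED3 tables, the sample sheet CSV and a JSON manifest."""
    out = Path(out_dir)
    sheet_path = out / "samples.csv"
    if sheet_path.exists() and not overwrite:
        raise FileExistsError(f"{sheet_path} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    frag_dir = out / "fragments"
    frag_dir.mkdir(exist_ok=True)
    sheet = cohort.sample_sheet()
    paths = []
    for sid in sheet["sample_id"]:
        p = frag_dir / f"{sid}.bed"
        cohort.fragments[sid].to_csv(p, sep="\t", header=False, index=False)
        paths.append(str(p.relative_to(out)))
    sheet["fragments_path"] = paths
    sheet.to_csv(sheet_path, index=False)
    manifest = {"spec": cohort.spec.to_json(), "seed": cohort.spec.seed,
                "n_samples": len(cohort.samples)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
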