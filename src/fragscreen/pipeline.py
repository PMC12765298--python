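"""End-to-end wiring: fragments -> feature matrices -> scores -> report.

Thin orchestration over the genome, fsc, cnv, classifier and evaluation
modules; this is what the CLI subcommands and the worked examples call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import MB, BinSet, GenomeBuild, tile_genome
from .fsc import FragmentSizeClasses, fsc_cohort_matrix
from .cnv import (
    PanelOfNormals,
    bin_depth,
    build_panel_of_normals,
    cnv_cohort_matrix,
    gc_correct_depth,
)
from .classifier import (
    AssayConfigs,
    FittedAssay,
    ThresholdPolicy,
    choose_threshold,
    run_loocv,
    train_full,
)
from . import evaluation as ev

__all__ = ["FeatureBundle", "extract_features", "score_training_cohort", "evaluate_scores"]

CNV_BIN_WIDTH = 1 * MB
FSC_BIN_WIDTH = 5 * MB


@dataclass
class FeatureBundle:
    cnv: pd.DataFrame  # samples x retained 1 Mb bins, log2 ratios
    fsc: pd.DataFrame  # samples x (2 x usable 5 Mb bins), z-scores
    pon: PanelOfNormals
    binset_cnv: BinSet
    binset_fsc: BinSet


def _transfer_gc(src: BinSet, dst: BinSet) -> BinSet:
    """Average fine-bin GC onto a coarser tiling (same genome, width multiple)."""
    gc = np.full(len(dst), np.nan)
    mid = (src.start + src.end) // 2
    idx = dst.bin_index(src.chrom, mid)
    for i in range(len(dst)):
        vals = src.gc[idx == i]
        vals = vals[~np.isnan(vals)]
        if len(vals):
            gc[i] = vals.mean()
    return dst.replace(gc=gc)


def extract_features(
    fragments_by_sample: Mapping[str, pd.DataFrame],
    normal_fragments: Mapping[str, pd.DataFrame],
    binset_cnv: BinSet,
    binset_fsc: BinSet | None = None,
    classes: FragmentSizeClasses = FragmentSizeClasses(),
) -> FeatureBundle:
    """Compute the CNV and FSC matrices for a cohort.

    ``normal_fragments`` are the designated panel-of-normals samples; to
    avoid leakage they should be disjoint from any evaluation cohort.  If
    no 5 Mb tiling is given it is derived from the 1 Mb tiling's
    chromosomes, inheriting averaged GC.
    """
    if binset_fsc is None:
        sizes = {}
        for c in dict.fromkeys(binset_cnv.chrom):
            sizes[c] = int(binset_cnv.end[binset_cnv.chrom == c].max())
        build = GenomeBuild(tuple(sizes.items()))
        binset_fsc = _transfer_gc(binset_cnv, tile_genome(build, FSC_BIN_WIDTH))
    normals = [
        gc_correct_depth(bin_depth(df, binset_cnv), binset_cnv)
        for df in normal_fragments.values()
    ]
    pon = build_panel_of_normals(normals)
    cnv = cnv_cohort_matrix(fragments_by_sample, binset_cnv, pon)
    fsc = fsc_cohort_matrix(fragments_by_sample, binset_fsc, classes)
    return FeatureBundle(cnv, fsc, pon, binset_cnv, binset_fsc)


def score_training_cohort(
    bundle: FeatureBundle,
    samples: pd.DataFrame,
    configs: AssayConfigs = AssayConfigs(),
    loocv: bool = False,
) -> tuple[pd.DataFrame, FittedAssay]:
    """Train on a cohort and return its ScoreSet plus the fitted assay.

    With ``loocv=True`` the returned scores are out-of-sample (the whole
    pipeline re-trained in each leave-one-out fold); the fitted assay is
    always the final full-cohort model.
    """
    ids = samples["sample_id"].tolist()
    cnv_X = bundle.cnv.loc[ids].to_numpy()
    fsc_X = bundle.fsc.loc[ids].to_numpy()
    psa = samples["psa_ng_ml"].to_numpy(dtype=float)
    y = (samples["label"] == "cancer").astype(int).to_numpy()
    fit = train_full(cnv_X, fsc_X, psa, y, configs)
    if loocv:
        scores = run_loocv(cnv_X, fsc_X, psa, y, configs, sample_ids=ids)
    else:
        scores = fit.score(cnv_X, fsc_X, psa, provenance="in-sample")
        scores.insert(0, "sample_id", ids)
    return scores, fit


def evaluate_scores(
    scores: pd.DataFrame,
    samples: pd.DataFrame,
    threshold: float,
    score_col: str = "fragmentomic_score",
    grey_zone: bool = True,
) -> dict:
    """Full numeric evaluation report for one score column at a threshold."""
    merged = scores.merge(samples, on="sample_id", validate="one_to_one")
    s = merged[score_col].to_numpy(dtype=float)
    y = (merged["label"] == "cancer").astype(int).to_numpy()
    psa = merged["psa_ng_ml"].to_numpy(dtype=float)
    report: dict = {
        "n": int(len(merged)),
        "threshold": threshold,
        "auc": ev.roc_auc(s, y),
        "metrics": ev.confusion_metrics(s, y, threshold).as_dict(),
    }
    try:
        cal = ev.calibration(s, y)
        report["calibration"] = {
            "intercept": cal.intercept, "slope": cal.slope,
            "intercept_free": cal.intercept_free,
        }
    except ValueError:
        report["calibration"] = None
    if grey_zone:
        gz = ev.grey_zone_report(s, y, psa, threshold)
        report["grey_zone"] = {
            "n": gz.n,
            "assay": gz.assay.as_dict() if gz.assay else None,
            "psa_as_score": gz.psa_as_score.as_dict() if gz.psa_as_score else None,
            "auc_assay": gz.auc_assay,
            "auc_psa": gz.auc_psa,
        }
    if "stage" in merged.columns:
        stage = merged["stage"].fillna("").astype(str).to_numpy(dtype=object)
        report["per_stage_sensitivity"] = ev.per_stage_sensitivity(
            s, y, stage, threshold
        ).to_dict(orient="records")
    return report
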