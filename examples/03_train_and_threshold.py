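"""Train the stacked classifier and pick a specificity-anchored threshold.

Trains per-family gradient-boosted base learners on t-test-selected
features, stacks their out-of-fold scores with an elastic-net logistic
model, adds the PSA-integrated XGBoost model, then selects the decision
threshold at targeted 98% specificity among non-cancer samples with
PSA >= 4 ng/mL.
"""

import numpy as np

from fragscreen.classifier import (
    AssayConfigs,
    BaseLearnerConfig,
    StackerConfig,
    choose_threshold,
)
from fragscreen.evaluation import confusion_metrics, roc_auc
from fragscreen.genome import MB, GenomeBuild, tile_genome
from fragscreen.pipeline import extract_features, score_training_cohort
from fragscreen.synthetic import (
    CnvSegment,
    CohortSpec,
    annotate_gc_synthetic,
    simulate_cohort,
)

build = GenomeBuild.from_dict({"chr2": 100 * MB, "chr6": 80 * MB, "chr7": 80 * MB})
binset = annotate_gc_synthetic(tile_genome(build, MB), seed=5)
segments = (CnvSegment("chr2", 0, 60 * MB, 3.0), CnvSegment("chr6", 10 * MB, 70 * MB, 1.0))

cohort = simulate_cohort(
    CohortSpec(n_cancer=20, n_noncancer=220, fragments_per_sample=20_000, seed=3,
               cnv_segments=segments, tumor_fraction_range=(0.1, 0.2)),
    binset,
)
panel = simulate_cohort(
    CohortSpec(n_cancer=1, n_noncancer=5, fragments_per_sample=30_000, seed=1003,
               cnv_segments=segments),
    binset,
)
normals = {s: panel.fragments[s]
           for s in panel.sample_sheet().query("label == 'non-cancer'")["sample_id"]}
bundle = extract_features(cohort.fragments, normals, binset)

sheet = cohort.sample_sheet()
configs = AssayConfigs(base=BaseLearnerConfig(n_configs=6, inner_folds=3),
                       stacker=StackerConfig(n_lambda=4, inner_folds=3), seed=9)
scores, fit = score_training_cohort(bundle, sheet, configs, loocv=False)

y = (sheet["label"] == "cancer").astype(int).to_numpy()
psa = sheet["psa_ng_ml"].to_numpy(float)
frag = scores["fragmentomic_score"].to_numpy(float)
print(f"training AUC: CNV {roc_auc(scores['cnv_score'], y):.3f}, "
      f"FSC {roc_auc(scores['fsc_score'], y):.3f}, "
      f"stacked {roc_auc(frag, y):.3f}, "
      f"integrated {roc_auc(scores['integrated_score'], y):.3f}")

res = choose_threshold(frag, y, psa)
print(f"threshold {res.threshold:.4f} chosen on {res.n_subcohort} non-cancer "
      f"samples with PSA >= 4 (subcohort specificity "
      f"{100 * res.achieved_specificity:.1f}%)")
if np.isfinite(res.threshold):
    m = confusion_metrics(frag, y, res.threshold)
    print(f"whole cohort at that threshold: sensitivity {100 * m.sensitivity:.1f}%, "
          f"specificity {100 * m.specificity:.1f}%")
else:
    # with < 50 subcohort samples only 100% specificity is attainable and
    # the threshold lands above every subcohort score
    print("subcohort too small for a finite 98%-specificity cut-point")
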