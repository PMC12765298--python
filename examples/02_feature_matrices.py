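"""Extract FSC and CNV feature matrices from a simulated cohort.

FSC: short (100-150 bp) and long (151-220 bp) fragment coverages per 5 Mb
bin, z-scored within sample.  CNV: GC-corrected, median-normalized log2
depth ratios per 1 Mb bin against a panel of normals simulated
independently of the cohort.
"""

import numpy as np

from fragscreen.genome import MB, GenomeBuild, tile_genome
from fragscreen.pipeline import extract_features
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
    CohortSpec(n_cancer=8, n_noncancer=8, fragments_per_sample=30_000, seed=2,
               cnv_segments=segments, tumor_fraction_range=(0.1, 0.2)),
    binset,
)
panel = simulate_cohort(
    CohortSpec(n_cancer=1, n_noncancer=5, fragments_per_sample=30_000, seed=1002,
               cnv_segments=segments),
    binset,
)
normals = {s: panel.fragments[s]
           for s in panel.sample_sheet().query("label == 'non-cancer'")["sample_id"]}

bundle = extract_features(cohort.fragments, normals, binset)
print(f"CNV matrix: {bundle.cnv.shape[0]} samples x {bundle.cnv.shape[1]} bins (1 Mb)")
print(f"FSC matrix: {bundle.fsc.shape[0]} samples x {bundle.fsc.shape[1]} features "
      f"(2 x {bundle.fsc.shape[1] // 2} five-Mb bins)")

sheet = cohort.sample_sheet().set_index("sample_id")
cancer = sheet[sheet["label"] == "cancer"].index
gain = [c for c in bundle.cnv.columns if c.startswith("cnv__chr2_")][:55]
loss = [c for c in bundle.cnv.columns if c.startswith("cnv__chr6_")][15:55]
print(f"\ncancer-group mean log2 ratio in planted gain: "
      f"{bundle.cnv.loc[cancer, gain].mean().mean():+.3f} (expected > 0)")
print(f"cancer-group mean log2 ratio in planted loss: "
      f"{bundle.cnv.loc[cancer, loss].mean().mean():+.3f} (expected < 0)")
# At tumor fraction tf a gain with tumor copy number c shifts the depth
# ratio to (2(1-tf) + c*tf)/2, e.g. log2(1.075) ~ +0.10 at tf = 0.15, c = 3.
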