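"""Simulate a small synthetic cfDNA screening cohort and inspect it.

Builds a two-group cohort (cancer vs non-cancer) on a three-chromosome
genome: cancer samples carry a tumor fragment admixture placed according
to planted copy-number segments and drawn from a left-shifted fragment
length law; PSA is log-normal per group.
"""

import numpy as np

from fragscreen.genome import MB, GenomeBuild, tile_genome
from fragscreen.synthetic import (
    CnvSegment,
    CohortSpec,
    annotate_gc_synthetic,
    simulate_cohort,
)

build = GenomeBuild.from_dict({"chr2": 100 * MB, "chr6": 80 * MB, "chr7": 80 * MB})
binset = annotate_gc_synthetic(tile_genome(build, MB), seed=5)

spec = CohortSpec(
    n_cancer=5,
    n_noncancer=5,
    fragments_per_sample=20_000,
    seed=1,
    cnv_segments=(
        CnvSegment("chr2", 0, 60 * MB, 3.0),   # planted gain
        CnvSegment("chr6", 10 * MB, 70 * MB, 1.0),  # planted loss
    ),
    tumor_fraction_range=(0.1, 0.2),
)
cohort = simulate_cohort(spec, binset)

print(cohort.sample_sheet().to_string(index=False))
frags = cohort.fragments["C001"]
lengths = frags["end"] - frags["start"]
print(f"\nC001: {len(frags)} fragments, median length {int(np.median(lengths))} bp")
print(f"short (100-150 bp) fraction: {((lengths >= 100) & (lengths <= 150)).mean():.3f}")
# Cancer samples mix in tumor fragments ~22 bp shorter than the 167 bp
# background mode, so their short-fragment fraction sits above that of the
# non-cancer samples (compare with N001 below).
n_lengths = cohort.fragments["N001"].eval("end - start")
print(f"N001 short fraction:         "
      f"{((n_lengths >= 100) & (n_lengths <= 150)).mean():.3f}")
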