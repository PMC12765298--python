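"""Shared fixtures: toy genomes, small synthetic cohorts, desk-scale configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fragscreen.genome import MB, GenomeBuild, tile_genome
from fragscreen.synthetic import (
    CnvSegment,
    CohortSpec,
    annotate_gc_synthetic,
    simulate_cohort,
)
from fragscreen.classifier import (
    AssayConfigs,
    BaseLearnerConfig,
    StackerConfig,
)


@pytest.fixture(scope="session")
def toy_build() -> GenomeBuild:
    return GenomeBuild.from_dict({"chrA": 10 * MB, "chrB": 7 * MB})


@pytest.fixture(scope="session")
def toy_binset(toy_build):
    """17 one-megabase bins with synthetic GC."""
    return annotate_gc_synthetic(tile_genome(toy_build, MB), seed=11)


@pytest.fixture(scope="session")
def small_build() -> GenomeBuild:
    """Three-chromosome 260 Mb genome for desk-scale cohort simulations."""
    return GenomeBuild.from_dict({"chr2": 100 * MB, "chr6": 80 * MB, "chr7": 80 * MB})


@pytest.fixture(scope="session")
def small_binset(small_build):
    return annotate_gc_synthetic(tile_genome(small_build, MB), seed=5)


@pytest.fixture(scope="session")
def small_segments() -> tuple[CnvSegment, ...]:
    return (
        CnvSegment("chr2", 0, 60 * MB, 3.0),
        CnvSegment("chr6", 10 * MB, 70 * MB, 1.0),
    )


@pytest.fixture(scope="session")
def signal_cohort(small_binset, small_segments):
    """24-sample cohort with strong planted signal (tf 0.1-0.2)."""
    spec = CohortSpec(
        n_cancer=12, n_noncancer=12, fragments_per_sample=20_000, seed=3,
        cnv_segments=small_segments, tumor_fraction_range=(0.1, 0.2),
    )
    return simulate_cohort(spec, small_binset)


@pytest.fixture(scope="session")
def panel_cohort(small_binset, small_segments):
    """Independent normals for the panel (separate seed stream)."""
    spec = CohortSpec(
        n_cancer=1, n_noncancer=6, fragments_per_sample=20_000, seed=1003,
        cnv_segments=small_segments,
    )
    cohort = simulate_cohort(spec, small_binset)
    return {
        sid: cohort.fragments[sid]
        for sid in cohort.sample_sheet().query("label == 'non-cancer'")["sample_id"]
    }


@pytest.fixture(scope="session")
def desk_configs() -> AssayConfigs:
    """Reduced search breadth for fast test runs; search breadth is compute
    budget, not a study condition."""
    return AssayConfigs(
        base=BaseLearnerConfig(n_configs=4, inner_folds=3),
        stacker=StackerConfig(n_lambda=4, inner_folds=3),
        seed=7,
    )


def toy_fragments(rows: list[tuple[str, int, int]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
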