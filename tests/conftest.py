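"""Shared fixtures: small synthetic cohorts and hand-built fragment sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fragmedip import (
    FragmentSet,
    GenomeLayout,
    SimulationConfig,
    WindowGrid,
    deduplicate,
    filter_size_range,
    simulate_cohort,
)
from fragmedip.fragment_io import make_fragment_set


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A fast cohort: 80 x 10-kb windows, ~375 Input fragments per window."""
    return SimulationConfig(
        chrom_lengths=(("chr1", 400_000), ("chr2", 400_000)),
        n_input_fragments=30_000,
        n_hypo=8,
        n_hyper=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_strong_cfg() -> SimulationConfig:
    """Strong-effect preset scaled down to the small genome, 8v8."""
    return SimulationConfig.strong_effect(
        chrom_lengths=(("chr1", 400_000), ("chr2", 400_000)),
        n_input_fragments=60_000,
        n_hypo=20,
        n_hyper=10,
        n_healthy=8,
        n_cancer=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_strong_cohort(small_strong_cfg):
    return simulate_cohort(small_strong_cfg)


def prep(fs: FragmentSet) -> FragmentSet:
    """Deduplicate and size-filter, the standard pre-analysis treatment."""
    return filter_size_range(deduplicate(fs))


@pytest.fixture()
def tiny_grid() -> WindowGrid:
    return WindowGrid(GenomeLayout(("chr1",), (30_000,)), 10_000)


def fragments_of_lengths(lengths, sample_id="S", library="INPUT",
                         chrom="chr1", start=0) -> FragmentSet:
    """One fragment per requested length, laid head-to-head from ``start``."""
    lengths = list(lengths)
    starts, ends, pos = [], [], start
    for L in lengths:
        starts.append(pos)
        ends.append(pos + L)
        pos += L
    return make_fragment_set(sample_id, library,
                             [chrom] * len(lengths), starts, ends,
                             [f"B{i}" for i in range(len(lengths))])
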