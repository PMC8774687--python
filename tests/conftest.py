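"""Shared fixtures: toy SAM files and session-scoped simulated cohorts.

The heavier cohorts are session-scoped so the property tests (null
calibration, power ordering, specificity, fetal-fraction sweep) reuse one
panel and reference instead of re-simulating per test.
"""
from __future__ import annotations

import numpy as np
import pytest

from fragcnv import (
    CNVSpec,
    ControlPanel,
    SimParams,
    build_reference_set,
    miniature_grid,
    simulate_cohort,
    simulate_sample,
)
from fragcnv.simdata import write_toy_sam

# hand-enumerated 5-pair fixture: pair1 ok, pair2 reuses pair1's first start
# (duplicate), pair3 has a MAPQ-0 mate, pairs 4-5 ok -> 3 retained
FIVE_PAIRS = [
    {"name": "p1", "start1": 1000, "start2": 1150},
    {"name": "p2", "start1": 1000, "start2": 1400},
    {"name": "p3", "start1": 2000, "start2": 2150, "mapq1": 0},
    {"name": "p4", "start1": 3000, "start2": 3170},
    {"name": "p5", "start1": 4000, "start2": 4200},
]


@pytest.fixture
def five_pair_sam(tmp_path):
    path = tmp_path / "five.sam"
    write_toy_sam(path, FIVE_PAIRS)
    return path


@pytest.fixture
def mapq_ladder_sam(tmp_path):
    """Six otherwise-valid pairs whose mates carry MAPQ 0..5."""
    pairs = [
        {"name": f"q{q}", "start1": 10_000 * (q + 1), "start2": 10_000 * (q + 1) + 170,
         "mapq1": q, "mapq2": q}
        for q in range(6)
    ]
    path = tmp_path / "mapq.sam"
    write_toy_sam(path, pairs)
    return path


@pytest.fixture(scope="session")
def mini_params():
    """8 x 30 Mb pseudo-chromosomes at 750 kb bins, whole-chr8 gain."""
    grid = miniature_grid(n_chroms=8, chrom_length=30_000_000, bin_size=750_000)
    return SimParams(
        grid=grid,
        n_controls=20,
        n_cases=20,
        coverage=2600.0,
        ff=0.075,
        cnv=CNVSpec("chr8", 0, 30_000_000, "gain"),
        seed=7,
    )


@pytest.fixture(scope="session")
def mini_cohort(mini_params):
    controls, cases, truth = simulate_cohort(mini_params)
    return controls, cases, truth


@pytest.fixture(scope="session")
def mini_ref(mini_cohort):
    controls, _, _ = mini_cohort
    return build_reference_set(ControlPanel(controls), K=100, n_comp=2)


@pytest.fixture(scope="session")
def null_queries(mini_params):
    """20 extra negative samples disjoint from the panel (seeds 3000+)."""
    return [
        simulate_sample(mini_params, is_case=False, seed=3000 + i)
        for i in range(20)
    ]


@pytest.fixture(scope="session")
def calib_setup():
    """Large null cohort for Z calibration: 2200 bins, disjoint queries."""
    grid = miniature_grid(n_chroms=22, chrom_length=75_000_000, bin_size=750_000)
    params = SimParams(
        grid=grid, n_controls=25, n_cases=0, coverage=400.0, seed=11
    )
    controls, _, _ = simulate_cohort(params)
    ref = build_reference_set(ControlPanel(controls), K=300, n_comp=2)
    queries = [simulate_sample(params, False, seed=5000 + i) for i in range(3)]
    return ref, queries
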