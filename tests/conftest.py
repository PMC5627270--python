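"""Shared fixtures: simulated worlds and pipeline runs reused across tests.

The end-to-end objects are expensive (seconds each), so they are built
once per session. Tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from ysubtract.evaluate import match_candidates
from ysubtract.mapping import compute_coverage, map_reads
from ysubtract.pipeline import PipelineConfig, PipelineInputs, run_pipeline
from ysubtract.seqio import flatten_pairs
from ysubtract.simulate import SimConfig, SimulatedWorld, YGeneSpec, simulate_world

END_TO_END_SEEDS = (1, 2, 3, 4, 5)


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """A reduced world for tests that rerun the pipeline many times."""
    genes = [
        YGeneSpec("yu_01", "unique", 0.0, {"head": 0.1, "gonad": 1.0}, 780),
        YGeneSpec("yu_02", "unique", 0.0, {"head": 0.1, "gonad": 1.0}, 840),
        YGeneSpec("ya_01", "autosomal_acquisition", 0.20, {"head": 0.1, "gonad": 1.0}, 780),
        YGeneSpec("yx_01", "X_escapee", 0.20, {"head": 0.1, "gonad": 1.0}, 780),
        YGeneSpec("yf_01", "recent_duplicate", 0.02, {"head": 0.1, "gonad": 1.0}, 780),
        YGeneSpec("yr_01", "repeat_embedded", 0.0, {"head": 0.1, "gonad": 1.0}, 780),
    ]
    defaults = dict(
        seed=seed,
        n_autosomal_scaffolds=3,
        n_x_scaffolds=2,
        n_y_scaffolds=2,
        scaffold_len=5000,
        y_gene_spec=genes,
        n_shared_genes=3,
        n_x_genes=2,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_world() -> SimulatedWorld:
    return simulate_world(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_world):
    """(inputs, report, confusion) for the default world at seed 1."""
    inputs = PipelineInputs.from_world(default_world)
    report = run_pipeline(inputs, PipelineConfig())
    confusion = match_candidates(report.candidates, default_world)
    return inputs, report, confusion


@pytest.fixture(scope="session")
def multiseed_runs():
    """(world, report, confusion) per seed for the five end-to-end seeds."""
    out = []
    for seed in END_TO_END_SEEDS:
        world = simulate_world(SimConfig(seed=seed))
        report = run_pipeline(PipelineInputs.from_world(world), PipelineConfig())
        out.append((world, report, match_candidates(report.candidates, world)))
    return out


@pytest.fixture(scope="session")
def scaffold_coverage(multiseed_runs):
    """Per-seed scaffold coverage profiles of the female genome."""
    from ysubtract.mapping import library_bases

    out = []
    for world, _, _ in multiseed_runs:
        m_reads = list(flatten_pairs(world.reads("male", "genomic")))
        f_reads = list(flatten_pairs(world.reads("female", "genomic")))
        cov = compute_coverage(
            map_reads(m_reads, world.female_genome),
            map_reads(f_reads, world.female_genome),
            world.female_genome,
            total_male_bases=library_bases(m_reads),
            total_female_bases=library_bases(f_reads),
        )
        out.append((world, cov))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
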