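"""Shared fixtures: the default synthetic benchmark and one finished run.

The expensive objects (benchmark generation, the full iterative search and
the classification stage) are session-scoped so the whole suite pays for
them once.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from famforge.iterpipe import PipelineParams, run_pipeline

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")
from famforge.phyloclass import classify_homologs
from famforge.synthdata import BenchmarkConfig, generate_benchmark, seed_alignment

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark():
    """Default benchmark: 3 proteomes x (3x20 family + 20 decoys + 200
    background + 2 tandems), seed 1."""
    proteomes, truth = generate_benchmark(BenchmarkConfig(seed=BENCHMARK_SEED))
    return proteomes, truth


@pytest.fixture(scope="session")
def db(benchmark):
    proteomes, _ = benchmark
    return [r for pid in sorted(proteomes) for r in proteomes[pid]]


@pytest.fixture(scope="session")
def db_map(db):
    return {r.id: r for r in db}


@pytest.fixture(scope="session")
def truth(benchmark):
    return benchmark[1]


@pytest.fixture(scope="session")
def seed_aln(truth):
    return seed_alignment(truth, "subfamily_1", 5)


@pytest.fixture(scope="session")
def pipeline_state(seed_aln, db):
    """The iterative search run to its fixed point on the benchmark."""
    return run_pipeline(seed_aln, db, PipelineParams(seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def reference_labels(truth, pipeline_state):
    """Three reference members per subfamily, emulating curated seeds."""
    refs = {}
    for sf in ("subfamily_1", "subfamily_2", "subfamily_3"):
        ids = sorted(i for i, lab in truth.labels.items()
                     if lab == sf and i in pipeline_state.homolog_ids)[:3]
        for i in ids:
            refs[i] = sf
    return refs


@pytest.fixture(scope="session")
def classification(pipeline_state, db_map, truth, reference_labels):
    return classify_homologs(pipeline_state.master_alignment,
                             pipeline_state.match_columns,
                             db_map, reference_labels, truth.proteomes,
                             seed=BENCHMARK_SEED)
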