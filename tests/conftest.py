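"""Shared fixtures: one small simulation for module tests and the
full-scale runs the recovery tests consume (built once per session)."""
from __future__ import annotations

import time

import pytest

import rrbskit as rk
from rrbskit.pipeline import run_analysis

SMALL_CONFIG = dict(
    tissues=("liver", "muscle", "spleen"),
    chrom_length=150_000, n_genes=36, n_cgis=15,
    n_ase_genes=4, n_monoallelic_genes=2, n_nonase_het_genes=8,
)


@pytest.fixture(scope="session")
def small_sim() -> rk.SimulatedData:
    return rk.simulate_dataset(rk.SimConfig(seed=3, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_analysis(small_sim):
    return run_analysis(small_sim)


@pytest.fixture(scope="session")
def default_run():
    """Full default-scale individual (2 Mb genome, 8 tissues) plus the
    wall-clock time of simulation + analysis."""
    t0 = time.perf_counter()
    sim = rk.simulate_dataset(rk.SimConfig(seed=7))
    result = run_analysis(sim)
    elapsed = time.perf_counter() - t0
    return sim, result, elapsed


@pytest.fixture(scope="session")
def validation_run():
    """Second individual sharing the first one's planted truth."""
    sim = rk.simulate_dataset(rk.SimConfig(seed=1007, truth_seed=7))
    return sim, run_analysis(sim)


@pytest.fixture(scope="session")
def male_run():
    """Male methylome (no X hypermethylation), reduced scale."""
    cfg = rk.SimConfig(seed=21, sex="male", tissues=("liver", "muscle"))
    sim = rk.simulate_dataset(cfg)
    return sim, run_analysis(sim)
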