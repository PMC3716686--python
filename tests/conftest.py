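"""Shared fixtures: scoring params and cached pipeline runs.

The expensive end-to-end runs (2-Mb benchmark genome, reduced-divergence
duplication benchmark, and a small pipeline bundle for unit tests) are
session-scoped so the whole suite pays for each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from numtscape.align import ScoringParams
from numtscape.evaluate import (
    duplication_config,
    recovery_config,
    run_recovery_experiment,
)
from numtscape.pipeline import PipelineConfig, run_synthetic
from numtscape.simulate import EstSpec, SimConfig

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


@pytest.fixture(scope="session")
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=5,
        nuclear_length=700_000,
        n_scaffolds=2,
        n_genes=30,
        n_insertions=40,
        duplication_spec=((2, 4), (3, 1)),
        n_interrupted=4,
        n_intronic=5,
        est_spec=EstSpec(pure_mito=3, chimeric_utr5=2, chimeric_internal=2, plain_nuclear=2),
    )


@pytest.fixture(scope="session")
def small_run(small_config) -> dict:
    """Full pipeline on a 700-kb synthetic genome."""
    return run_synthetic(small_config, PipelineConfig())


@pytest.fixture(scope="session")
def recovery_run() -> dict:
    """The 2-Mb, 100-insertion planted-NUMT benchmark (divergence <= 10%)."""
    return run_recovery_experiment(seed=1)


@pytest.fixture(scope="session")
def duplication_run() -> dict:
    """The same benchmark at divergence <= 5%, for exact family recovery."""
    return run_recovery_experiment(seed=1, sim_config=duplication_config(1))
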