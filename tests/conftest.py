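"""Shared fixtures: session-scoped synthetic pools (template construction
and pool sampling are the expensive steps, so they are built once)."""

from __future__ import annotations

import numpy as np
import pytest

from hairpinxb.classify import default_hairpin_criteria
from hairpinxb.structures import Atom, Conformer, ConformerPool
from hairpinxb.synthetic import (
    GeneratorConfig,
    NoiseModel,
    build_folded_template,
    sample_pool,
    simulate_observables,
)


@pytest.fixture(scope="session")
def gen_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=101)


@pytest.fixture(scope="session")
def template(gen_cfg):
    return build_folded_template(gen_cfg)


@pytest.fixture(scope="session")
def hairpin_criteria():
    return default_hairpin_criteria()


@pytest.fixture(scope="session")
def pool_and_truth(gen_cfg):
    return sample_pool(gen_cfg)


@pytest.fixture(scope="session")
def small_diverse_pool():
    """Five well-separated conformers (large jitter, no near-duplicates)
    with a generic truth weight vector: the well-conditioned recovery
    setting."""
    cfg = GeneratorConfig(
        n_folded=3, n_unfolded=2, dihedral_jitter=10.0, sidechain_jitter=120.0,
        seed=77,
    )
    pool, truth = sample_pool(cfg)
    weights = np.array([0.35, 0.10, 0.05, 0.30, 0.20])
    truth.populations = weights / weights.sum()
    return cfg, pool, truth


@pytest.fixture(scope="session")
def noiseless_observables(pool_and_truth):
    pool, truth = pool_and_truth
    return simulate_observables(pool, truth, NoiseModel(0.0, 0.0, 0.0), seed=11)


def make_toy_conformer(coords, elements=None, names=None, id="toy") -> Conformer:
    """Small free-form conformer for geometry unit tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    elements = elements or ["C"] * n
    names = names or [f"A{i+1}" for i in range(n)]
    atoms = [
        Atom(names[i], elements[i], 1, "TOY", coords[i]) for i in range(n)
    ]
    return Conformer(id, atoms)


@pytest.fixture
def toy_factory():
    return make_toy_conformer
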