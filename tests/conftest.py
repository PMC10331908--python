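"""Shared fixtures: small synthetic worlds reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from beaknest import forest, materials, phylo, synth


@pytest.fixture(scope="session")
def lexicon():
    return materials.load_lexicon()


@pytest.fixture(scope="session")
def small_dataset():
    """150-species default-config world with 5 topologies."""
    return synth.generate_dataset(synth.SynthConfig(n_species=150, n_trees=5, seed=7))


@pytest.fixture(scope="session")
def small_rf_config():
    return forest.RFConfig(n_trees=150, seed=0)


@pytest.fixture(scope="session")
def yule_tree_200():
    return synth.simulate_tree(200, seed=31)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def star_tree(labels, length=1.0):
    return phylo.read_newick(
        "(" + ",".join(f"{l}:{length}" for l in labels) + ");"
    )
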