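import numpy as np
import pandas as pd
import pytest

from reeffd import (
    SyntheticConfig,
    expand_traits,
    fixture_small,
    generate,
)
from reeffd.trait_coding import BinaryTraitMatrix, TraitTable


def make_random_table(
    rng: np.random.Generator,
    n_species: int = 8,
    trait_sizes: tuple[int, ...] = (3, 2),
    multi_prob: float = 0.25,
) -> TraitTable:
    """Random multi-valued trait table for property tests."""
    schema = {
        f"trait{t + 1}": tuple(f"t{t + 1}c{c + 1}" for c in range(k))
        for t, k in enumerate(trait_sizes)
    }
    assignments = {}
    for i in range(n_species):
        row = {}
        for trait, cats in schema.items():
            n = 1
            while n < len(cats) and rng.random() < multi_prob:
                n += 1
            chosen = rng.choice(len(cats), size=n, replace=False)
            row[trait] = frozenset(cats[j] for j in chosen)
        assignments[f"sp{i + 1}"] = row
    return TraitTable(schema=schema, assignments=assignments)


def make_random_matrix(rng, **kwargs) -> BinaryTraitMatrix:
    return expand_traits(make_random_table(rng, **kwargs))


@pytest.fixture(scope="session")
def small_fixture():
    return fixture_small()


@pytest.fixture(scope="session")
def small_survey():
    """A modest synthetic survey shared across tests (120 species)."""
    config = SyntheticConfig(seed=42, n_species=120)
    return config, *generate(config)
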