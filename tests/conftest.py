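"""Shared fixtures: toy models, synthetic catalogs and helix structures."""

from __future__ import annotations

import numpy as np
import pytest

from krabstrat.hmm import ProfileHMM, build_profile
from krabstrat.synth import (
    SyntheticCatalogSpec,
    builtin_generators,
    ideal_helix,
    reference_stand_ins,
    sample_catalog,
)


def random_profile(rng: np.random.Generator, n_match: int,
                   active_letters: int = 4) -> ProfileHMM:
    """A random valid profile concentrated on the first few letters.

    Emissions put almost all mass on a reduced alphabet so short test
    sequences over those letters exercise non-trivial likelihoods.
    """
    def emission_rows(n):
        rows = np.full((n, 20), 1e-4)
        for k in range(n):
            rows[k, :active_letters] += rng.dirichlet(np.ones(active_letters))
        return rows / rows.sum(axis=1, keepdims=True)

    t_m = rng.dirichlet(np.ones(3), size=n_match)
    t_i = rng.dirichlet(np.ones(2), size=n_match)
    t_d = rng.dirichlet(np.ones(2), size=n_match)
    t_m[-1] = (1.0, 0.0, 0.0)
    t_d[-1] = (1.0, 0.0)
    return ProfileHMM(
        n_match=n_match,
        match_emissions=emission_rows(n_match),
        insert_emissions=emission_rows(n_match),
        t_m=t_m,
        t_i=t_i,
        t_d=t_d,
        begin=rng.dirichlet(np.ones(2)),
        background=np.full(20, 1 / 20),
        name=f"random{n_match}",
    )


@pytest.fixture(scope="session")
def generators():
    return builtin_generators()


@pytest.fixture(scope="session")
def stand_ins():
    return reference_stand_ins()


@pytest.fixture(scope="session")
def small_catalog():
    """20 entries (5 per group) at mild divergence, fixed seed."""
    spec = SyntheticCatalogSpec(n_per_group=5, divergence=0.05, seed=11)
    return sample_catalog(spec)


@pytest.fixture(scope="session")
def peaked_model():
    """A sharply peaked 6-state model built from identical rows."""
    return build_profile(["ACDEFG"] * 8, name="peaked")


@pytest.fixture
def helix12():
    return ideal_helix(12)
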