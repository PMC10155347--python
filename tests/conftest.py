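"""Shared fixtures: small synthetic datasets generated at test time."""

import pytest

from methylotype import (
    MethylomeSimSpec,
    ReadSimSpec,
    intersect_profiles,
    select_informative_sites,
    simulate_reads,
    simulate_reference_pair,
)


@pytest.fixture(scope="session")
def separable_refs():
    """Fully separable tumor/immune pair: tumor 100%, immune 0% everywhere."""
    spec = MethylomeSimSpec(
        n_sites=2000, informative_fraction=1.0, divergence=100.0, seed=11
    )
    return simulate_reference_pair(spec)


@pytest.fixture(scope="session")
def separable_sites(separable_refs):
    tumor, immune, _ = separable_refs
    return select_informative_sites(intersect_profiles(tumor, immune))


@pytest.fixture(scope="session")
def realistic_refs():
    """Partially informative pair with 80-point divergence at half the sites."""
    spec = MethylomeSimSpec(
        n_sites=2000, informative_fraction=0.5, divergence=80.0, seed=23
    )
    return simulate_reference_pair(spec)


@pytest.fixture(scope="session")
def realistic_sites(realistic_refs):
    tumor, immune, _ = realistic_refs
    return select_informative_sites(intersect_profiles(tumor, immune))


@pytest.fixture(scope="session")
def mixed_read_pools(separable_refs):
    """Labelled tumor and immune read pools from the separable references."""
    tumor, immune, _ = separable_refs
    t_reads, t_truth = simulate_reads(tumor, ReadSimSpec(n_reads=1500, seed=5))
    i_reads, i_truth = simulate_reads(immune, ReadSimSpec(n_reads=1500, seed=6))
    return t_reads, i_reads, t_truth, i_truth
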