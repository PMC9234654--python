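from __future__ import annotations

import numpy as np
import pytest

from amphigen.datatypes import Individual, MicrosatDataset, sorted_call
from amphigen.simulate import SimulationConfig, simulate_bundle


def make_dataset(
    genotypes: dict[str, list[list[tuple[int, int] | None]]],
    loci: list[str] | None = None,
    site_to_river: dict[str, str] | None = None,
    river_to_catchment: dict[str, str] | None = None,
) -> MicrosatDataset:
    """Build a dataset from {site_id: [per-individual locus calls]}."""
    individuals: list[Individual] = []
    calls: list[list[tuple[int, int] | None]] = []
    n_loci = None
    for site, rows in genotypes.items():
        for k, row in enumerate(rows, start=1):
            individuals.append(Individual(f"{site}_{k:03d}", site))
            calls.append([None if c is None else sorted_call(*c) for c in row])
            n_loci = len(row)
    loci = loci or [f"loc{j + 1:02d}" for j in range(n_loci or 0)]
    return MicrosatDataset(
        individuals=individuals,
        loci=loci,
        calls=calls,
        site_to_river=site_to_river or {},
        river_to_catchment=river_to_catchment or {},
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down study design: 4 rivers / 2 catchments, short history."""
    return SimulationConfig(
        n_catchments=2,
        rivers_per_catchment=2,
        sites_per_river=(3, 3, 3, 3),
        min_individuals=12,
        max_individuals=18,
        n_loci=8,
        generations=25,
        ne_base=100,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture(scope="session")
def paper_like_bundle():
    """Full-size default design (34 sites, 16 loci); shared across tests."""
    return simulate_bundle(SimulationConfig(seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
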