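"""Independent forward Wright-Fisher simulator used as an oracle.

Deliberately written from scratch (plain diploid WF with unlinked loci,
selfing allowed) rather than reusing the package's stepping-stone
generator, so estimator-recovery tests check the estimators against an
implementation they share no code with.
"""

from __future__ import annotations

import numpy as np

from amphigen.datatypes import Individual, MicrosatDataset, sorted_call


def wf_population(
    ne: int, n_loci: int, n_alleles: int, gens: int, rng: np.random.Generator
) -> np.ndarray:
    """(ne, n_loci, 2) allele array after ``gens`` generations of drift."""
    pop = np.empty((ne, n_loci, 2), dtype=np.int32)
    for l in range(n_loci):
        freqs = rng.dirichlet(np.full(n_alleles, 2.0))
        pop[:, l, 0] = rng.choice(np.arange(1, n_alleles + 1), size=ne, p=freqs)
        pop[:, l, 1] = rng.choice(np.arange(1, n_alleles + 1), size=ne, p=freqs)
    for _ in range(gens):
        new = np.empty_like(pop)
        for slot in range(2):
            parents = rng.integers(0, ne, size=ne)
            sides = rng.integers(0, 2, size=(ne, n_loci))
            new[:, :, slot] = np.take_along_axis(
                pop[parents], sides[:, :, None], axis=2
            )[:, :, 0]
        pop = new
    return pop


def dataset_from_array(sample: np.ndarray, site_id: str = "X") -> MicrosatDataset:
    s, n_loci, _ = sample.shape
    individuals = [Individual(f"{site_id}_{i:03d}", site_id) for i in range(s)]
    calls = [
        [
            sorted_call(int(sample[k, l, 0]), int(sample[k, l, 1]))
            for l in range(n_loci)
        ]
        for k in range(s)
    ]
    return MicrosatDataset(
        individuals, [f"l{l:02d}" for l in range(n_loci)], calls
    )


def sample_population(
    pop: np.ndarray, s: int, rng: np.random.Generator, site_id: str = "X"
) -> MicrosatDataset:
    idx = rng.choice(pop.shape[0], size=s, replace=False)
    return dataset_from_array(pop[idx], site_id)
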