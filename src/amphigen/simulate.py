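"""Synthetic study-bundle generator.

Produces genotype, chemistry, toxicity-reference, metadata and distance
tables with the spatial and genetic structure the analysis pipeline
assumes: several rivers nested in catchments, pollution that increases
downstream of treatment-plant outfalls, and a forward Wright-Fisher
stepping-stone genotype simulation whose per-site drift intensity is tied
to the pollution score (plus optional within-site substructure to inflate
the inbreeding coefficient at polluted sites).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .datatypes import (
    CompoundProperties,
    ConcentrationTable,
    DistanceMatrix,
    Individual,
    LC50Record,
    MicrosatDataset,
    SiteMetadata,
    sorted_call,
)
from . import tables
from .genepop import write_genepop


@dataclass
class SimulationConfig:
    n_catchments: int = 3
    rivers_per_catchment: int = 2
    sites_per_river: tuple[int, ...] = (6, 6, 5, 6, 6, 5)  # 34 sites
    min_individuals: int = 10
    max_individuals: int = 30
    n_loci: int = 16
    min_founding_alleles: int = 4
    max_founding_alleles: int = 12
    catchment_divergence_gens: int = 120
    river_divergence_gens: int = 40
    migration: float = 0.05  # per-generation rate between adjacent sites
    ne_base: int = 180
    gamma: float = 1.2  # site Ne = ne_base * exp(-gamma * pollution)
    wahlund_w: float = 0.30  # mixing fraction at substructured sites
    wahlund_pollution_min: float = 0.5  # pollution above which substructure kicks in
    generations: int = 60
    mutation_rate: float = 5e-4  # stepwise model
    site_spacing_km: float = 4.0
    confluence_km: float = 20.0  # extra waterway distance between rivers
    catchment_gap_km: float = 120.0  # extra distance across catchments
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.migration <= 1:
            raise ValueError("migration must be in [0, 1]")
        if not 0 <= self.wahlund_w <= 1:
            raise ValueError("wahlund_w must be in [0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.ne_base < 2:
            raise ValueError("ne_base must be >= 2")
        n_rivers = self.n_catchments * self.rivers_per_catchment
        if len(self.sites_per_river) != n_rivers:
            raise ValueError(
                f"sites_per_river needs {n_rivers} entries, got {len(self.sites_per_river)}"
            )


@dataclass
class TruthTable:
    site_ids: list[str]
    pollution: dict[str, float]
    realized_ne: dict[str, int]
    wwtp_upstream: dict[str, bool]
    distance_from_source: dict[str, float]
    wahlund: dict[str, bool]
    params: dict[str, float] = field(default_factory=dict)


_RIVER_NAMES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

# Synthetic compound roster: (name, class, log_dow, pollution loading,
# base tissue level ng/g at pollution score 1).  The LC50 table below gives
# some compounds target-species records, some fallback-species only, and
# one none at all, to exercise every aggregation branch.
_COMPOUNDS = [
    ("neonic-1", "insecticide", 1.0, 1.0, 0.04),
    ("neonic-2", "insecticide", 0.7, 1.0, 0.015),
    ("analgesic-1", "pharmaceutical", 0.5, 0.8, 2.0),
    ("ssri-1", "pharmaceutical", 1.2, 0.9, 2.0),
    ("anticorrosive-1", "industrial", 2.0, 0.7, 400.0),
    ("plasticizer-1", "industrial", 2.8, 0.6, 250.0),
    ("triazine-1", "herbicide", 2.5, 0.9, 60.0),
    ("azole-1", "fungicide", 2.2, 0.8, 2.0),
    ("sweetener-1", "food ingredient", 0.0, 0.5, 2.0),
    ("quat-1", "biocide", 3.0, 0.6, 10.0),
]

_LC50_RECORDS = [
    # target species, 24 h and 48 h
    ("neonic-1", "Gammarus pulex", 24.0, 50.0),
    ("neonic-1", "Gammarus pulex", 48.0, 30.0),
    ("analgesic-1", "Gammarus pulex", 48.0, 20000.0),
    ("triazine-1", "Gammarus pulex", 24.0, 10000.0),
    ("quat-1", "Gammarus pulex", 24.0, 300.0),
    ("quat-1", "Gammarus pulex", 48.0, 200.0),
    # fallback species only
    ("neonic-2", "Daphnia magna", 48.0, 100.0),
    ("ssri-1", "Daphnia magna", 24.0, 4500.0),
    ("ssri-1", "Daphnia magna", 48.0, 3500.0),
    ("sweetener-1", "Daphnia magna", 48.0, 50000.0),
    ("azole-1", "Daphnia magna", 48.0, 800.0),
    ("plasticizer-1", "Daphnia magna", 24.0, 12000.0),
    # a 96 h record that must be ignored by the 24/48 h aggregation rule
    ("neonic-1", "Gammarus pulex", 96.0, 10.0),
    # anticorrosive-1 has no usable record at all -> skipped in TU scoring
]


def _layout(config: SimulationConfig):
    """River/site layout: ids, label maps, per-river site lists."""
    rivers = []
    river_to_catchment = {}
    k = 0
    for c in range(config.n_catchments):
        for _ in range(config.rivers_per_catchment):
            name = _RIVER_NAMES[k]
            rivers.append(name)
            river_to_catchment[name] = f"C{c + 1}"
            k += 1
    site_ids = []
    site_to_river = {}
    sites_of = {}
    for r, river in enumerate(rivers):
        ids = [f"{river}{i + 1}" for i in range(config.sites_per_river[r])]
        sites_of[river] = ids
        for s in ids:
            site_to_river[s] = river
        site_ids.extend(ids)
    return rivers, river_to_catchment, site_ids, site_to_river, sites_of


def simulate_pollution(
    config: SimulationConfig, seed: int | None = None
) -> tuple[dict[str, SiteMetadata], ConcentrationTable, ConcentrationTable,
           dict[str, CompoundProperties], list[LC50Record], TruthTable]:
    """Site metadata plus water/tissue chemistry tables with a downstream
    pollution gradient.

    The latent pollution score starts near 0 at the uppermost reference
    sites, jumps after each treatment-plant outfall, and creeps up with
    distance downstream; tissue and water concentrations are log-normal
    around class-specific means proportional to the score.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rivers, river_to_catchment, site_ids, site_to_river, sites_of = _layout(config)

    pollution: dict[str, float] = {}
    wwtp: dict[str, bool] = {}
    distance: dict[str, float] = {}
    meta: dict[str, SiteMetadata] = {}
    for river in rivers:
        ids = sites_of[river]
        n_sites = len(ids)
        # outfall sits between the reference stretch and the rest
        n_ref = int(rng.integers(1, 3))
        score = 0.0
        for i, sid in enumerate(ids):
            distance[sid] = round((i + 1) * config.site_spacing_km
                                  + rng.uniform(-1.0, 1.0), 2)
            has_wwtp = i >= n_ref
            wwtp[sid] = has_wwtp
            if has_wwtp:
                if i == n_ref:
                    score += rng.uniform(0.45, 0.75)  # the outfall jump
                else:
                    score += rng.uniform(0.02, 0.12)  # downstream creep
            else:
                score += rng.uniform(0.0, 0.03)
            pollution[sid] = round(score * rng.uniform(0.85, 1.15), 4)
        del n_sites
    for sid in site_ids:
        p = pollution[sid]
        meta[sid] = SiteMetadata(
            site_id=sid,
            river=site_to_river[sid],
            catchment=river_to_catchment[site_to_river[sid]],
            distance_from_source=distance[sid],
            wwtp_upstream=wwtp[sid],
            conductivity=round(300 + 600 * p + rng.normal(0, 40), 1),
            ph=round(7.6 + rng.normal(0, 0.25), 2),
            oxygen_saturation=round(
                float(np.clip(100 - 18 * p + rng.normal(0, 4), 30, 120)), 1
            ),
            abundance=round(
                float(np.exp(2.5 + 0.4 * math.log10(max(p, 1e-3) * 100)
                             + rng.normal(0, 0.5))), 1
            ),
        )

    compounds = {
        name: CompoundProperties(name=name, application_class=cls, log_dow=ld)
        for name, cls, ld, _, _ in _COMPOUNDS
    }
    names = [c[0] for c in _COMPOUNDS]
    tissue = np.zeros((len(site_ids), len(names)))
    water = np.zeros((len(site_ids), len(names)))
    sigma = 0.5
    for i, sid in enumerate(site_ids):
        p = pollution[sid]
        for j, (name, cls, ld, loading, base) in enumerate(_COMPOUNDS):
            mean_t = base * (0.01 + p * loading)
            tissue[i, j] = rng.lognormal(math.log(mean_t) - sigma**2 / 2, sigma)
            mean_w = base * 0.01 * (0.01 + p * loading)
            water[i, j] = rng.lognormal(math.log(mean_w) - sigma**2 / 2, sigma)
            # sporadic non-detects at barely polluted sites
            if p < 0.1 and rng.random() < 0.3:
                tissue[i, j] = 0.0
            if p < 0.1 and rng.random() < 0.3:
                water[i, j] = 0.0
    tissue_table = ConcentrationTable("tissue", "ng/g wet", list(site_ids), names, tissue)
    water_table = ConcentrationTable("water", "ug/L", list(site_ids), names, water)
    lc50 = [LC50Record(*rec) for rec in _LC50_RECORDS]
    truth = TruthTable(
        site_ids=list(site_ids),
        pollution=pollution,
        realized_ne={},
        wwtp_upstream=wwtp,
        distance_from_source=distance,
        wahlund={},
        params={"gamma": config.gamma, "ne_base": config.ne_base,
                "wahlund_w": config.wahlund_w},
    )
    return meta, water_table, tissue_table, compounds, lc50, truth


def _dirichlet_drift(freqs: np.ndarray, gens: int, ne: int, rng) -> np.ndarray:
    """Approximate ``gens`` generations of drift by a Dirichlet perturbation
    with matched variance (Var = p(1-p) * (1 - (1 - 1/2Ne)^gens))."""
    if gens <= 0:
        return freqs.copy()
    var_factor = 1.0 - (1.0 - 1.0 / (2 * ne)) ** gens
    conc = max(1.0 / var_factor - 1.0, 0.05)
    alpha = np.maximum(freqs * conc, 1e-6)
    return rng.dirichlet(alpha)


class _Deme:
    __slots__ = ("alleles", "n")

    def __init__(self, alleles: np.ndarray):
        self.alleles = alleles  # (n, n_loci, 2) int
        self.n = alleles.shape[0]


def _found_deme(freqs_per_locus: list[np.ndarray], codes: list[np.ndarray],
                n: int, rng) -> _Deme:
    n_loci = len(freqs_per_locus)
    alleles = np.zeros((n, n_loci, 2), dtype=np.int32)
    for l in range(n_loci):
        alleles[:, l, :] = rng.choice(
            codes[l], size=(n, 2), p=freqs_per_locus[l]
        )
    return _Deme(alleles)


def _next_generation(sources: list[_Deme], probs: np.ndarray, n_out: int,
                     mu: float, rng) -> np.ndarray:
    """One Wright-Fisher generation: each offspring draws two parents from
    the migrant-weighted source demes and one gamete from each."""
    n_loci = sources[0].alleles.shape[1]
    out = np.empty((n_out, n_loci, 2), dtype=np.int32)
    for slot in range(2):
        src_choice = rng.choice(len(sources), size=n_out, p=probs)
        gamete_side = rng.integers(0, 2, size=(n_out, n_loci))
        for s, deme in enumerate(sources):
            mask = src_choice == s
            k = int(mask.sum())
            if k == 0:
                continue
            parents = rng.integers(0, deme.n, size=k)
            chosen = deme.alleles[parents]  # (k, L, 2)
            side = gamete_side[mask]
            out[mask, :, slot] = np.take_along_axis(
                chosen, side[:, :, None], axis=2
            )[:, :, 0]
    if mu > 0:
        hits = rng.random(out.shape) < mu
        if hits.any():
            steps = rng.choice([-1, 1], size=int(hits.sum()))
            vals = out[hits] + steps
            out[hits] = np.maximum(vals, 1)
    return out


def simulate_genotypes(
    config: SimulationConfig,
    truth: TruthTable,
    seed: int | None = None,
) -> tuple[MicrosatDataset, TruthTable]:
    """Forward stepping-stone Wright-Fisher simulation of site genotypes.

    Founder frequencies drift apart between catchments and rivers
    (variance-matched Dirichlet); sites along a river then exchange migrants
    between adjacent demes while resampling at a pollution-dependent
    effective size Ne = ne_base * exp(-gamma * pollution).  Sites whose
    pollution exceeds ``wahlund_pollution_min`` are simulated as two
    half-size internal demes and sampled as a w/(1-w) mixture, which
    inflates the inbreeding coefficient without changing allele frequencies
    in expectation.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rivers, river_to_catchment, site_ids, site_to_river, sites_of = _layout(config)

    n_loci = config.n_loci
    codes: list[np.ndarray] = []
    regional: list[np.ndarray] = []
    for l in range(n_loci):
        k = int(rng.integers(config.min_founding_alleles, config.max_founding_alleles + 1))
        start = int(rng.integers(10, 30))
        codes.append(np.arange(start, start + k, dtype=np.int32))
        regional.append(rng.dirichlet(np.full(k, 1.2)))

    catchments = sorted(set(river_to_catchment.values()))
    catch_freqs = {
        c: [
            _dirichlet_drift(regional[l], config.catchment_divergence_gens,
                             config.ne_base, rng)
            for l in range(n_loci)
        ]
        for c in catchments
    }
    river_freqs = {
        r: [
            _dirichlet_drift(catch_freqs[river_to_catchment[r]][l],
                             config.river_divergence_gens, config.ne_base, rng)
            for l in range(n_loci)
        ]
        for r in rivers
    }

    realized_ne: dict[str, int] = {}
    wahlund_flag: dict[str, bool] = {}
    demes: dict[str, list[_Deme]] = {}
    for sid in site_ids:
        p = truth.pollution[sid]
        ne = int(round(config.ne_base * math.exp(-config.gamma * p)))
        if ne < 2:
            raise ValueError(
                f"site {sid!r}: pollution {p} drives Ne below 2; relax gamma or ne_base"
            )
        realized_ne[sid] = ne
        sub = config.wahlund_w > 0 and p > config.wahlund_pollution_min
        wahlund_flag[sid] = sub
        freqs = river_freqs[site_to_river[sid]]
        if sub:
            half = max(ne // 2, 2)
            demes[sid] = [
                _found_deme(freqs, codes, half, rng),
                _found_deme(freqs, codes, half, rng),
            ]
        else:
            demes[sid] = [_found_deme(freqs, codes, ne, rng)]

    m = config.migration
    for _ in range(config.generations):
        new: dict[str, list[np.ndarray]] = {}
        for river in rivers:
            ids = sites_of[river]
            for i, sid in enumerate(ids):
                neighbours: list[_Deme] = []
                for j in (i - 1, i + 1):
                    if 0 <= j < len(ids):
                        # migrants arrive from a random subdeme of the neighbour
                        nd = demes[ids[j]]
                        neighbours.append(nd[int(rng.integers(len(nd)))])
                arrays = []
                for deme in demes[sid]:
                    sources = [deme] + neighbours
                    probs = np.empty(len(sources))
                    probs[0] = 1.0 - m * len(neighbours) / 2.0
                    probs[1:] = m / 2.0
                    arrays.append(
                        _next_generation(sources, probs, deme.n,
                                         config.mutation_rate, rng)
                    )
                new[sid] = arrays
        for sid, arrays in new.items():
            demes[sid] = [_Deme(a) for a in arrays]

    individuals: list[Individual] = []
    calls: list[list[tuple[int, int] | None]] = []
    for sid in site_ids:
        n_sample = int(rng.integers(config.min_individuals, config.max_individuals + 1))
        site_demes = demes[sid]
        if len(site_demes) == 2:
            w = config.wahlund_w
            n_b = int(round(w * n_sample))
            n_b = min(n_b, site_demes[1].n)
            n_a = min(n_sample - n_b, site_demes[0].n)
            picks = [(site_demes[0], n_a), (site_demes[1], n_b)]
        else:
            picks = [(site_demes[0], min(n_sample, site_demes[0].n))]
        counter = 0
        for deme, k in picks:
            chosen = rng.choice(deme.n, size=k, replace=False)
            for idx in chosen:
                counter += 1
                individuals.append(Individual(id=f"{sid}_{counter:03d}", site_id=sid))
                calls.append(
                    [
                        sorted_call(int(deme.alleles[idx, l, 0]),
                                    int(deme.alleles[idx, l, 1]))
                        for l in range(n_loci)
                    ]
                )
    dataset = MicrosatDataset(
        individuals=individuals,
        loci=[f"loc{l + 1:02d}" for l in range(n_loci)],
        calls=calls,
        site_to_river=site_to_river,
        river_to_catchment=river_to_catchment,
    )
    truth.realized_ne = realized_ne
    truth.wahlund = wahlund_flag
    return dataset, truth


def waterway_distances(config: SimulationConfig,
                       truth: TruthTable) -> DistanceMatrix:
    """Along-river distances; inter-river routes go through the confluence."""
    rivers, river_to_catchment, site_ids, site_to_river, _ = _layout(config)
    n = len(site_ids)
    mat = np.zeros((n, n))
    for i, a in enumerate(site_ids):
        for j in range(i + 1, n):
            b = site_ids[j]
            ra, rb = site_to_river[a], site_to_river[b]
            da, db = truth.distance_from_source[a], truth.distance_from_source[b]
            if ra == rb:
                d = abs(da - db)
            elif river_to_catchment[ra] == river_to_catchment[rb]:
                d = da + db + config.confluence_km
            else:
                d = da + db + config.catchment_gap_km
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(list(site_ids), mat, "waterway")


def simulate_bundle(config: SimulationConfig, seed: int | None = None):
    """In-memory synthetic study: (dataset, metadata, water, tissue,
    compounds, lc50, distances, truth)."""
    base = config.seed if seed is None else seed
    meta, water, tissue, compounds, lc50, truth = simulate_pollution(config, seed=base)
    dataset, truth = simulate_genotypes(config, truth, seed=base + 1)
    distances = waterway_distances(config, truth)
    return dataset, meta, water, tissue, compounds, lc50, distances, truth


def generate_study(
    config: SimulationConfig, out_dir: str | Path, seed: int | None = None
) -> dict[str, str]:
    """Write a complete bundle to ``out_dir``; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, meta, water, tissue, compounds, lc50, distances, truth = simulate_bundle(
        config, seed=seed
    )
    write_genepop(dataset, out / "genotypes.gen")
    tables.write_site_metadata(meta, out / "sites.csv")
    tables.write_concentrations(water, out / "water.csv")
    tables.write_concentrations(tissue, out / "tissue.csv")
    tables.write_compound_properties(compounds, out / "compounds.csv")
    tables.write_lc50(lc50, out / "lc50.csv")
    tables.write_distance_matrix(distances, out / "distances.csv")
    import pandas as pd

    pd.DataFrame(
        {
            "site_id": truth.site_ids,
            "pollution": [truth.pollution[s] for s in truth.site_ids],
            "realized_ne": [truth.realized_ne[s] for s in truth.site_ids],
            "wwtp_upstream": [truth.wwtp_upstream[s] for s in truth.site_ids],
            "distance_from_source_km": [
                truth.distance_from_source[s] for s in truth.site_ids
            ],
            "wahlund": [truth.wahlund[s] for s in truth.site_ids],
        }
    ).to_csv(out / "truth.csv", index=False)
    manifest = {
        "files": {
            "genotypes": "genotypes.gen",
            "sites": "sites.csv",
            "water": "water.csv",
            "tissue": "tissue.csv",
            "compounds": "compounds.csv",
            "lc50": "lc50.csv",
            "distances": "distances.csv",
            "truth": "truth.csv",
        },
        "config": asdict(config),
        "seed": config.seed if seed is None else seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest["files"]
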