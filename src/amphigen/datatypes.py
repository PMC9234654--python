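"""Core data model shared by every pipeline stage.

Genotypes are diploid microsatellite calls: each individual carries, per
locus, an unordered pair of positive-integer allele codes or the MISSING
sentinel (whole-genotype missingness only; there are no half-called
genotypes).  Sites resolve to rivers and rivers to catchments through the
label maps carried on the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel for a missing diploid call (both allele slots).
MISSING: tuple[int, int] | None = None

#: Controlled vocabulary for compound application classes.
APPLICATION_CLASSES = frozenset(
    {
        "pesticide",
        "insecticide",
        "herbicide",
        "fungicide",
        "pharmaceutical",
        "industrial",
        "food ingredient",
        "biocide",
        "surfactant",
        "transformation product",
        "other",
    }
)


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass(frozen=True)
class Individual:
    id: str
    site_id: str


@dataclass
class MicrosatDataset:
    """Individuals x loci diploid allele calls with site/river/catchment labels."""

    individuals: list[Individual]
    loci: list[str]
    # calls[i][j] is an unordered (sorted) pair of allele codes, or None.
    calls: list[list[tuple[int, int] | None]]
    site_to_river: dict[str, str] = field(default_factory=dict)
    river_to_catchment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("duplicate locus names")
        if len(self.calls) != len(self.individuals):
            raise ValidationError("calls rows != individuals")
        for ind, row in zip(self.individuals, self.calls):
            if len(row) != len(self.loci):
                raise ValidationError(
                    f"individual {ind.id!r}: {len(row)} calls for {len(self.loci)} loci"
                )
            for call in row:
                if call is None:
                    continue
                a, b = call
                if a <= 0 or b <= 0:
                    raise ValidationError(
                        f"individual {ind.id!r}: non-positive allele code {call}"
                    )
        if self.site_to_river:
            for ind in self.individuals:
                if ind.site_id not in self.site_to_river:
                    raise ValidationError(f"site {ind.site_id!r} missing from site_to_river")
            for site, river in self.site_to_river.items():
                if self.river_to_catchment and river not in self.river_to_catchment:
                    raise ValidationError(f"river {river!r} missing from river_to_catchment")

    @property
    def site_ids(self) -> list[str]:
        """Site ids in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.site_id, None)
        return list(seen)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def site_indices(self, site_id: str) -> list[int]:
        return [i for i, ind in enumerate(self.individuals) if ind.site_id == site_id]

    def subset(self, *, individuals: Sequence[int] | None = None,
               loci: Sequence[int] | None = None) -> "MicrosatDataset":
        ii = list(range(self.n_individuals)) if individuals is None else list(individuals)
        jj = list(range(self.n_loci)) if loci is None else list(loci)
        sites = {self.individuals[i].site_id for i in ii}
        s2r = {s: r for s, r in self.site_to_river.items() if s in sites}
        rivers = set(s2r.values())
        r2c = {r: c for r, c in self.river_to_catchment.items() if r in rivers}
        return MicrosatDataset(
            individuals=[self.individuals[i] for i in ii],
            loci=[self.loci[j] for j in jj],
            calls=[[self.calls[i][j] for j in jj] for i in ii],
            site_to_river=s2r,
            river_to_catchment=r2c,
        )

    def group_of(self, grouping: str) -> list[str]:
        """Per-individual group label under ``site``/``river``/``catchment`` grouping."""
        if grouping == "site":
            return [ind.site_id for ind in self.individuals]
        if grouping == "river":
            return [self.site_to_river[ind.site_id] for ind in self.individuals]
        if grouping == "catchment":
            return [
                self.river_to_catchment[self.site_to_river[ind.site_id]]
                for ind in self.individuals
            ]
        raise ValueError(f"unknown grouping {grouping!r}")

    def allele_array(self) -> np.ndarray:
        """(n_individuals, n_loci, 2) int array with 0 encoding MISSING."""
        arr = np.zeros((self.n_individuals, self.n_loci, 2), dtype=np.int32)
        for i, row in enumerate(self.calls):
            for j, call in enumerate(row):
                if call is not None:
                    arr[i, j, 0], arr[i, j, 1] = call
        return arr

    def content_equal(self, other: "MicrosatDataset") -> bool:
        return (
            self.loci == other.loci
            and [ind.id for ind in self.individuals] == [i.id for i in other.individuals]
            and [ind.site_id for ind in self.individuals]
            == [i.site_id for i in other.individuals]
            and self.calls == other.calls
        )


@dataclass(frozen=True)
class SiteMetadata:
    site_id: str
    river: str
    catchment: str
    distance_from_source: float  # km
    wwtp_upstream: bool
    conductivity: float  # uS/cm
    ph: float
    oxygen_saturation: float  # percent
    abundance: float  # individuals per catch

    def __post_init__(self) -> None:
        if self.distance_from_source < 0:
            raise ValidationError(
                f"site {self.site_id!r}: negative distance from source"
            )


@dataclass
class ConcentrationTable:
    """Site x compound concentration matrix; not-detected is stored as 0."""

    matrix_kind: str  # "water" | "tissue"
    units: str  # "ug/L" (water) or "ng/g wet" (tissue)
    sites: list[str]
    compounds: list[str]
    values: np.ndarray  # shape (n_sites, n_compounds)

    def __post_init__(self) -> None:
        if self.matrix_kind not in ("water", "tissue"):
            raise ValidationError(f"bad matrix kind {self.matrix_kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sites), len(self.compounds)):
            raise ValidationError("concentration matrix shape mismatch")
        if np.any(self.values < 0):
            bad = [self.sites[i] for i in np.where((self.values < 0).any(axis=1))[0]]
            raise ValidationError(f"negative concentrations at sites {bad}")

    def row(self, site_id: str) -> dict[str, float]:
        i = self.sites.index(site_id)
        return dict(zip(self.compounds, self.values[i]))


@dataclass(frozen=True)
class CompoundProperties:
    name: str
    application_class: str
    log_dow: float

    def __post_init__(self) -> None:
        if self.application_class not in APPLICATION_CLASSES:
            raise ValidationError(
                f"compound {self.name!r}: unknown application class "
                f"{self.application_class!r}"
            )


@dataclass(frozen=True)
class LC50Record:
    compound: str
    species: str
    duration_h: float
    lc50: float  # ug/L

    def __post_init__(self) -> None:
        if self.lc50 <= 0:
            raise ValidationError(f"non-positive LC50 for {self.compound!r}")


@dataclass
class DistanceMatrix:
    sites: list[str]
    values: np.ndarray
    kind: str = "waterway"  # waterway | aom_difference | tu_difference

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sites)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if np.any(self.values < 0):
            raise ValidationError("negative distances")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValidationError("distance matrix diagonal not zero")

    def subset(self, site_ids: Iterable[str]) -> "DistanceMatrix":
        wanted = list(site_ids)
        idx = [self.sites.index(s) for s in wanted]
        return DistanceMatrix(wanted, self.values[np.ix_(idx, idx)], self.kind)


@dataclass
class StudyBundle:
    """Cross-referenced study inputs, as loaded by :func:`read_study_tables`."""

    metadata: dict[str, SiteMetadata]
    water: ConcentrationTable | None
    tissue: ConcentrationTable | None
    compounds: dict[str, CompoundProperties]
    lc50: list[LC50Record]
    distances: DistanceMatrix | None
    # Sites present in the study but absent from the tissue table; these are
    # excluded from tissue-based models downstream.
    tissue_excluded_sites: list[str] = field(default_factory=list)


def sorted_call(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)
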