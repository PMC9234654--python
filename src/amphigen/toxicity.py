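"""Toxic-unit scoring from tissue chemistry.

The freely dissolved concentration of a compound is back-calculated from
its tissue burden by equilibrium partitioning: the tissue concentration is
lipid-normalized and divided by the octanol/water distribution ratio
(10**log_dow) standing in for the lipid/water partition coefficient,

    c_fd = c_tissue / (f_lipid * 10**log_dow)

with c_tissue in ng/g wet weight.  Under unit tissue and water density
(1 g/mL), ng/g wet is numerically identical to ug/L, so c_fd is reported
in ug/L without a conversion factor.  Each compound's toxic unit is
c_fd / LC50 (LC50 in ug/L) and site toxic units add across compounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .datatypes import CompoundProperties, ConcentrationTable, LC50Record

#: Sum-TU above which acute adverse effects are expected in crustaceans.
ACUTE_TU_THRESHOLD = 0.01
#: Sum-TU above which chronic adverse effects are expected.
CHRONIC_TU_THRESHOLD = 0.001
#: Lipid fraction of amphipod wet body weight.
DEFAULT_F_LIPID = 0.0134


@dataclass(frozen=True)
class ToxicityConfig:
    f_lipid: float = DEFAULT_F_LIPID
    acute_threshold: float = ACUTE_TU_THRESHOLD
    chronic_threshold: float = CHRONIC_TU_THRESHOLD
    target_species: str = "Gammarus pulex"
    fallback_species: str = "Daphnia magna"

    def __post_init__(self) -> None:
        if not 0 < self.f_lipid < 1:
            raise ValueError("f_lipid must be in (0, 1)")
        if not self.chronic_threshold < self.acute_threshold:
            raise ValueError("chronic threshold must be below acute threshold")


@dataclass
class TUResult:
    site_id: str
    cfd: dict[str, float] = field(default_factory=dict)  # ug/L
    tu: dict[str, float] = field(default_factory=dict)
    sum_tu: float = 0.0
    log10_sum_tu: float | None = None
    class_share: dict[str, float] = field(default_factory=dict)
    compounds_skipped: list[str] = field(default_factory=list)


def select_lc50(
    compound: str,
    lc50_table: list[LC50Record],
    target_species: str = "Gammarus pulex",
    fallback_species: str = "Daphnia magna",
    durations: tuple[float, ...] = (24.0, 48.0),
) -> float | None:
    """Aggregate LC50 records for one compound.

    Returns the arithmetic mean of the target species' 24 h and 48 h
    records; if the target species has none, the fallback species' mean;
    if neither has records, None (the compound is excluded from scoring).
    """
    for species in (target_species, fallback_species):
        vals = [
            r.lc50
            for r in lc50_table
            if r.compound == compound
            and r.species == species
            and r.duration_h in durations
        ]
        if vals:
            return sum(vals) / len(vals)
    return None


def freely_dissolved(c_tissue: float, f_lipid: float, log_dow: float) -> float:
    """Freely dissolved concentration (ug/L) from tissue burden (ng/g wet)."""
    if f_lipid <= 0:
        raise ValueError("f_lipid must be positive")
    if c_tissue < 0:
        raise ValueError("negative tissue concentration")
    if not math.isfinite(log_dow):
        raise ValueError("log_dow must be finite")
    return c_tissue / (f_lipid * 10.0 ** log_dow)


def toxic_units(
    tissue_table: ConcentrationTable,
    compound_properties: dict[str, CompoundProperties],
    lc50_table: list[LC50Record],
    config: ToxicityConfig = ToxicityConfig(),
) -> dict[str, TUResult]:
    """Per-site toxic-unit scoring from the tissue concentration table.

    Compounds without an aggregable LC50 (either species) are listed in
    ``compounds_skipped`` and contribute nothing.  Sites absent from the
    tissue table are simply not in the result (mirrors the field-data
    exclusions); compounds with zero concentration contribute tu = 0.
    """
    if tissue_table.matrix_kind != "tissue":
        raise ValueError("toxic units are computed from the tissue matrix")
    lc50_of: dict[str, float | None] = {
        c: select_lc50(c, lc50_table, config.target_species, config.fallback_species)
        for c in tissue_table.compounds
    }
    results: dict[str, TUResult] = {}
    for i, site in enumerate(tissue_table.sites):
        res = TUResult(site_id=site)
        class_tu: dict[str, float] = {}
        for j, comp in enumerate(tissue_table.compounds):
            props = compound_properties[comp]
            lc50 = lc50_of[comp]
            if lc50 is None:
                if comp not in res.compounds_skipped:
                    res.compounds_skipped.append(comp)
                continue
            cfd = freely_dissolved(tissue_table.values[i, j], config.f_lipid, props.log_dow)
            tu = cfd / lc50
            res.cfd[comp] = cfd
            res.tu[comp] = tu
            class_tu[props.application_class] = class_tu.get(props.application_class, 0.0) + tu
        res.sum_tu = sum(res.tu.values())
        res.log10_sum_tu = math.log10(res.sum_tu) if res.sum_tu > 0 else None
        if res.sum_tu > 0:
            res.class_share = {k: v / res.sum_tu for k, v in class_tu.items()}
        results[site] = res
    return results


def classify_tu(value: float, config: ToxicityConfig = ToxicityConfig()) -> str:
    """Classify a toxic-unit value; thresholds are strict (boundary -> lower class)."""
    if value > config.acute_threshold:
        return "acute"
    if value > config.chronic_threshold:
        return "chronic"
    return "below"


def classify_toxicity(
    result: TUResult, config: ToxicityConfig = ToxicityConfig()
) -> tuple[str, dict[str, str]]:
    """Site-level classification on sum_tu plus a per-compound breakdown."""
    per_compound = {c: classify_tu(v, config) for c, v in result.tu.items()}
    return classify_tu(result.sum_tu, config), per_compound


def total_aom(conc_table: ConcentrationTable) -> dict[str, tuple[float, float | None]]:
    """Per-site total concentration and its log10 (None when the total is 0)."""
    out: dict[str, tuple[float, float | None]] = {}
    for i, site in enumerate(conc_table.sites):
        total = float(conc_table.values[i].sum())
        out[site] = (total, math.log10(total) if total > 0 else None)
    return out
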