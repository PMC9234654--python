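"""Readers/writers for the delimited-text study tables.

All tables are comma-separated UTF-8 text with a header row.  Schemas:

``sites.csv``
    site_id,river,catchment,distance_from_source_km,wwtp_upstream,
    conductivity_uScm,ph,oxygen_saturation_pct,abundance
``water.csv`` / ``tissue.csv``
    site_id,<compound>,<compound>,...   (one row per site)
``compounds.csv``
    compound,application_class,log_dow
``lc50.csv``
    compound,species,duration_h,lc50_ugL
``distances.csv``
    site_id,<site>,<site>,...           (square matrix, header = site ids)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CompoundProperties,
    ConcentrationTable,
    DistanceMatrix,
    LC50Record,
    SiteMetadata,
    StudyBundle,
    ValidationError,
)

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _to_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return _BOOL[str(x).strip().lower()]


def read_site_metadata(path: str | Path) -> dict[str, SiteMetadata]:
    df = pd.read_csv(path)
    meta: dict[str, SiteMetadata] = {}
    for _, r in df.iterrows():
        sid = str(r["site_id"])
        if sid in meta:
            raise ValidationError(f"duplicate site id {sid!r} in metadata")
        meta[sid] = SiteMetadata(
            site_id=sid,
            river=str(r["river"]),
            catchment=str(r["catchment"]),
            distance_from_source=float(r["distance_from_source_km"]),
            wwtp_upstream=_to_bool(r["wwtp_upstream"]),
            conductivity=float(r["conductivity_uScm"]),
            ph=float(r["ph"]),
            oxygen_saturation=float(r["oxygen_saturation_pct"]),
            abundance=float(r["abundance"]),
        )
    return meta


def read_concentrations(path: str | Path, matrix_kind: str) -> ConcentrationTable:
    df = pd.read_csv(path)
    sites = [str(s) for s in df["site_id"]]
    compounds = [c for c in df.columns if c != "site_id"]
    values = df[compounds].to_numpy(dtype=float)
    units = "ug/L" if matrix_kind == "water" else "ng/g wet"
    return ConcentrationTable(matrix_kind, units, sites, compounds, values)


def read_compound_properties(path: str | Path) -> dict[str, CompoundProperties]:
    df = pd.read_csv(path)
    out: dict[str, CompoundProperties] = {}
    for _, r in df.iterrows():
        name = str(r["compound"])
        out[name] = CompoundProperties(
            name=name,
            application_class=str(r["application_class"]),
            log_dow=float(r["log_dow"]),
        )
    return out


def read_lc50(path: str | Path) -> list[LC50Record]:
    df = pd.read_csv(path)
    return [
        LC50Record(
            compound=str(r["compound"]),
            species=str(r["species"]),
            duration_h=float(r["duration_h"]),
            lc50=float(r["lc50_ugL"]),
        )
        for _, r in df.iterrows()
    ]


def read_distance_matrix(path: str | Path, kind: str = "waterway") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    sites = [str(s) for s in df.columns]
    if [str(s) for s in df.index] != sites:
        raise ValidationError("distance matrix rows and columns disagree")
    return DistanceMatrix(sites, df.to_numpy(dtype=float), kind)


@dataclass
class StudyPaths:
    sites: str | Path
    water: str | Path | None = None
    tissue: str | Path | None = None
    compounds: str | Path | None = None
    lc50: str | Path | None = None
    distances: str | Path | None = None


def read_study_tables(paths: StudyPaths) -> StudyBundle:
    """Load and cross-validate a study bundle.

    Sites present in the metadata but absent from the tissue table are
    retained and flagged in ``tissue_excluded_sites`` (they are dropped from
    tissue-based models downstream rather than rejected here).  A site
    appearing in any other table but not in the metadata is an error.
    """
    meta = read_site_metadata(paths.sites)
    known = set(meta)

    def check_sites(sites, label):
        unknown = [s for s in sites if s not in known]
        if unknown:
            raise ValidationError(f"unknown site ids in {label}: {unknown}")

    water = tissue = distances = None
    if paths.water:
        water = read_concentrations(paths.water, "water")
        check_sites(water.sites, "water concentrations")
    if paths.tissue:
        tissue = read_concentrations(paths.tissue, "tissue")
        check_sites(tissue.sites, "tissue concentrations")
    compounds = read_compound_properties(paths.compounds) if paths.compounds else {}
    lc50 = read_lc50(paths.lc50) if paths.lc50 else []
    if paths.distances:
        distances = read_distance_matrix(paths.distances)
        check_sites(distances.sites, "distance matrix")

    excluded = []
    if tissue is not None:
        excluded = sorted(known - set(tissue.sites))
    return StudyBundle(
        metadata=meta,
        water=water,
        tissue=tissue,
        compounds=compounds,
        lc50=lc50,
        distances=distances,
        tissue_excluded_sites=excluded,
    )


def write_site_metadata(meta: dict[str, SiteMetadata], path: str | Path) -> None:
    rows = [
        {
            "site_id": m.site_id,
            "river": m.river,
            "catchment": m.catchment,
            "distance_from_source_km": m.distance_from_source,
            "wwtp_upstream": m.wwtp_upstream,
            "conductivity_uScm": m.conductivity,
            "ph": m.ph,
            "oxygen_saturation_pct": m.oxygen_saturation,
            "abundance": m.abundance,
        }
        for m in meta.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_concentrations(table: ConcentrationTable, path: str | Path) -> None:
    df = pd.DataFrame(table.values, columns=table.compounds)
    df.insert(0, "site_id", table.sites)
    df.to_csv(path, index=False)


def write_compound_properties(
    compounds: dict[str, CompoundProperties], path: str | Path
) -> None:
    rows = [
        {"compound": c.name, "application_class": c.application_class, "log_dow": c.log_dow}
        for c in compounds.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_lc50(records: list[LC50Record], path: str | Path) -> None:
    rows = [
        {
            "compound": r.compound,
            "species": r.species,
            "duration_h": r.duration_h,
            "lc50_ugL": r.lc50,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.values, index=dm.sites, columns=dm.sites)
    df.to_csv(path, index_label="site_id")
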