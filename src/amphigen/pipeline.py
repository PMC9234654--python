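"""End-to-end orchestration: toxicity -> diversity -> structure -> association.

The pipeline is configured from a YAML mapping (see ``PipelineConfig``),
reads the study bundle through :mod:`amphigen.tables` /
:mod:`amphigen.genepop`, and writes plain delimited outputs plus a JSON
run-metadata sidecar into the output directory.  Every stochastic step is
driven by the single configured seed, so reruns are bit-identical.
"""

from __future__ import annotations

import json
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import dredge, fit_path_model
from .datatypes import MicrosatDataset, StudyBundle
from .diversity import het_stats, qc_filter, rarefaction_table, site_diversity
from .genepop import read_genepop
from .structure import (
    aom_distance_matrix,
    fst_distance_matrix,
    fst_matrix,
    fst_permutation_test,
    mantel,
    partial_mantel,
)
from .tables import StudyPaths, read_study_tables
from .toxicity import ToxicityConfig, classify_toxicity, total_aom, toxic_units

log = logging.getLogger("amphigen")


@dataclass
class PipelineConfig:
    genotypes: str
    sites: str
    tissue: str | None = None
    water: str | None = None
    compounds: str | None = None
    lc50: str | None = None
    distances: str | None = None
    out_dir: str = "results"
    seed: int = 0
    allele_digits: int = 3
    permutations: int = 999
    rarefaction_size: int | None = None
    max_missing: float = 0.20
    exclude_loci: list[str] = field(default_factory=list)
    estimate_ne: bool = True
    pcrit: float = 0.05
    f_lipid: float = 0.0134
    fst_pair_tests: int = 0  # how many site pairs get permutation p-values
    model_group: str = "river"
    run_models: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _fmt(x) -> object:
    if x is None:
        return ""
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return x


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, pd.DataFrame] = {}
    resolved = dict(vars(config))

    def write(name: str, df: pd.DataFrame) -> None:
        outputs[name] = df
        df.to_csv(out_dir / f"{name}.csv", index=False)

    # -- load ---------------------------------------------------------------
    try:
        bundle: StudyBundle = read_study_tables(
            StudyPaths(
                sites=config.sites,
                water=config.water,
                tissue=config.tissue,
                compounds=config.compounds,
                lc50=config.lc50,
                distances=config.distances,
            )
        )
        dataset = read_genepop(config.genotypes, allele_digits=config.allele_digits)
        dataset.site_to_river = {
            s: bundle.metadata[s].river for s in dataset.site_ids
        }
        dataset.river_to_catchment = {
            m.river: m.catchment for m in bundle.metadata.values()
        }
        dataset.validate()
    except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
        raise StageError("load", exc) from exc
    if bundle.tissue_excluded_sites:
        log.warning(
            "sites without tissue chemistry (excluded from tissue-based models): %s",
            bundle.tissue_excluded_sites,
        )

    # -- toxicity -----------------------------------------------------------
    tu_results = {}
    totals = {}
    try:
        if bundle.tissue is not None and bundle.compounds and bundle.lc50:
            tox_cfg = ToxicityConfig(f_lipid=config.f_lipid)
            tu_results = toxic_units(bundle.tissue, bundle.compounds, bundle.lc50, tox_cfg)
            totals = total_aom(bundle.tissue)
            rows = []
            comp_rows = []
            for site, res in tu_results.items():
                site_class, per_comp = classify_toxicity(res, tox_cfg)
                rows.append(
                    {
                        "site_id": site,
                        "sum_tu": res.sum_tu,
                        "log10_sum_tu": _fmt(res.log10_sum_tu),
                        "classification": site_class,
                        "total_aom": totals[site][0],
                        "log10_total_aom": _fmt(totals[site][1]),
                        "n_compounds_skipped": len(res.compounds_skipped),
                        **{
                            f"share_{cls}": share
                            for cls, share in sorted(res.class_share.items())
                        },
                    }
                )
                for comp, tu in res.tu.items():
                    comp_rows.append(
                        {
                            "site_id": site,
                            "compound": comp,
                            "cfd_ugL": res.cfd[comp],
                            "tu": tu,
                            "classification": per_comp[comp],
                        }
                    )
            write("tu_site_summary", pd.DataFrame(rows).fillna(0.0))
            write("tu_per_compound", pd.DataFrame(comp_rows))
    except Exception as exc:  # noqa: BLE001
        raise StageError("toxicity", exc) from exc

    # -- diversity ----------------------------------------------------------
    try:
        filtered, qc = qc_filter(dataset, max_missing=config.max_missing)
        resolved["qc_removed_individuals"] = qc.removed_individuals
        resolved["qc_removed_loci"] = qc.removed_loci
        diversity = site_diversity(
            filtered,
            g=config.rarefaction_size,
            estimate_ne=config.estimate_ne,
            pcrit=config.pcrit,
        )
        div_rows = []
        for site, sd in diversity.items():
            ci = sd.ne_ci or (None, None)
            div_rows.append(
                {
                    "site_id": site,
                    "n": sd.n_individuals,
                    "h_obs": _fmt(sd.h_obs),
                    "h_exp": _fmt(sd.h_exp),
                    "f_is": _fmt(sd.f_is),
                    "mean_ar": _fmt(sd.mean_ar),
                    "mean_pa": _fmt(sd.mean_pa),
                    "ne_hat": _fmt(sd.ne_hat),
                    "ne_lo": _fmt(ci[0]),
                    "ne_hi": _fmt(ci[1]),
                }
            )
        write("diversity_sites", pd.DataFrame(div_rows))
        # per-locus appendix with HWE and null-allele screening
        from .diversity import hwe_test, null_allele_freq

        site_het = het_stats(filtered, "site")
        rng_hwe = np.random.default_rng(config.seed + 7)
        locus_rows = []
        for site in filtered.site_ids:
            idx = filtered.site_indices(site)
            for j, locus in enumerate(filtered.loci):
                lh = site_het[site].per_locus[locus]
                if lh is None:
                    continue
                hwe_p = None
                if config.permutations >= 1:
                    genos = [
                        filtered.calls[i][j]
                        for i in idx
                        if filtered.calls[i][j] is not None
                    ]
                    hwe_p = hwe_test(
                        genos, config.permutations, seed=int(rng_hwe.integers(2**32))
                    )
                nulls = null_allele_freq(lh.h_obs, lh.h_exp)
                chak, brook = nulls if nulls is not None else (None, None)
                locus_rows.append(
                    {
                        "site_id": site,
                        "locus": locus,
                        "n": lh.n,
                        "h_obs": lh.h_obs,
                        "h_exp": lh.h_exp,
                        "f_is": _fmt(lh.f_is),
                        "hwe_p": _fmt(hwe_p),
                        "null_chakraborty": _fmt(chak),
                        "null_brookfield": _fmt(brook),
                        "null_flagged": bool(chak is not None and chak > 0.2),
                    }
                )
        write("diversity_per_locus", pd.DataFrame(locus_rows))
        river_het = het_stats(filtered, "river")
        river_rar = rarefaction_table(filtered, "river", g=config.rarefaction_size)
        write(
            "diversity_rivers",
            pd.DataFrame(
                [
                    {
                        "river": r,
                        "h_obs": _fmt(river_het[r].h_obs),
                        "h_exp": _fmt(river_het[r].h_exp),
                        "f_is": _fmt(river_het[r].f_is),
                        "mean_ar": _fmt(river_rar.mean_ar.get(r)),
                        "mean_pa": _fmt(river_rar.mean_pa.get(r)),
                    }
                    for r in river_het
                ]
            ),
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("diversity", exc) from exc

    # -- structure ----------------------------------------------------------
    try:
        struct_ds = filtered
        site_fst = fst_matrix(struct_ds, "site", exclude_loci=config.exclude_loci)
        rng = np.random.default_rng(config.seed)
        n_tests = config.fst_pair_tests
        fst_rows = []
        for k, pf in enumerate(site_fst):
            p_val = None
            if config.permutations >= 1 and (n_tests < 0 or k < n_tests):
                p_val = fst_permutation_test(
                    struct_ds,
                    pf.pair,
                    n_perm=config.permutations,
                    seed=int(rng.integers(2**32)),
                )
            fst_rows.append(
                {
                    "group_a": pf.pair[0],
                    "group_b": pf.pair[1],
                    "theta": _fmt(pf.theta),
                    "p_value": _fmt(p_val),
                    "n_permutations": config.permutations if p_val is not None else 0,
                }
            )
        write("fst_sites", pd.DataFrame(fst_rows))
        river_fst = fst_matrix(struct_ds, "river", exclude_loci=config.exclude_loci)
        write(
            "fst_rivers",
            pd.DataFrame(
                [
                    {"group_a": p.pair[0], "group_b": p.pair[1], "theta": _fmt(p.theta)}
                    for p in river_fst
                ]
            ),
        )
        mantel_rows = []
        if bundle.distances is not None:
            fst_dm = fst_distance_matrix(
                struct_ds, "site", exclude_loci=config.exclude_loci
            )
            common = [s for s in fst_dm.sites if s in bundle.distances.sites]
            fst_dm_c = fst_dm.subset(common)
            way = bundle.distances.subset(common)
            n_perm = config.permutations
            res = mantel(fst_dm_c, way, n_perm=n_perm, seed=config.seed)
            mantel_rows.append(
                {
                    "test": "fst~waterway",
                    "r": res.r,
                    "p_value": _fmt(res.p_value),
                    "n_permutations": res.n_permutations,
                }
            )
            if totals:
                tot_scalar = {
                    s: totals[s][0]
                    for s in common
                    if s in totals and totals[s][0] > 0
                }
                if len(tot_scalar) >= 4:
                    aom_dm = aom_distance_matrix(tot_scalar, transform="log10")
                    sub = [s for s in common if s in aom_dm.sites]
                    res2 = partial_mantel(
                        fst_dm_c.subset(sub),
                        aom_dm.subset(sub),
                        way.subset(sub),
                        n_perm=n_perm,
                        seed=config.seed + 1,
                    )
                    mantel_rows.append(
                        {
                            "test": "fst~aom|waterway",
                            "r": res2.r,
                            "p_value": _fmt(res2.p_value),
                            "n_permutations": res2.n_permutations,
                        }
                    )
                tu_scalar = {
                    s: tu_results[s].log10_sum_tu
                    for s in common
                    if s in tu_results and tu_results[s].log10_sum_tu is not None
                }
                if len(tu_scalar) >= 4:
                    tu_dm = aom_distance_matrix(
                        tu_scalar, transform="identity", kind="tu_difference"
                    )
                    sub = [s for s in common if s in tu_dm.sites]
                    res3 = partial_mantel(
                        fst_dm_c.subset(sub),
                        tu_dm.subset(sub),
                        way.subset(sub),
                        n_perm=n_perm,
                        seed=config.seed + 2,
                    )
                    mantel_rows.append(
                        {
                            "test": "fst~tu|waterway",
                            "r": res3.r,
                            "p_value": _fmt(res3.p_value),
                            "n_permutations": res3.n_permutations,
                        }
                    )
        write("mantel", pd.DataFrame(mantel_rows))
    except Exception as exc:  # noqa: BLE001
        raise StageError("structure", exc) from exc

    # -- association --------------------------------------------------------
    try:
        if config.run_models and tu_results:
            frame = _model_frame(bundle, diversity, tu_results, totals)
            rank_rows = []
            coef_rows = []
            predictors = [
                "wwtp",
                "log10_total_aom",
                "log10_sum_tu",
                "distance_from_source",
                "conductivity",
                "ph",
                "oxygen_saturation",
            ]
            for response in ("mean_ar", "f_is", "abundance", "log10_ne"):
                sub = frame.dropna(subset=[response] + predictors)
                if len(sub) < 12 or sub[config.model_group].nunique() < 2:
                    continue
                ranking = dredge(
                    response,
                    sub[response].to_numpy(),
                    {p: sub[p].to_numpy() for p in predictors},
                    sub[config.model_group].to_numpy(),
                )
                for mdl in ranking.retained():
                    rank_rows.append(
                        {
                            "response": response,
                            "terms": "+".join(mdl.terms) or "(intercept)",
                            "loglik_ml": mdl.loglik_ml,
                            "aicc": mdl.aicc,
                            "delta_aicc": mdl.delta_aicc,
                            "rank": mdl.rank,
                        }
                    )
                best = ranking.best.fit
                for name, b, se, t, p in zip(
                    best.fixed_names, best.beta, best.se, best.t_values, best.p_values
                ):
                    coef_rows.append(
                        {
                            "response": response,
                            "term": name,
                            "estimate": b,
                            "se": se,
                            "t_value": t,
                            "p_value": p,
                        }
                    )
            write("lmm_ranking", pd.DataFrame(rank_rows))
            write("lmm_best_coefficients", pd.DataFrame(coef_rows))

            sem_sub = frame.dropna(
                subset=["mean_ar", "log10_total_aom", "distance_from_source",
                        "log10_sum_tu", "abundance"]
            )
            if len(sem_sub) >= 8:
                fit = fit_path_model(
                    [
                        ("log10_sum_tu", ["log10_total_aom"]),
                        ("abundance", ["log10_total_aom"]),
                        (
                            "mean_ar",
                            [
                                "log10_total_aom",
                                "distance_from_source",
                                "log10_sum_tu",
                                "abundance",
                            ],
                        ),
                    ],
                    {c: sem_sub[c].to_numpy() for c in sem_sub.columns
                     if c in ("mean_ar", "log10_total_aom", "distance_from_source",
                              "log10_sum_tu", "abundance")},
                )
                path_rows = [
                    {
                        "response": eq.response,
                        "predictor": p_name,
                        "coefficient": eq.coefficients[p_name],
                        "se": eq.se[p_name],
                        "p_value": eq.p_values[p_name],
                    }
                    for eq in fit.equations
                    for p_name in eq.predictors
                ]
                write("path_model", pd.DataFrame(path_rows))
    except Exception as exc:  # noqa: BLE001
        raise StageError("association", exc) from exc

    meta = {
        "amphigen_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "resolved_config": {k: v for k, v in resolved.items()},
        "outputs": sorted(outputs),
    }
    (out_dir / "run_metadata.json").write_text(
        json.dumps(meta, indent=2, default=str) + "\n"
    )
    return outputs


def _model_frame(bundle, diversity, tu_results, totals) -> pd.DataFrame:
    """Per-site modelling table; sites without tissue chemistry get NaN
    responses/predictors and drop out of complete-case fits."""
    rows = []
    for site, m in bundle.metadata.items():
        sd = diversity.get(site)
        tu = tu_results.get(site)
        tot = totals.get(site)
        ne = sd.ne_hat if sd else None
        log_ne = (
            math.log10(ne)
            if ne is not None and math.isfinite(ne) and ne > 0
            else np.nan
        )
        rows.append(
            {
                "site_id": site,
                "river": m.river,
                "catchment": m.catchment,
                "wwtp": 1.0 if m.wwtp_upstream else 0.0,
                "distance_from_source": m.distance_from_source,
                "conductivity": m.conductivity,
                "ph": m.ph,
                "oxygen_saturation": m.oxygen_saturation,
                "abundance": m.abundance,
                "mean_ar": sd.mean_ar if sd else np.nan,
                "f_is": sd.f_is if sd and sd.f_is is not None else np.nan,
                "log10_ne": log_ne,
                "log10_sum_tu": tu.log10_sum_tu
                if tu and tu.log10_sum_tu is not None
                else np.nan,
                "log10_total_aom": tot[1] if tot and tot[1] is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
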