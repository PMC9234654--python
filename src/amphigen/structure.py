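"""Between-group differentiation and spatial association.

Weir-Cockerham theta (multiallelic, component-summed over loci) with a
genotype-permutation significance test, hierarchical AMOVA on allele
mismatch distances, and (partial) Mantel tests on distance matrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .datatypes import DistanceMatrix, MicrosatDataset


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def _group_locus_stats(
    calls: list[tuple[int, int] | None], alleles: list[int]
) -> tuple[int, np.ndarray, np.ndarray] | None:
    """(n genotypes, allele freqs, heterozygote-carrier freqs) for one group/locus."""
    genos = [c for c in calls if c is not None]
    n = len(genos)
    if n == 0:
        return None
    idx = {a: k for k, a in enumerate(alleles)}
    p = np.zeros(len(alleles))
    h = np.zeros(len(alleles))
    for a, b in genos:
        p[idx[a]] += 1
        p[idx[b]] += 1
        if a != b:
            h[idx[a]] += 1
            h[idx[b]] += 1
    return n, p / (2 * n), h / n


def wc_components(
    per_group: list[tuple[int, np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-allele variance components (a, b, c) for one locus across r groups."""
    r = len(per_group)
    ns = np.array([g[0] for g in per_group], dtype=float)
    ps = np.stack([g[1] for g in per_group])  # (r, n_alleles)
    hs = np.stack([g[2] for g in per_group])
    n_bar = ns.mean()
    n_c = (ns.sum() - (ns**2).sum() / ns.sum()) / (r - 1)
    p_bar = (ns[:, None] * ps).sum(axis=0) / (r * n_bar)
    s2 = (ns[:, None] * (ps - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (ns[:, None] * hs).sum(axis=0) / (r * n_bar)
    inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
    a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2.0
    return a, b, c


def wc_fst(
    dataset: MicrosatDataset, labels: list[str], groups: list[str]
) -> float | None:
    """Multilocus Weir-Cockerham theta across the given groups.

    Components are summed over alleles and loci before the ratio is taken.
    Loci lacking data in any group, or monomorphic across the pooled groups,
    contribute nothing; returns None when no locus is usable.
    """
    num = den = 0.0
    usable = False
    member = [[i for i, lab in enumerate(labels) if lab == g] for g in groups]
    for j in range(dataset.n_loci):
        alleles = sorted(
            {
                a
                for idxs in member
                for i in idxs
                if dataset.calls[i][j] is not None
                for a in dataset.calls[i][j]
            }
        )
        if len(alleles) < 2:
            continue
        stats = []
        ok = True
        for idxs in member:
            st = _group_locus_stats([dataset.calls[i][j] for i in idxs], alleles)
            if st is None or st[0] < 2:
                ok = False
                break
            stats.append(st)
        if not ok:
            continue
        n_bar = np.mean([s[0] for s in stats])
        if n_bar <= 1:
            continue
        a, b, c = wc_components(stats)
        num += a.sum()
        den += (a + b + c).sum()
        usable = True
    if not usable or den == 0:
        return None
    return num / den


def wc_fst_pair(
    dataset: MicrosatDataset, group_a: str, group_b: str, grouping: str = "site"
) -> float | None:
    labels = dataset.group_of(grouping)
    return wc_fst(dataset, labels, [group_a, group_b])


@dataclass
class PairwiseFst:
    pair: tuple[str, str]
    theta: float | None
    p_value: float | None = None
    n_permutations: int = 0


def _precompute_stats(
    dataset: MicrosatDataset, labels: list[str]
) -> dict[str, list[tuple[int, np.ndarray, np.ndarray] | None]]:
    """Per group, per locus (n, allele freqs, het-carrier freqs) over the
    global allele list of that locus (absent alleles get frequency 0)."""
    global_alleles = []
    for j in range(dataset.n_loci):
        global_alleles.append(
            sorted(
                {
                    a
                    for i in range(dataset.n_individuals)
                    if dataset.calls[i][j] is not None
                    for a in dataset.calls[i][j]
                }
            )
        )
    out: dict[str, list] = {}
    for g in dict.fromkeys(labels):
        idxs = [i for i, lab in enumerate(labels) if lab == g]
        per_locus = []
        for j in range(dataset.n_loci):
            if not global_alleles[j]:
                per_locus.append(None)
                continue
            st = _group_locus_stats(
                [dataset.calls[i][j] for i in idxs], global_alleles[j]
            )
            per_locus.append(st)
        out[g] = per_locus
    return out


def _theta_from_stats(stats_a: list, stats_b: list, n_loci: int) -> float | None:
    num = den = 0.0
    usable = False
    for j in range(n_loci):
        sa, sb = stats_a[j], stats_b[j]
        if sa is None or sb is None or sa[0] < 2 or sb[0] < 2:
            continue
        a, b, c = wc_components([sa, sb])
        num += a.sum()
        den += (a + b + c).sum()
        usable = True
    if not usable or den == 0:
        return None
    return num / den


def fst_matrix(
    dataset: MicrosatDataset,
    grouping: str = "site",
    min_individuals: int = 2,
    exclude_loci: list[str] | None = None,
) -> list[PairwiseFst]:
    """Theta for every unordered group pair; river grouping pools sites.

    Groups with fewer than ``min_individuals`` are excluded (with the pairs
    that would involve them).  ``exclude_loci`` drops loci (e.g. ones with
    persistent null alleles) before estimation.
    """
    ds = dataset
    if exclude_loci:
        keep = [j for j, l in enumerate(ds.loci) if l not in exclude_loci]
        ds = ds.subset(loci=keep)
    labels = ds.group_of(grouping)
    order: dict[str, int] = {}
    for lab in labels:
        order.setdefault(lab, len(order))
    groups = [g for g in order if labels.count(g) >= min_individuals]
    stats = _precompute_stats(ds, labels)
    out = []
    for ga, gb in itertools.combinations(groups, 2):
        out.append(
            PairwiseFst(
                pair=(ga, gb),
                theta=_theta_from_stats(stats[ga], stats[gb], ds.n_loci),
            )
        )
    return out


def fst_distance_matrix(
    dataset: MicrosatDataset,
    grouping: str = "site",
    exclude_loci: list[str] | None = None,
) -> DistanceMatrix:
    """Pairwise theta as a (clamped non-negative) distance matrix for Mantel use."""
    pairs = fst_matrix(dataset, grouping=grouping, exclude_loci=exclude_loci)
    groups: list[str] = []
    for p in pairs:
        for g in p.pair:
            if g not in groups:
                groups.append(g)
    n = len(groups)
    mat = np.zeros((n, n))
    for p in pairs:
        i, j = groups.index(p.pair[0]), groups.index(p.pair[1])
        theta = 0.0 if p.theta is None else max(p.theta, 0.0)
        mat[i, j] = mat[j, i] = theta
    return DistanceMatrix(groups, mat, "fst")


def fst_permutation_test(
    dataset: MicrosatDataset,
    pair: tuple[str, str],
    n_perm: int = 10000,
    seed: int | None = None,
    grouping: str = "site",
    permute: str = "genotypes",
) -> float | None:
    """Permutation p-value for theta > 0 between two groups.

    The exchangeable unit is the multilocus genotype (individuals shuffled
    between the two groups); ``permute="loci"`` instead reassigns whole loci
    between the groups' allele pools per permutation (legacy mode).  The
    add-one estimator p = (1 + hits) / (1 + n_perm) is used, so p is never 0.
    """
    if n_perm < 1:
        return None
    labels = dataset.group_of(grouping)
    ga, gb = pair
    idx = [i for i, lab in enumerate(labels) if lab in (ga, gb)]
    sub = dataset.subset(individuals=idx)
    sub_labels = [labels[i] for i in idx]
    theta_obs = wc_fst(sub, sub_labels, [ga, gb])
    if theta_obs is None:
        return None
    rng = np.random.default_rng(seed)
    lab_arr = np.array(sub_labels)
    hits = 0
    for _ in range(n_perm):
        if permute == "genotypes":
            perm = rng.permutation(lab_arr).tolist()
            theta_p = wc_fst(sub, perm, [ga, gb])
        elif permute == "loci":
            # swap each locus column between groups at random
            swap = rng.random(sub.n_loci) < 0.5
            calls = [list(row) for row in sub.calls]
            a_idx = [i for i, lab in enumerate(sub_labels) if lab == ga]
            b_idx = [i for i, lab in enumerate(sub_labels) if lab == gb]
            m = min(len(a_idx), len(b_idx))
            for j, do in enumerate(swap):
                if do:
                    for ia, ib in zip(a_idx[:m], b_idx[:m]):
                        calls[ia][j], calls[ib][j] = calls[ib][j], calls[ia][j]
            shuffled = MicrosatDataset(
                individuals=sub.individuals, loci=sub.loci, calls=calls,
                site_to_river=sub.site_to_river,
                river_to_catchment=sub.river_to_catchment,
            )
            theta_p = wc_fst(shuffled, sub_labels, [ga, gb])
        else:
            raise ValueError(f"unknown permute mode {permute!r}")
        if theta_p is not None and theta_p >= theta_obs - 1e-15:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    sigma_among: float  # among top-level groups
    sigma_among_sites: float  # among sites within groups
    sigma_within: float  # within sites
    phi_ct: float | None
    phi_sc: float | None
    phi_st: float | None
    df: tuple[int, int, int]
    ss: tuple[float, float, float]
    p_values: dict[str, float | None]


def allele_mismatch_matrix(dataset: MicrosatDataset) -> np.ndarray:
    """Pairwise squared distances: allele differences summed over shared loci."""
    n = dataset.n_individuals
    arr = dataset.allele_array()  # (n, L, 2), 0 = missing
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tot = 0.0
            for l in range(dataset.n_loci):
                a = arr[i, l]
                b = arr[j, l]
                if a[0] == 0 or b[0] == 0:
                    continue
                # multiset mismatch count between two diploid calls
                shared = 0
                used = [False, False]
                for x in a:
                    for k, y in enumerate(b):
                        if not used[k] and x == y:
                            used[k] = True
                            shared += 1
                            break
                tot += 2 - shared
            d[i, j] = d[j, i] = tot
    return d


def _amova_components(
    d2: np.ndarray, sites: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float, tuple[int, int, int], tuple[float, float, float]]:
    def ss_within(partition: np.ndarray) -> float:
        total = 0.0
        for lab in np.unique(partition):
            idx = np.where(partition == lab)[0]
            total += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
        return total

    n = len(sites)
    uniq_groups = np.unique(groups)
    uniq_sites = np.unique(sites)
    g = len(uniq_groups)
    s = len(uniq_sites)
    ss_total = d2.sum() / (2.0 * n)
    ss_ws = ss_within(sites)
    ss_wg = ss_within(groups)
    ss_as = ss_wg - ss_ws  # among sites within groups
    ss_ag = ss_total - ss_wg
    df_ag, df_as, df_ws = g - 1, s - g, n - s
    sigma_c = ss_ws / df_ws if df_ws > 0 else 0.0
    site_sizes = {lab: np.sum(sites == lab) for lab in uniq_sites}
    group_of_site = {
        lab: groups[np.where(sites == lab)[0][0]] for lab in uniq_sites
    }
    group_sizes = {lab: np.sum(groups == lab) for lab in uniq_groups}
    sum_ns2_over_nr = sum(
        sum(site_sizes[s_] ** 2 for s_ in uniq_sites if group_of_site[s_] == gr)
        / group_sizes[gr]
        for gr in uniq_groups
    )
    n_prime = (n - sum_ns2_over_nr) / df_as if df_as > 0 else float("nan")
    sigma_b = (ss_as / df_as - sigma_c) / n_prime if df_as > 0 else 0.0
    sum_ns2_over_n = sum(v**2 for v in site_sizes.values()) / n
    n_dprime = (sum_ns2_over_nr - sum_ns2_over_n) / df_ag
    n_tprime = (n - sum(v**2 for v in group_sizes.values()) / n) / df_ag
    sigma_a = (ss_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    return (
        sigma_a,
        sigma_b,
        sigma_c,
        (df_ag, df_as, df_ws),
        (ss_ag, ss_as, ss_ws),
    )


def amova(
    dataset: MicrosatDataset,
    top_level: str = "river",
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA: top-level groups / sites within groups / within sites.

    Distances are allele mismatch counts (missing loci skipped pairwise).
    Permutation schemes: Phi_ST permutes individuals among all sites,
    Phi_SC permutes individuals among sites within their group, and Phi_CT
    permutes whole sites among groups.
    """
    sites = np.array([ind.site_id for ind in dataset.individuals])
    groups = np.array(dataset.group_of(top_level))
    if len(np.unique(groups)) < 2 or len(np.unique(sites)) <= len(np.unique(groups)):
        raise ValueError("degenerate hierarchy: need >=2 groups and more sites than groups")
    d2 = allele_mismatch_matrix(dataset)
    sigma_a, sigma_b, sigma_c, df, ss = _amova_components(d2, sites, groups)
    total = sigma_a + sigma_b + sigma_c

    def phis(sa, sb, sc):
        tot = sa + sb + sc
        return (
            sa / tot if tot > 0 else None,
            sb / (sb + sc) if (sb + sc) > 0 else None,
            (sa + sb) / tot if tot > 0 else None,
        )

    phi_ct, phi_sc, phi_st = phis(sigma_a, sigma_b, sigma_c)
    p_values: dict[str, float | None] = {"phi_ct": None, "phi_sc": None, "phi_st": None}
    if n_perm >= 1 and total > 0:
        rng = np.random.default_rng(seed)
        hits = {"phi_ct": 0, "phi_sc": 0, "phi_st": 0}
        site_list = np.unique(sites)
        group_of_site = {s_: groups[np.where(sites == s_)[0][0]] for s_ in site_list}
        for _ in range(n_perm):
            # phi_st: individuals among all sites
            perm_sites = rng.permutation(sites)
            pa, pb, pc, _, _ = _amova_components(
                d2, perm_sites, np.array([group_of_site[s_] for s_ in perm_sites])
            )
            st = phis(pa, pb, pc)[2]
            if st is not None and phi_st is not None and st >= phi_st - 1e-15:
                hits["phi_st"] += 1
            # phi_sc: individuals among sites within their group
            perm2 = sites.copy()
            for gr in np.unique(groups):
                idx = np.where(groups == gr)[0]
                perm2[idx] = rng.permutation(sites[idx])
            pa, pb, pc, _, _ = _amova_components(d2, perm2, groups)
            sc = phis(pa, pb, pc)[1]
            if sc is not None and phi_sc is not None and sc >= phi_sc - 1e-15:
                hits["phi_sc"] += 1
            # phi_ct: whole sites among groups
            shuffled = rng.permutation([group_of_site[s_] for s_ in site_list])
            remap = dict(zip(site_list, shuffled))
            perm_groups = np.array([remap[s_] for s_ in sites])
            pa, pb, pc, _, _ = _amova_components(d2, sites, perm_groups)
            ct = phis(pa, pb, pc)[0]
            if ct is not None and phi_ct is not None and ct >= phi_ct - 1e-15:
                hits["phi_ct"] += 1
        p_values = {k: (v + 1) / (n_perm + 1) for k, v in hits.items()}
    return AmovaResult(
        sigma_among=sigma_a,
        sigma_among_sites=sigma_b,
        sigma_within=sigma_c,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        phi_st=phi_st,
        df=df,
        ss=ss,
        p_values=p_values,
    )


# ---------------------------------------------------------------------------
# Distance matrices and Mantel tests


def aom_distance_matrix(
    per_site: dict[str, float | None], transform: str = "log10", kind: str = "aom_difference"
) -> DistanceMatrix:
    """Pairwise absolute differences of a per-site scalar, optionally log10."""
    sites = [s for s, v in per_site.items() if v is not None]
    if transform == "log10":
        vals = np.log10([per_site[s] for s in sites])
    elif transform == "identity":
        vals = np.array([per_site[s] for s in sites], dtype=float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    mat = np.abs(vals[:, None] - vals[None, :])
    return DistanceMatrix(sites, mat, kind)


@dataclass
class MantelResult:
    r: float
    p_value: float | None
    n_permutations: int
    partial: bool = False
    conditioning: str | None = None


def _lower(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices_from(m, k=-1)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    den = math.sqrt((x @ x) * (y @ y))
    return float(x @ y / den) if den > 0 else 0.0


def _check_conformable(*mats: DistanceMatrix) -> None:
    sites = mats[0].sites
    for m in mats[1:]:
        if m.sites != sites:
            raise ValueError("distance matrices cover different site sets/orders")


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
    method: str = "monte-carlo",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the lower triangles; significance by
    simultaneous row/column permutation of ``a``.  One-sided positive by
    default (isolation-by-distance usage).  ``method="exhaustive"``
    enumerates all n! relabelings (small n only) and the p-value is the
    exact share of permutations with a statistic at least as extreme.
    """
    _check_conformable(a, b)
    n = len(a.sites)
    if n < 4:
        raise ValueError("need at least 4 sites for a Mantel test")
    va, vb = _lower(a.values), _lower(b.values)
    r_obs = _pearson(va, vb)

    def stat(perm: np.ndarray) -> float:
        ap = a.values[np.ix_(perm, perm)]
        return _pearson(_lower(ap), vb)

    def extreme(r_p: float) -> bool:
        if alternative == "greater":
            return r_p >= r_obs - 1e-15
        if alternative == "two-sided":
            return abs(r_p) >= abs(r_obs) - 1e-15
        raise ValueError(f"unknown alternative {alternative!r}")

    if method == "exhaustive":
        perms = list(itertools.permutations(range(n)))
        hits = sum(1 for p in perms if extreme(stat(np.array(p))))
        return MantelResult(r=r_obs, p_value=hits / len(perms), n_permutations=len(perms) - 1)
    if n_perm < 1:
        return MantelResult(r=r_obs, p_value=None, n_permutations=0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if extreme(stat(rng.permutation(n))):
            hits += 1
    return MantelResult(r=r_obs, p_value=(hits + 1) / (n_perm + 1), n_permutations=n_perm)


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel test of a ~ b conditioning on c (residual correlation).

    Residuals of the lower triangles of ``a`` and ``b`` on ``c`` are
    correlated; the permutation scheme relabels ``a`` and re-residualizes it
    each time.
    """
    _check_conformable(a, b, c)
    n = len(a.sites)
    if n < 4:
        raise ValueError("need at least 4 sites for a partial Mantel test")
    vb, vc = _lower(b.values), _lower(c.values)

    def residuals(y: np.ndarray) -> np.ndarray:
        x = np.column_stack([np.ones_like(vc), vc])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        # a perfectly explained matrix leaves numerical dust; zero it so the
        # degenerate partial correlation is exactly 0 rather than noise
        scale = max(float(np.abs(y).max()), 1.0)
        if float(np.abs(r).max()) < 1e-10 * scale:
            return np.zeros_like(r)
        return r

    rb = residuals(vb)
    r_obs = _pearson(residuals(_lower(a.values)), rb)

    def extreme(r_p: float) -> bool:
        if alternative == "greater":
            return r_p >= r_obs - 1e-15
        return abs(r_p) >= abs(r_obs) - 1e-15

    p_value = None
    if n_perm >= 1:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            ra = residuals(_lower(a.values[np.ix_(perm, perm)]))
            if extreme(_pearson(ra, rb)):
                hits += 1
        p_value = (hits + 1) / (n_perm + 1)
    return MantelResult(
        r=r_obs,
        p_value=p_value,
        n_permutations=n_perm,
        partial=True,
        conditioning=c.kind,
    )
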