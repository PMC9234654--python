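"""Per-site genetic diversity statistics.

QC filtering, observed/expected heterozygosity and the inbreeding
coefficient, hypergeometric-rarefied allelic and private-allele richness,
a Monte-Carlo Hardy-Weinberg exact test, and the two textbook null-allele
frequency estimators.  The LD effective-size estimator lives in
:mod:`amphigen.neld`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .datatypes import MicrosatDataset


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    removed_individuals: list[str]
    removed_loci: list[str]
    max_missing: float
    order: str = "individuals-then-loci"


def qc_filter(
    dataset: MicrosatDataset, max_missing: float = 0.20
) -> tuple[MicrosatDataset, QCReport]:
    """Drop individuals, then loci, with a missing fraction above ``max_missing``.

    Comparisons are strict (> max_missing removed), so an individual missing
    exactly 20% of loci is retained.  Individuals are filtered first, which
    maximizes locus retention; locus missingness is then assessed on the
    retained individuals only.
    """
    n_loci = dataset.n_loci
    keep_ind = []
    removed_ind = []
    for i, ind in enumerate(dataset.individuals):
        miss = sum(1 for c in dataset.calls[i] if c is None)
        if n_loci > 0 and miss / n_loci > max_missing:
            removed_ind.append(ind.id)
        else:
            keep_ind.append(i)
    if dataset.individuals and not keep_ind:
        raise ValueError("QC removed every individual")
    keep_loc = []
    removed_loc = []
    n_kept = len(keep_ind)
    for j, locus in enumerate(dataset.loci):
        miss = sum(1 for i in keep_ind if dataset.calls[i][j] is None)
        if n_kept > 0 and miss / n_kept > max_missing:
            removed_loc.append(locus)
        else:
            keep_loc.append(j)
    filtered = dataset.subset(individuals=keep_ind, loci=keep_loc)
    return filtered, QCReport(removed_ind, removed_loc, max_missing)


# ---------------------------------------------------------------------------
# Allele counts

def allele_counts(
    dataset: MicrosatDataset, grouping: str = "site"
) -> dict[str, dict[str, Counter]]:
    """counts[group][locus] -> Counter(allele code -> gene copies)."""
    labels = dataset.group_of(grouping)
    out: dict[str, dict[str, Counter]] = {}
    for i, lab in enumerate(labels):
        per_locus = out.setdefault(lab, {loc: Counter() for loc in dataset.loci})
        for j, locus in enumerate(dataset.loci):
            call = dataset.calls[i][j]
            if call is not None:
                per_locus[locus][call[0]] += 1
                per_locus[locus][call[1]] += 1
    return out


# ---------------------------------------------------------------------------
# Heterozygosity


@dataclass
class LocusHet:
    n: int  # non-missing genotypes
    h_obs: float
    h_exp: float  # Nei unbiased gene diversity
    f_is: float | None


def het_locus(genotypes: list[tuple[int, int]]) -> LocusHet | None:
    """Nei-style statistics for one locus in one group.

    H_e is the unbiased estimator  (n/(n-1)) * (1 - sum p^2 - H_o/(2n)).
    Returns None when fewer than two genotypes are available; F_IS is None
    for monomorphic loci (H_e = 0).
    """
    n = len(genotypes)
    if n < 2:
        return None
    h_obs = sum(1 for a, b in genotypes if a != b) / n
    counts = Counter()
    for a, b in genotypes:
        counts[a] += 1
        counts[b] += 1
    total = 2 * n
    sum_p2 = sum((c / total) ** 2 for c in counts.values())
    h_exp = (n / (n - 1)) * (1.0 - sum_p2 - h_obs / (2 * n))
    f_is = 1.0 - h_obs / h_exp if h_exp > 1e-12 else None
    return LocusHet(n=n, h_obs=h_obs, h_exp=h_exp, f_is=f_is)


@dataclass
class SiteHetStats:
    per_locus: dict[str, LocusHet | None]
    h_obs: float | None  # mean over informative loci
    h_exp: float | None
    f_is: float | None  # 1 - sum(Ho)/sum(He) over polymorphic loci


def het_stats(dataset: MicrosatDataset, grouping: str = "site") -> dict[str, SiteHetStats]:
    """Per-group heterozygosity statistics.

    The multilocus F_IS is a ratio of summed components,
    1 - sum_l H_o(l) / sum_l H_e(l), over loci with H_e > 0; this is more
    stable than averaging per-locus ratios at low-diversity loci.
    """
    labels = dataset.group_of(grouping)
    groups = sorted(set(labels), key=labels.index)
    out: dict[str, SiteHetStats] = {}
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        per_locus: dict[str, LocusHet | None] = {}
        for j, locus in enumerate(dataset.loci):
            genos = [dataset.calls[i][j] for i in idx if dataset.calls[i][j] is not None]
            per_locus[locus] = het_locus(genos)
        informative = [lh for lh in per_locus.values() if lh is not None]
        if informative:
            h_obs = float(np.mean([lh.h_obs for lh in informative]))
            h_exp = float(np.mean([lh.h_exp for lh in informative]))
        else:
            h_obs = h_exp = None
        poly = [lh for lh in informative if lh.h_exp > 1e-12]
        sum_he = sum(lh.h_exp for lh in poly)
        f_is = 1.0 - sum(lh.h_obs for lh in poly) / sum_he if sum_he > 1e-12 else None
        out[g] = SiteHetStats(per_locus=per_locus, h_obs=h_obs, h_exp=h_exp, f_is=f_is)
    return out


# ---------------------------------------------------------------------------
# Rarefaction


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def prob_allele_in_subsample(n_i: int, n_total: int, g: int) -> float:
    """P(allele with n_i copies out of n_total appears in a subsample of g)."""
    if n_i <= 0:
        return 0.0
    if n_total - n_i < g:
        return 1.0
    return 1.0 - math.exp(_log_comb(n_total - n_i, g) - _log_comb(n_total, g))


def rarefied_allelic_richness(counts: Counter, g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` gene copies.

    Exact hypergeometric rarefaction; combinatorials evaluated in log space.
    """
    n_total = sum(counts.values())
    if g < 1:
        raise ValueError("g must be >= 1")
    if g > n_total:
        raise ValueError(f"g={g} exceeds available gene copies ({n_total})")
    return sum(prob_allele_in_subsample(c, n_total, g) for c in counts.values())


def rarefied_private_alleles(
    group_counts: dict[str, Counter], g: int
) -> dict[str, float]:
    """Rarefied private-allele richness per group at subsample size ``g``.

    For each allele, the probability that it shows up in a size-g subsample
    of the focal group while missing from size-g subsamples of every other
    group; probabilities use each group's own total gene count.
    """
    groups = list(group_counts)
    if len(groups) < 2:
        raise ValueError("need at least two groups for private alleles")
    totals = {grp: sum(c.values()) for grp, c in group_counts.items()}
    for grp, tot in totals.items():
        if g > tot:
            raise ValueError(f"g={g} exceeds gene copies in group {grp!r} ({tot})")
    alleles = sorted(set().union(*group_counts.values()))
    present = {
        grp: {a: prob_allele_in_subsample(group_counts[grp].get(a, 0), totals[grp], g)
              for a in alleles}
        for grp in groups
    }
    out: dict[str, float] = {}
    for grp in groups:
        pa = 0.0
        for a in alleles:
            term = present[grp][a]
            for other in groups:
                if other != grp:
                    term *= 1.0 - present[other][a]
            pa += term
        out[grp] = pa
    return out


@dataclass
class RarefactionResult:
    # per-locus per-group values; NaN where a locus has no data in a group
    ar: dict[str, dict[str, float]]  # group -> locus -> AR(g)
    pa: dict[str, dict[str, float]]  # group -> locus -> PA(g)
    g: dict[str, int]  # locus -> rarefaction size used
    mean_ar: dict[str, float]
    mean_pa: dict[str, float]


def rarefaction_table(
    dataset: MicrosatDataset, grouping: str = "site", g: int | None = None
) -> RarefactionResult:
    """AR(g) and PA(g) per locus per group plus over-locus means.

    When ``g`` is None the per-locus size is 2 x the smallest per-group
    count of complete genotypes at that locus (i.e., the smallest gene-copy
    total across groups).  Loci where the smallest total is 0 are skipped.
    """
    counts = allele_counts(dataset, grouping)
    groups = list(counts)
    ar: dict[str, dict[str, float]] = {grp: {} for grp in groups}
    pa: dict[str, dict[str, float]] = {grp: {} for grp in groups}
    g_used: dict[str, int] = {}
    for locus in dataset.loci:
        totals = [sum(counts[grp][locus].values()) for grp in groups]
        if min(totals) == 0:
            continue
        g_loc = g if g is not None else min(totals)
        if g_loc > min(totals):
            raise ValueError(
                f"g={g_loc} exceeds gene copies at locus {locus!r} "
                f"(min across groups = {min(totals)})"
            )
        g_used[locus] = g_loc
        for grp in groups:
            ar[grp][locus] = rarefied_allelic_richness(counts[grp][locus], g_loc)
        if len(groups) >= 2:
            pa_loc = rarefied_private_alleles(
                {grp: counts[grp][locus] for grp in groups}, g_loc
            )
            for grp in groups:
                pa[grp][locus] = pa_loc[grp]
    mean_ar = {grp: float(np.mean(list(v.values()))) for grp, v in ar.items() if v}
    mean_pa = {grp: float(np.mean(list(v.values()))) for grp, v in pa.items() if v}
    return RarefactionResult(ar=ar, pa=pa, g=g_used, mean_ar=mean_ar, mean_pa=mean_pa)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte Carlo)


def _log_table_prob(genotypes: list[tuple[int, int]]) -> float:
    """Log conditional probability of a genotype table given allele counts."""
    n = len(genotypes)
    allele = Counter()
    geno = Counter()
    n_het = 0
    for a, b in genotypes:
        allele[a] += 1
        allele[b] += 1
        geno[(a, b) if a <= b else (b, a)] += 1
        if a != b:
            n_het += 1
    logp = (
        gammaln(n + 1)
        - gammaln(2 * n + 1)
        + n_het * math.log(2.0)
        + sum(gammaln(c + 1) for c in allele.values())
        - sum(gammaln(c + 1) for c in geno.values())
    )
    return logp


def hwe_test(
    genotypes: list[tuple[int, int]], n_reps: int, seed: int | None = None
) -> float | None:
    """Monte-Carlo exact Hardy-Weinberg test for one locus in one group.

    Gene copies are shuffled into new diploid genotypes ``n_reps`` times;
    the p-value is the add-one-smoothed share of replicates whose table is
    no more probable than the observed one.  Returns None with fewer than
    five genotypes or when n_reps is 0.
    """
    if len(genotypes) < 5 or n_reps < 1:
        return None
    rng = np.random.default_rng(seed)
    genes = np.array([a for g in genotypes for a in g])
    obs = _log_table_prob(genotypes)
    hits = 0
    for _ in range(n_reps):
        rng.shuffle(genes)
        perm = list(zip(genes[0::2].tolist(), genes[1::2].tolist()))
        if _log_table_prob(perm) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_reps + 1)


# ---------------------------------------------------------------------------
# Null alleles


def null_allele_freq(h_obs: float, h_exp: float) -> tuple[float, float] | None:
    """Chakraborty and Brookfield-1 null-allele frequency estimators.

    chakraborty = (He - Ho) / (He + Ho);  brookfield = (He - Ho) / (1 + He).
    Raw values are returned (no flooring at 0); None when He = 0.
    """
    if h_exp <= 0:
        return None
    chakraborty = (h_exp - h_obs) / (h_exp + h_obs) if (h_exp + h_obs) > 0 else None
    brookfield = (h_exp - h_obs) / (1.0 + h_exp)
    return chakraborty, brookfield


NULL_ALLELE_FLAG_LEVEL = 0.2


@dataclass
class SiteDiversity:
    """Summary row for one site: the per-site diversity table."""

    site_id: str
    n_individuals: int
    h_obs: float | None
    h_exp: float | None
    f_is: float | None
    mean_ar: float | None = None
    mean_pa: float | None = None
    ne_hat: float | None = None
    ne_ci: tuple[float | None, float | None] | None = None


def site_diversity(
    dataset: MicrosatDataset,
    g: int | None = None,
    estimate_ne: bool = True,
    pcrit: float = 0.05,
) -> dict[str, SiteDiversity]:
    """Assemble the per-site diversity summary (heterozygosity, rarefied
    richness, LD effective size)."""
    from .neld import ne_ld

    hets = het_stats(dataset, "site")
    sites = dataset.site_ids
    rar = rarefaction_table(dataset, "site", g=g) if len(sites) >= 1 else None
    out: dict[str, SiteDiversity] = {}
    for site in sites:
        idx = dataset.site_indices(site)
        sd = SiteDiversity(
            site_id=site,
            n_individuals=len(idx),
            h_obs=hets[site].h_obs,
            h_exp=hets[site].h_exp,
            f_is=hets[site].f_is,
        )
        if rar is not None and site in rar.mean_ar:
            sd.mean_ar = rar.mean_ar[site]
            sd.mean_pa = rar.mean_pa.get(site)
        if estimate_ne:
            est = ne_ld(dataset.subset(individuals=idx), pcrit=pcrit)
            if est is not None:
                sd.ne_hat = est.ne_hat
                sd.ne_ci = est.ci
        out[site] = sd
    return out
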