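"""Effective population size from background linkage disequilibrium.

For every pair of loci the Burrows composite disequilibrium is computed
for every retained allele pair, converted to a squared correlation, and
averaged (weighted by the pairwise sample size).  The sampling expectation
of r-squared under random mating is subtracted and the drift component is
inverted to an effective-size estimate; a delete-one-locus jackknife gives
the confidence interval.

Alleles with frequency below ``pcrit`` are screened out before the
computation (low-frequency alleles upwardly bias r-squared).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import MicrosatDataset


@dataclass
class NeEstimate:
    ne_hat: float  # math.inf when LD is at or below its sampling expectation
    r2_mean: float
    r2_drift: float
    s_mean: float  # weighted mean pairwise sample size
    n_comparisons: int
    ci: tuple[float | None, float | None] | None = None  # 95% jackknife


def expected_r2_sample(s: float) -> float:
    """Sampling expectation of r-squared for sample size ``s`` (random mating)."""
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def ne_from_r2_drift(r2_drift: float, s: float) -> float:
    """Invert the drift r-squared to an effective size (bias-adjusted form)."""
    if r2_drift <= 0:
        return math.inf
    if s >= 30:
        disc = max(1.0 / 9.0 - 2.76 * r2_drift, 0.0)
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2_drift)
    disc = max(0.308**2 - 2.08 * r2_drift, 0.0)
    return (0.308 + math.sqrt(disc)) / (2.0 * r2_drift)


def _pair_r2(
    arr: np.ndarray, j: int, k: int, keep: dict[int, np.ndarray]
) -> tuple[np.ndarray, int] | None:
    """r-squared values for all retained allele pairs of loci ``j`` and ``k``.

    Returns (flat array of r2 values, pairwise sample size) or None when the
    pair is unusable (too few joint observations or no polymorphism).
    """
    ok = (arr[:, j, 0] > 0) & (arr[:, k, 0] > 0)
    s = int(ok.sum())
    if s < 3:
        return None
    sub_j = arr[ok, j, :]
    sub_k = arr[ok, k, :]

    def dosage(sub: np.ndarray, alleles: np.ndarray) -> np.ndarray:
        return (sub[:, :1] == alleles).astype(float) + (sub[:, 1:] == alleles).astype(float)

    a_j = keep[j]
    a_k = keep[k]
    gj = dosage(sub_j, a_j)  # (s, kj)
    gk = dosage(sub_k, a_k)
    pj = gj.mean(axis=0) / 2.0
    pk = gk.mean(axis=0) / 2.0
    # screen again within the pair sample: alleles may be fixed/absent here
    use_j = (pj > 0) & (pj < 1)
    use_k = (pk > 0) & (pk < 1)
    if not use_j.any() or not use_k.any():
        return None
    gj, pj = gj[:, use_j], pj[use_j]
    gk, pk = gk[:, use_k], pk[use_k]
    # Burrows composite disequilibrium with the small-sample factor s/(s-1)
    delta = (gj.T @ gk) / (2.0 * s) - 2.0 * np.outer(pj, pk)
    delta *= s / (s - 1.0)
    # Weir's composite correlation: the denominator includes the observed
    # homozygote excess, which keeps the estimator unbiased off HWE
    d_j = (gj == 2.0).mean(axis=0) - pj**2
    d_k = (gk == 2.0).mean(axis=0) - pk**2
    denom = np.outer(pj * (1.0 - pj) + d_j, pk * (1.0 - pk) + d_k)
    good = denom > 0
    if not good.any():
        return None
    r2 = delta[good] ** 2 / denom[good]
    return r2.ravel(), s


def ne_ld(
    dataset: MicrosatDataset,
    pcrit: float = 0.05,
    jackknife: bool = True,
) -> NeEstimate | None:
    """Waples-Do style LD effective-size estimate for one sample.

    Returns None when fewer than two loci remain polymorphic after allele
    screening.  ``ne_hat`` is ``math.inf`` when the observed mean r-squared
    does not exceed its sampling expectation.
    """
    arr = dataset.allele_array()
    n_loci = arr.shape[1]
    keep: dict[int, np.ndarray] = {}
    for j in range(n_loci):
        sub = arr[arr[:, j, 0] > 0, j, :]
        if len(sub) == 0:
            continue
        alleles, counts = np.unique(sub, return_counts=True)
        freqs = counts / counts.sum()
        sel = alleles[(freqs >= pcrit) & (freqs < 1.0)]
        if len(sel) >= 2 or (len(sel) == 1 and len(alleles) > 1):
            # biallelic loci carry one independent comparison: keep one allele
            keep[j] = sel[:1] if len(alleles) == 2 else sel
    loci = sorted(keep)
    if len(loci) < 2:
        return None

    per_pair: list[tuple[int, int, np.ndarray, int]] = []
    for a in range(len(loci)):
        for b in range(a + 1, len(loci)):
            res = _pair_r2(arr, loci[a], loci[b], keep)
            if res is not None:
                per_pair.append((loci[a], loci[b], res[0], res[1]))
    if not per_pair:
        return None

    def combine(pairs) -> tuple[float, float, int]:
        num = den = 0.0
        ncmp = 0
        for _, _, r2, s in pairs:
            num += r2.sum() * s
            den += len(r2) * s
            ncmp += len(r2)
        r2_mean = num / den
        s_mean = sum(s * len(r2) for _, _, r2, s in pairs) / sum(
            len(r2) for _, _, r2, s in pairs
        )
        return r2_mean, s_mean, ncmp

    r2_mean, s_mean, ncmp = combine(per_pair)
    r2_drift = r2_mean - expected_r2_sample(s_mean)
    ne_hat = ne_from_r2_drift(r2_drift, s_mean)

    ci = None
    if jackknife and len(loci) > 2:
        pseudo = []
        for drop in loci:
            sub = [p for p in per_pair if drop not in (p[0], p[1])]
            if sub:
                pseudo.append(combine(sub)[0])
        m = len(pseudo)
        if m > 1:
            pseudo_arr = np.array(pseudo)
            jk_mean = pseudo_arr.mean()
            jk_var = (m - 1) / m * float(((pseudo_arr - jk_mean) ** 2).sum())
            half = 1.96 * math.sqrt(jk_var)
            r2_lo, r2_hi = r2_mean - half, r2_mean + half
            e = expected_r2_sample(s_mean)
            # Ne is antitone in r2: upper r2 bound -> lower Ne bound
            lo = ne_from_r2_drift(r2_hi - e, s_mean)
            hi = ne_from_r2_drift(r2_lo - e, s_mean)
            ci = (lo, hi)
    return NeEstimate(
        ne_hat=ne_hat,
        r2_mean=r2_mean,
        r2_drift=r2_drift,
        s_mean=s_mean,
        n_comparisons=ncmp,
        ci=ci,
    )
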