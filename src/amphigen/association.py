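"""Diversity-versus-pollution inference.

Random-intercept linear mixed models fitted by profiling the variance
ratio, small-sample AIC model ranking over all fixed-effect subsets, and
recursive path models on standardized observed variables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# Linear mixed model: y = X beta + Z u + e, one random intercept per group.
#
# With lambda = sigma_u^2 / sigma^2 the covariance is sigma^2 (I + lambda Z Z'),
# block diagonal per group, so H^-1 and log|H| have closed forms and the
# likelihood is profiled over a single bounded parameter.


@dataclass
class LmmFit:
    response: str
    fixed_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    sigma2_u: float
    sigma2_e: float
    loglik_ml: float
    loglik_reml: float
    n: int
    k: int  # estimated parameters: fixed effects + 2 variance components
    aicc: float | None
    group_label: str = "group"
    method: str = "REML"


def _group_blocks(groups: np.ndarray) -> list[np.ndarray]:
    uniq = np.unique(groups)
    return [np.where(groups == g)[0] for g in uniq]


def _profiled_quantities(
    y: np.ndarray, x: np.ndarray, blocks: list[np.ndarray], lam: float
):
    """GLS beta, residual quadratic form, log|H|, and X'H^-1X at a given lambda."""
    xtwx = np.zeros((x.shape[1], x.shape[1]))
    xtwy = np.zeros(x.shape[1])
    logdet = 0.0
    for idx in blocks:
        ng = len(idx)
        shrink = lam / (1.0 + lam * ng)
        xg, yg = x[idx], y[idx]
        xtwx += xg.T @ xg - shrink * np.outer(xg.sum(0), xg.sum(0))
        xtwy += xg.T @ yg - shrink * xg.sum(0) * yg.sum()
        logdet += math.log1p(lam * ng)
    beta = np.linalg.solve(xtwx, xtwy)
    quad = 0.0
    for idx in blocks:
        ng = len(idx)
        shrink = lam / (1.0 + lam * ng)
        rg = y[idx] - x[idx] @ beta
        quad += rg @ rg - shrink * rg.sum() ** 2
    return beta, quad, logdet, xtwx


def _score(
    lam: float, y: np.ndarray, x: np.ndarray, blocks: list[np.ndarray], reml: bool
) -> float:
    """d(-2 loglik)/d lambda at fixed lambda (envelope theorem for beta-hat).

    Per group g with size n_g and shrink factor 1/(1 + lam n_g):
    d log|H| = sum n_g/(1+lam n_g);  d quad = -sum s_g^2/(1+lam n_g)^2 with
    s_g the group sum of GLS residuals; the REML term differentiates
    log|X' H^-1 X| the same way through the group column sums of X.
    """
    n, p = x.shape
    beta, quad, _, xtwx = _profiled_quantities(y, x, blocks, lam)
    r = y - x @ beta
    d_logdet = 0.0
    d_quad = 0.0
    d_xtwx = np.zeros((p, p))
    for idx in blocks:
        ng = len(idx)
        denom = (1.0 + lam * ng) ** 2
        d_logdet += ng / (1.0 + lam * ng)
        d_quad -= r[idx].sum() ** 2 / denom
        if reml:
            cs = x[idx].sum(0)
            d_xtwx -= np.outer(cs, cs) / denom
    dof = n - p if reml else n
    score = dof * d_quad / quad + d_logdet
    if reml:
        score += np.trace(np.linalg.solve(xtwx, d_xtwx))
    return score


def _neg_loglik(
    lam: float, y: np.ndarray, x: np.ndarray, blocks: list[np.ndarray], reml: bool
) -> float:
    n, p = x.shape
    _, quad, logdet, xtwx = _profiled_quantities(y, x, blocks, lam)
    if quad <= 0:
        return np.inf
    if reml:
        dof = n - p
        sigma2 = quad / dof
        sign, logdet_xtwx = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            dof * math.log(2 * math.pi * sigma2) + logdet + logdet_xtwx + dof
        )
    else:
        sigma2 = quad / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return -ll


def fit_lmm(
    response: str,
    y: np.ndarray,
    x: np.ndarray,
    fixed_names: list[str],
    groups: np.ndarray,
    method: str = "REML",
    group_label: str = "group",
) -> LmmFit:
    """Fit a single-random-intercept LMM by 1-D profile optimization.

    ``x`` must include the intercept column.  The variance ratio
    lambda = sigma_u^2 / sigma^2 is optimized on a bounded log grid plus a
    boundary check at lambda = 0 (so sigma_u^2 = 0 is an admissible fit and
    then beta equals OLS).  Wald t statistics use n - p residual degrees of
    freedom (approximate).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("too few observations for the requested design")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise ValueError(
            f"singular fixed-effect design for response {response!r} "
            f"(rank {rank} < {p} columns: {fixed_names})"
        )
    blocks = _group_blocks(np.asarray(groups))
    if len(blocks) < 2:
        raise ValueError("need at least two groups for a random intercept")
    reml = method.upper() == "REML"

    # the profile score d(-2ll)/d lambda is >= 0 at the optimum boundary;
    # root-find it for full precision, falling back to lambda = 0 when the
    # likelihood is decreasing in lambda already at the origin
    if _score(0.0, y, x, blocks, reml) >= 0:
        lam_hat = 0.0
    else:
        hi = 1.0
        while _score(hi, y, x, blocks, reml) < 0 and hi < 1e8:
            hi *= 4.0
        if _score(hi, y, x, blocks, reml) < 0:
            lam_hat = hi  # effectively all variance between groups
        else:
            lam_hat = optimize.brentq(
                _score, 0.0, hi, args=(y, x, blocks, reml), xtol=1e-14, rtol=1e-15
            )

    beta, quad, _, xtwx = _profiled_quantities(y, x, blocks, lam_hat)
    dof = n - p
    sigma2_e = quad / (dof if reml else n)
    sigma2_u = lam_hat * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov_beta))
    t_values = beta / se
    p_values = 2 * stats.t.sf(np.abs(t_values), df=dof)
    ll_ml = -_neg_loglik(lam_hat, y, x, blocks, reml=False)
    ll_reml = -_neg_loglik(lam_hat, y, x, blocks, reml=True)
    k = p + 2
    return LmmFit(
        response=response,
        fixed_names=list(fixed_names),
        beta=beta,
        se=se,
        t_values=t_values,
        p_values=p_values,
        sigma2_u=sigma2_u,
        sigma2_e=sigma2_e,
        loglik_ml=ll_ml,
        loglik_reml=ll_reml,
        n=n,
        k=k,
        aicc=aicc(ll_ml, k, n),
        group_label=group_label,
        method=method.upper(),
    )


def aicc(log_likelihood_ml: float, k: int, n: int) -> float | None:
    """Small-sample corrected AIC; None (with the standard guard) when
    n <= k + 1 makes the correction undefined."""
    if n - k - 1 <= 0:
        return None
    return -2.0 * log_likelihood_ml + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class RankedModel:
    terms: tuple[str, ...]
    loglik_ml: float
    aicc: float
    delta_aicc: float = 0.0
    rank: int = 0
    fit: LmmFit | None = None


@dataclass
class ModelRanking:
    response: str
    models: list[RankedModel]
    delta_max: float

    @property
    def best(self) -> RankedModel:
        return self.models[0]

    def retained(self) -> list[RankedModel]:
        return [m for m in self.models if m.delta_aicc < self.delta_max]


def dredge(
    response: str,
    y: np.ndarray,
    predictors: dict[str, np.ndarray],
    groups: np.ndarray,
    delta_max: float = 5.0,
    max_terms: int = 12,
    force: bool = False,
) -> ModelRanking:
    """All-subsets fixed-effect selection by ML AICc.

    Fits all 2^m subsets of ``predictors`` (always with an intercept and the
    random intercept), ranks them by AICc ascending, and marks the retained
    set (delta AICc below ``delta_max``).  The intercept-only model is always
    among the candidates.  Refuses m > ``max_terms`` unless forced.
    """
    names = list(predictors)
    m = len(names)
    if m > max_terms and not force:
        raise ValueError(f"{m} candidate terms exceed the combinatorial guard ({max_terms})")
    y = np.asarray(y, dtype=float)
    n = len(y)
    models: list[RankedModel] = []
    for size in range(m + 1):
        for subset in itertools.combinations(names, size):
            cols = [np.ones(n)] + [np.asarray(predictors[t], dtype=float) for t in subset]
            x = np.column_stack(cols)
            try:
                fit = fit_lmm(response, y, x, ["(intercept)", *subset], groups, method="ML")
            except ValueError:
                continue
            if fit.aicc is None:
                continue
            models.append(
                RankedModel(terms=subset, loglik_ml=fit.loglik_ml, aicc=fit.aicc, fit=fit)
            )
    if not models:
        raise ValueError("no candidate model could be fitted")
    models.sort(key=lambda mdl: (mdl.aicc, -mdl.loglik_ml))
    best = models[0].aicc
    for r, mdl in enumerate(models, start=1):
        mdl.delta_aicc = mdl.aicc - best
        mdl.rank = r
    return ModelRanking(response=response, models=models, delta_max=delta_max)


# ---------------------------------------------------------------------------
# Recursive path models (observed variables only)


@dataclass
class PathEquation:
    response: str
    predictors: list[str]
    coefficients: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)


@dataclass
class PathModelFit:
    equations: list[PathEquation]
    roles: dict[str, str]  # exogenous | intermediate | response
    direct: dict[tuple[str, str], float]
    indirect: dict[tuple[str, str], float]
    total: dict[tuple[str, str], float]
    n: int


def _toposort(equations: list[tuple[str, list[str]]]) -> list[str]:
    edges = {(p, r) for r, preds in equations for p in preds}
    nodes = {v for e in edges for v in e}
    indeg = {v: 0 for v in nodes}
    for _, dst in edges:
        indeg[dst] += 1
    order = [v for v in sorted(nodes) if indeg[v] == 0]
    out: list[str] = []
    queue = list(order)
    while queue:
        v = queue.pop(0)
        out.append(v)
        for src, dst in sorted(edges):
            if src == v:
                indeg[dst] -= 1
                if indeg[dst] == 0:
                    queue.append(dst)
    if len(out) != len(nodes):
        raise ValueError("path model graph contains a cycle")
    return out


def fit_path_model(
    equations: list[tuple[str, list[str]]],
    data: dict[str, np.ndarray],
    standardize: bool = True,
) -> PathModelFit:
    """Estimate a recursive path model by per-equation least squares.

    Variables are z-standardized first (so coefficients are standardized
    path coefficients); for a just-identified recursive system with observed
    variables this coincides with ML/GLS covariance fitting.  Direct effects
    are the equation coefficients; indirect effects are sums of coefficient
    products over all directed paths; total = direct + indirect.
    """
    order = _toposort(equations)
    cols = {}
    n = None
    for name in order:
        v = np.asarray(data[name], dtype=float)
        if n is None:
            n = len(v)
        elif len(v) != n:
            raise ValueError("variables have unequal lengths")
        if np.any(np.isnan(v)):
            raise ValueError(f"variable {name!r} has missing values (complete cases only)")
        if standardize:
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"variable {name!r} is constant")
            v = (v - v.mean()) / sd
        cols[name] = v

    responses = {r for r, _ in equations}
    preds_of = {r: list(p) for r, p in equations}
    all_preds = {p for _, ps in equations for p in ps}
    roles = {}
    for v in order:
        if v in responses and v in all_preds:
            roles[v] = "intermediate"
        elif v in responses:
            roles[v] = "response"
        else:
            roles[v] = "exogenous"

    fitted: list[PathEquation] = []
    direct: dict[tuple[str, str], float] = {}
    for resp, preds in equations:
        if n < len(preds) + 2:
            raise ValueError(f"too few observations for equation {resp!r}")
        x = np.column_stack([cols[p] for p in preds])
        xi = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(xi, cols[resp], rcond=None)
        resid = cols[resp] - xi @ beta
        dof = n - xi.shape[1]
        sigma2 = resid @ resid / dof if dof > 0 else np.nan
        cov = sigma2 * np.linalg.inv(xi.T @ xi)
        se = np.sqrt(np.diag(cov))
        eq = PathEquation(response=resp, predictors=list(preds))
        for j, p_name in enumerate(preds, start=1):
            eq.coefficients[p_name] = float(beta[j])
            eq.se[p_name] = float(se[j])
            eq.p_values[p_name] = float(
                2 * stats.t.sf(abs(beta[j] / se[j]), df=dof)
            ) if dof > 0 else float("nan")
            direct[(p_name, resp)] = float(beta[j])
        fitted.append(eq)

    # effect decomposition by path tracing over the directed graph
    def paths_from(src: str, dst: str, prefix: tuple[str, ...]) -> list[float]:
        out = []
        for (a, b), coef in direct.items():
            if a == src:
                if b == dst:
                    out.append(coef)
                elif b not in prefix:
                    out.extend(coef * w for w in paths_from(b, dst, prefix + (b,)))
        return out

    indirect: dict[tuple[str, str], float] = {}
    total: dict[tuple[str, str], float] = {}
    variables = list(cols)
    for src in variables:
        for dst in responses:
            if src == dst:
                continue
            all_paths = paths_from(src, dst, (src,))
            if not all_paths:
                continue
            d = direct.get((src, dst), 0.0)
            t = float(sum(all_paths))
            total[(src, dst)] = t
            if (src, dst) in direct:
                indirect[(src, dst)] = t - d
            else:
                indirect[(src, dst)] = t
    return PathModelFit(
        equations=fitted, roles=roles, direct=direct, indirect=indirect,
        total=total, n=n,
    )
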