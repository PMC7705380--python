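"""Bivariate Cholesky decomposition twin models fitted by FIML.

Partitions the variance of two residualized traits, and their covariance,
into additive genetic (A), shared environmental (C), twin-specific shared
environmental (Tw) and non-shared environmental (E) sources using MZ twin,
DZ twin and non-twin full-sibling pairs.  Each source contributes a 2x2
lower-triangular loading matrix; the model-implied covariance of the pair
4-vector (trait1_sib1, trait2_sib1, trait1_sib2, trait2_sib2) combines the
within-person blocks with cross-sibling blocks scaled by the sharing
coefficients: genetic correlation 1 (MZ) or 0.5 (DZ and siblings),
twin-specific environment correlation 1 (MZ, DZ) or 0 (siblings), shared
environment always fully shared within a family, non-shared environment
never shared.

Fitting maximizes the full-information multivariate-normal likelihood.
Because every complete pair in a zygosity group shares one expected mean
and covariance, the -2 log-likelihood is evaluated from per-group
sufficient statistics (count, sum, scatter), which makes simulation
studies with many refits cheap without changing the objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import GENETIC_SHARING, PAIR_TYPES, TWIN_ENV_SHARING, CholeskyParams

logger = logging.getLogger(__name__)

__all__ = [
    "CholeskyParams",
    "expected_covariance",
    "PairSummary",
    "summarize_pairs",
    "fiml_minus2ll",
    "TwinFit",
    "fit_model",
    "assumption_tests",
    "compare_models",
    "standardize",
    "Decomposition",
    "decompose",
]

_SOURCE_KEYS = {"A": "a", "C": "c", "Tw": "t", "E": "e"}
_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# model-implied covariance

def expected_covariance(params: CholeskyParams, pair_type: str) -> np.ndarray:
    """Model-implied 4x4 covariance of a sibling pair's trait vector."""
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"unknown pair_type {pair_type!r}; expected one of {PAIR_TYPES}")
    r_a = GENETIC_SHARING[pair_type]
    r_t = TWIN_ENV_SHARING[pair_type]
    covs = {s: params.lam(s) @ params.lam(s).T for s in ("a", "c", "t", "e")}
    within = covs["a"] + covs["c"] + covs["t"] + covs["e"]
    cross = r_a * covs["a"] + covs["c"] + r_t * covs["t"]
    sigma = np.empty((4, 4))
    sigma[:2, :2] = within
    sigma[2:, 2:] = within
    sigma[:2, 2:] = cross
    sigma[2:, :2] = cross.T
    return sigma


# ---------------------------------------------------------------------------
# FIML objective via per-group sufficient statistics

@dataclass
class PairSummary:
    """Sufficient statistics of complete pair 4-vectors, per pair type."""

    n: dict[str, int]
    mean: dict[str, np.ndarray]
    scatter: dict[str, np.ndarray]  # sum of x x^T over pairs
    n_dropped: int = 0

    @property
    def n_total(self) -> int:
        return sum(self.n.values())


_PAIR_COLS = ["sib1_trait1", "sib1_trait2", "sib2_trait1", "sib2_trait2"]


def summarize_pairs(pair_table: pd.DataFrame) -> PairSummary:
    """Collapse a pair table to per-group sufficient statistics.

    Pairs with any missing trait value are dropped with a logged count
    (complete-case 4-vectors).
    """
    complete = pair_table.dropna(subset=_PAIR_COLS)
    n_dropped = len(pair_table) - len(complete)
    if n_dropped:
        logger.info("summarize_pairs: dropped %d incomplete pairs", n_dropped)
    n, mean, scatter = {}, {}, {}
    for ptype, grp in complete.groupby("pair_type"):
        if ptype not in PAIR_TYPES:
            raise ValueError(f"unknown pair_type {ptype!r} in pair table")
        x = grp[_PAIR_COLS].to_numpy(dtype=float)
        n[ptype] = len(x)
        mean[ptype] = x.mean(axis=0)
        scatter[ptype] = x.T @ x
    return PairSummary(n=n, mean=mean, scatter=scatter, n_dropped=n_dropped)


def _group_m2ll(n: int, mean: np.ndarray, scatter: np.ndarray,
                mu: np.ndarray, sigma: np.ndarray) -> float:
    """-2 log MVN likelihood of one group from its sufficient statistics."""
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    # sum_i (x_i - mu)' Sigma^-1 (x_i - mu) = tr(Sigma^-1 M)
    m = scatter - n * (np.outer(mean, mu) + np.outer(mu, mean)) + n * np.outer(mu, mu)
    siginv_m = np.linalg.solve(sigma, m)
    return n * (4.0 * _LOG2PI + logdet) + float(np.trace(siginv_m))


def fiml_minus2ll(params: CholeskyParams, means: np.ndarray,
                  pairs: PairSummary | pd.DataFrame) -> float:
    """FIML -2 log-likelihood of the structural model over all pair groups.

    ``means`` is the per-trait mean pair (m1, m2), equal across siblings
    and zygosity groups.  Non-positive-definite expected covariances give
    +inf (treated as infeasible by the optimizer).
    """
    if isinstance(pairs, pd.DataFrame):
        pairs = summarize_pairs(pairs)
    m1, m2 = float(means[0]), float(means[1])
    mu = np.array([m1, m2, m1, m2])
    total = 0.0
    for ptype, n in pairs.n.items():
        sigma = expected_covariance(params, ptype)
        total += _group_m2ll(n, pairs.mean[ptype], pairs.scatter[ptype], mu, sigma)
        if not np.isfinite(total):
            logger.debug("non-positive-definite covariance for %s", ptype)
            return np.inf
    return total


# ---------------------------------------------------------------------------
# fast likelihood path
#
# Every model here implies a pair covariance [[W, B], [B, W]] with symmetric
# blocks, which the sibling sum/difference transform u = (x_s1 + x_s2)/sqrt2,
# v = (x_s1 - x_s2)/sqrt2 block-diagonalizes into Cov(u) = W + B and
# Cov(v) = W - B with E[v] = 0.  Evaluating the likelihood on transformed
# per-group sufficient statistics turns each evaluation into two 2x2
# determinants, which keeps multi-start fits and replicate studies cheap.
# The algebra is exact; tests assert agreement with fiml_minus2ll.

_T_SUMDIFF = np.sqrt(0.5) * np.array(
    [[1.0, 0.0, 1.0, 0.0],
     [0.0, 1.0, 0.0, 1.0],
     [1.0, 0.0, -1.0, 0.0],
     [0.0, 1.0, 0.0, -1.0]]
)


def _fast_group_stats(summary: PairSummary) -> list[tuple]:
    """Per-group (n, ubar, Su, Sv, r_a, r_t) in sum/difference coordinates."""
    out = []
    for ptype, n in summary.n.items():
        m_t = _T_SUMDIFF @ summary.mean[ptype]
        s_t = _T_SUMDIFF @ summary.scatter[ptype] @ _T_SUMDIFF.T
        out.append((n, m_t[:2], s_t[:2, :2], s_t[2:, 2:],
                    GENETIC_SHARING[ptype], TWIN_ENV_SHARING[ptype]))
    return out


def _m2ll_2x2(n: int, sigma: np.ndarray, m: np.ndarray) -> float:
    """n*log|sigma| + tr(sigma^-1 m) for a 2x2 sigma, or +inf if not PD."""
    a, b, c, d = sigma[0, 0], sigma[0, 1], sigma[1, 0], sigma[1, 1]
    det = a * d - b * c
    if det <= 0.0 or a <= 0.0:
        return np.inf
    tr = (d * m[0, 0] - b * m[1, 0] - c * m[0, 1] + a * m[1, 1]) / det
    return n * float(np.log(det)) + float(tr)


def _fast_m2ll(groups: list[tuple], within: np.ndarray, crosses: list[np.ndarray],
               mu2: np.ndarray) -> float:
    mu_u = np.sqrt(2.0) * mu2
    total = 0.0
    for (n, ubar, su, sv, _r_a, _r_t), cross in zip(groups, crosses):
        mu_ = np.outer(ubar, mu_u)
        m_u = su - n * (mu_ + mu_.T) + n * np.outer(mu_u, mu_u)
        val = (n * 4.0 * _LOG2PI
               + _m2ll_2x2(n, within + cross, m_u)
               + _m2ll_2x2(n, within - cross, sv))
        if not np.isfinite(val):
            return np.inf
        total += val
    return total


def _make_objective(summary: PairSummary, sources: tuple[str, ...],
                    estimate_means: bool):
    groups = _fast_group_stats(summary)
    keys = [_SOURCE_KEYS[s] for s in sources]
    zeros2 = np.zeros(2)

    def objective(theta: np.ndarray) -> float:
        within = np.zeros((2, 2))
        per_group_cross = [np.zeros((2, 2)) for _ in groups]
        i = 0
        for key in keys:
            lam = np.array([[theta[i], 0.0], [theta[i + 1], theta[i + 2]]])
            cov = lam @ lam.T
            within += cov
            for gi, (g, _c) in enumerate(zip(groups, per_group_cross)):
                coef = {"a": g[4], "c": 1.0, "t": g[5], "e": 0.0}[key]
                if coef:
                    per_group_cross[gi] = per_group_cross[gi] + coef * cov
            i += 3
        mu2 = theta[i : i + 2] if estimate_means else zeros2
        return _fast_m2ll(groups, within, per_group_cross, mu2)

    return objective


# ---------------------------------------------------------------------------
# structural model fitting

@dataclass
class TwinFit:
    """A fitted twin model: estimates, fit indices and curvature."""

    model_name: str
    sources: tuple[str, ...]
    estimates: CholeskyParams | None
    means: np.ndarray
    minus2ll: float
    n_free: int
    aic: float
    n_pairs: int
    converged: bool
    grad_norm: float
    param_names: list[str] = field(default_factory=list)
    param_vector: np.ndarray | None = None
    param_cov: np.ndarray | None = None  # from observed information; None if singular

    @property
    def df(self) -> int:
        """Free-parameter count (AIC penalty term)."""
        return self.n_free


def _unpack(theta: np.ndarray, sources: tuple[str, ...],
            estimate_means: bool) -> tuple[CholeskyParams, np.ndarray]:
    kw = {}
    i = 0
    for s in sources:
        key = _SOURCE_KEYS[s]
        kw[f"{key}11"], kw[f"{key}21"], kw[f"{key}22"] = theta[i], theta[i + 1], theta[i + 2]
        i += 3
    means = theta[i : i + 2] if estimate_means else np.zeros(2)
    # the implied covariance is invariant to flipping the sign of a latent
    # factor (negating one loading column), so fold wandering signs onto
    # the canonical representative with non-negative diagonals
    for s in sources:
        key = _SOURCE_KEYS[s]
        if kw[f"{key}11"] < 0:
            kw[f"{key}11"] = -kw[f"{key}11"]
            kw[f"{key}21"] = -kw[f"{key}21"]
        if kw[f"{key}22"] < 0:
            kw[f"{key}22"] = -kw[f"{key}22"]
    kw["e11"] = max(kw.get("e11", 1.0), 1e-10)
    kw["e22"] = max(kw.get("e22", 1.0), 1e-10)
    return CholeskyParams(**kw), np.asarray(means, dtype=float)


def _param_names(sources: tuple[str, ...], estimate_means: bool) -> list[str]:
    names = []
    for s in sources:
        k = _SOURCE_KEYS[s]
        names += [f"{k}11", f"{k}21", f"{k}22"]
    if estimate_means:
        names += ["mean1", "mean2"]
    return names


def _moment_start(summary: PairSummary, sources: tuple[str, ...],
                  estimate_means: bool) -> np.ndarray:
    """Method-of-moments starting values.

    Splits the pooled within-person covariance across the active sources,
    using twice the MZ-minus-sibling cross-covariance contrast as the
    genetic share when both groups are present.
    """
    n_tot = summary.n_total
    within = np.zeros((2, 2))
    mean12 = np.zeros(2)
    for ptype, n in summary.n.items():
        mu = summary.mean[ptype]
        s = summary.scatter[ptype] / n - np.outer(mu, mu)
        within += n * 0.5 * (s[:2, :2] + s[2:, 2:])
        mean12 += n * 0.5 * (mu[:2] + mu[2:])
    within /= n_tot
    mean12 /= n_tot

    shares = {}
    if "A" in sources:
        cross = {}
        for ptype, n in summary.n.items():
            mu = summary.mean[ptype]
            s = summary.scatter[ptype] / n - np.outer(mu, mu)
            cross[ptype] = 0.5 * (s[:2, 2:] + s[2:, :2].T)
        if "MZ" in cross and ("DZ" in cross or "NotTwin" in cross):
            other = cross.get("DZ", cross.get("NotTwin"))
            a_cov = 2.0 * (cross["MZ"] - other)
        else:
            a_cov = 0.4 * within
        shares["A"] = _nearest_psd(0.5 * (a_cov + a_cov.T))
    for s in sources:
        if s in ("A", "E"):
            continue
        shares[s] = 0.08 * within
    taken = sum(shares.values()) if shares else np.zeros((2, 2))
    e_cov = within - taken
    shares["E"] = _nearest_psd(e_cov, floor=0.05 * np.trace(within) / 2.0)

    theta = []
    for s in sources:
        L = _psd_chol(shares[s])
        theta += [L[0, 0], L[1, 0], L[1, 1]]
    if estimate_means:
        theta += list(mean12)
    return np.asarray(theta, dtype=float)


def _nearest_psd(m: np.ndarray, floor: float = 0.0) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    return v @ np.diag(np.clip(w, floor, None)) @ v.T


def _psd_chol(m: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(m + 1e-10 * np.eye(2))
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(_nearest_psd(m) + 1e-8 * np.eye(2))


def _num_grad(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        step = h * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (f(xp) - f(xm)) / (2.0 * step)
    return g


def _num_hess(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    hess = np.zeros((k, k))
    steps = h * (1.0 + np.abs(x))
    f0 = f(x)
    fp = np.zeros(k)
    fm = np.zeros(k)
    for i in range(k):
        xp, xm = x.copy(), x.copy()
        xp[i] += steps[i]
        xm[i] -= steps[i]
        fp[i], fm[i] = f(xp), f(xm)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / steps[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            xpp = x.copy(); xpp[i] += steps[i]; xpp[j] += steps[j]
            xmm = x.copy(); xmm[i] -= steps[i]; xmm[j] -= steps[j]
            hess[i, j] = hess[j, i] = (
                f(xpp) - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + f(xmm)
            ) / (2.0 * steps[i] * steps[j])
    return hess


def fit_model(
    pairs: pd.DataFrame | PairSummary,
    sources: tuple[str, ...] = ("A", "C", "Tw", "E"),
    estimate_means: bool = True,
    n_starts: int = 5,
    seed: int = 0,
    compute_cov: bool = True,
) -> TwinFit:
    """Fit a bivariate Cholesky twin model by FIML.

    ``sources`` selects the active variance components; E is mandatory for
    identifiability.  Means are, by default, estimated as per-trait
    constants equal across siblings and zygosity groups (phenotypes enter
    pre-residualized, so they sit near zero).  Optimization runs a seeded
    multi-start: a method-of-moments start plus perturbed copies, each
    polished by Nelder-Mead then BFGS; the best incumbent is returned.
    """
    sources = tuple(sources)
    for s in sources:
        if s not in _SOURCE_KEYS:
            raise ValueError(f"unknown source {s!r}")
    if "E" not in sources:
        raise ValueError("E must be an active source (identifiability)")
    summary = summarize_pairs(pairs) if isinstance(pairs, pd.DataFrame) else pairs
    if len([s for s in sources if s != "E"]) and len(summary.n) < 2:
        logger.warning("fewer than 2 pair types present; A/C/Tw are weakly identified")

    objective = _make_objective(summary, sources, estimate_means)

    rng = np.random.default_rng(seed)
    theta0 = _moment_start(summary, sources, estimate_means)
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(theta0 * (1.0 + 0.3 * rng.standard_normal(theta0.shape))
                      + 0.05 * rng.standard_normal(theta0.shape))

    best = None
    for s0 in starts:
        if not np.isfinite(objective(s0)):
            s0 = s0 * 0.5 + 0.1
        try:
            nm = optimize.minimize(objective, s0, method="Nelder-Mead",
                                   options={"maxiter": 800, "xatol": 1e-6, "fatol": 1e-8})
            bf = optimize.minimize(objective, nm.x, method="BFGS",
                                   options={"gtol": 1e-7, "maxiter": 500})
            cand = bf if bf.fun <= nm.fun else nm
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            logger.warning("optimization start failed: %s", exc)
            continue
        if best is None or cand.fun < best.fun:
            best = cand
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("twin-model optimization failed on every start")

    grad = _num_grad(objective, best.x)
    grad_norm = float(np.max(np.abs(grad)))
    converged = grad_norm < 1e-2  # loose: boundary solutions have one-sided gradients
    est, means = _unpack(best.x, sources, estimate_means)
    # canonical theta: re-pack so diagonals are the non-negative representatives
    theta_hat = np.array([getattr(est, nm) for nm in _param_names(sources, False)]
                         + (list(means) if estimate_means else []))
    n_free = len(theta_hat)
    m2ll = float(best.fun)

    cov = None
    if compute_cov:
        hess = _num_hess(objective, theta_hat)
        try:
            cov = 2.0 * np.linalg.inv(0.5 * (hess + hess.T))
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
                cov = None
        except np.linalg.LinAlgError:
            cov = None
        if cov is None:
            logger.warning("observed information not invertible; SEs unavailable")

    return TwinFit(
        model_name="".join(sources),
        sources=sources,
        estimates=est,
        means=means,
        minus2ll=m2ll,
        n_free=n_free,
        aic=m2ll + 2.0 * n_free,
        n_pairs=summary.n_total,
        converged=converged,
        grad_norm=grad_norm,
        param_names=_param_names(sources, estimate_means),
        param_vector=theta_hat,
        param_cov=cov,
    )


# ---------------------------------------------------------------------------
# saturated models and assumption tests

def _sym_pair(mu: np.ndarray, sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average a mean/covariance over the sibling-swap permutation."""
    perm = [2, 3, 0, 1]
    p_mu = mu[perm]
    p_sigma = sigma[np.ix_(perm, perm)]
    return 0.5 * (mu + p_mu), 0.5 * (sigma + p_sigma)


def _saturated_group(n: int, mean: np.ndarray, scatter: np.ndarray) -> float:
    """-2LL of the free-mean, free-covariance MLE for one group."""
    sigma = scatter / n - np.outer(mean, mean)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("singular saturated group covariance")
    return n * (4.0 * _LOG2PI + logdet + 4.0)


def _eq_order_group(n: int, mean: np.ndarray, scatter: np.ndarray) -> float:
    """-2LL of the sibling-exchangeable MLE for one group (closed form).

    The exchangeable model is invariant under the sib-swap permutation, so
    its MLE is the swap-symmetrized sample mean and covariance (the
    symmetrized statistics lie inside the model and maximize the
    likelihood over it).
    """
    ml_cov = scatter / n - np.outer(mean, mean)
    mu_s, _ = _sym_pair(mean, ml_cov)
    # covariance about the symmetrized mean, then symmetrized
    cov_about = ml_cov + np.outer(mean - mu_s, mean - mu_s)
    _, sig_s = _sym_pair(mean, cov_about)
    m = scatter - n * (np.outer(mean, mu_s) + np.outer(mu_s, mean)) + n * np.outer(mu_s, mu_s)
    sign, logdet = np.linalg.slogdet(sig_s)
    if sign <= 0:
        raise ValueError("singular exchangeable group covariance")
    return n * (4.0 * _LOG2PI + logdet) + float(np.trace(np.linalg.solve(sig_s, m)))


def _eq_zygosity_m2ll(summary: PairSummary) -> tuple[float, int]:
    """MLE -2LL with means/variances/within-person covariance common across
    zygosity groups; cross-sibling covariances stay group-specific."""
    groups = sorted(summary.n)
    k = len(groups)
    sub = PairSummary(
        n={g: summary.n[g] for g in groups},
        mean={g: summary.mean[g] for g in groups},
        scatter={g: summary.scatter[g] for g in groups},
    )
    fast = _fast_group_stats(sub)

    def obj(theta):
        m1, m2, lv1, lv2, cw = theta[:5]
        within = np.array([[np.exp(lv1), cw], [cw, np.exp(lv2)]])
        crosses = []
        for gi in range(k):
            cc11, cc22, cc12 = theta[5 + 3 * gi : 8 + 3 * gi]
            crosses.append(np.array([[cc11, cc12], [cc12, cc22]]))
        return _fast_m2ll(fast, within, crosses, np.array([m1, m2]))

    # pooled starting values from symmetrized per-group stats
    n_tot = summary.n_total
    mu0 = np.zeros(2)
    v0 = np.zeros(2)
    cw0 = 0.0
    cc0 = []
    for g in groups:
        n, mu, sc = summary.n[g], summary.mean[g], summary.scatter[g]
        s = sc / n - np.outer(mu, mu)
        mu_s, s_s = _sym_pair(mu, s)
        mu0 += n * mu_s[:2]
        v0 += n * np.array([s_s[0, 0], s_s[1, 1]])
        cw0 += n * s_s[0, 1]
        cc0 += [s_s[0, 2], s_s[1, 3], s_s[0, 3]]
    mu0, v0, cw0 = mu0 / n_tot, v0 / n_tot, cw0 / n_tot
    theta0 = np.array([*mu0, np.log(v0[0]), np.log(v0[1]), cw0, *cc0])
    res = optimize.minimize(obj, theta0, method="Nelder-Mead",
                            options={"maxiter": 6000, "xatol": 1e-8, "fatol": 1e-9})
    res2 = optimize.minimize(obj, res.x, method="BFGS", options={"gtol": 1e-7})
    best = min(res.fun, res2.fun)
    return float(best), 5 + 3 * k


def assumption_tests(pairs: pd.DataFrame | PairSummary) -> pd.DataFrame:
    """Likelihood-ratio tests of twin-model equality assumptions.

    Fits (i) a saturated model (free means and covariances per pair type),
    (ii) a model exchangeable across sibling order within each type, and
    (iii) additionally equates means, variances and the within-person
    covariance across zygosity groups.  Returns one row per model with
    -2LL, free-parameter counts, and the LRT of each nesting step against
    the previous model.
    """
    summary = summarize_pairs(pairs) if isinstance(pairs, pd.DataFrame) else pairs
    if len(summary.n) < 2:
        raise ValueError("assumption tests need at least 2 zygosity groups")
    groups = sorted(summary.n)
    for g in groups:
        if summary.n[g] < 5:
            raise ValueError(f"group {g} has too few pairs for a saturated covariance")

    sat = sum(_saturated_group(summary.n[g], summary.mean[g], summary.scatter[g]) for g in groups)
    sat_free = 14 * len(groups)
    eqo = sum(_eq_order_group(summary.n[g], summary.mean[g], summary.scatter[g]) for g in groups)
    eqo_free = 8 * len(groups)
    eqz, eqz_free = _eq_zygosity_m2ll(summary)

    rows = []
    prev = None
    for name, m2ll, nf in [
        ("saturated", sat, sat_free),
        ("equal_across_twin_order", eqo, eqo_free),
        ("equal_across_zygosity", eqz, eqz_free),
    ]:
        row = {"model": name, "minus2ll": m2ll, "n_free": nf,
               "delta_m2ll": np.nan, "delta_df": np.nan, "p_value": np.nan}
        if prev is not None:
            d = max(m2ll - prev[0], 0.0)
            ddf = prev[1] - nf
            row.update(delta_m2ll=d, delta_df=ddf,
                       p_value=float(stats.chi2.sf(d, ddf)))
        rows.append(row)
        prev = (m2ll, nf)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model comparison, standardization, decomposition

def compare_models(parent: TwinFit, child: TwinFit, tol: float = 1e-4) -> dict:
    """Likelihood-ratio test and AIC comparison of nested twin models.

    The child must be nested in the parent (fewer free parameters).  When
    the dropped parameters are variance-component loadings on their zero
    boundary the naive chi-square p-value is conservative; ``boundary``
    flags that case.
    """
    if child.n_free > parent.n_free:
        raise ValueError("child model must have no more free parameters than the parent")
    delta = child.minus2ll - parent.minus2ll
    if delta < -tol * (1.0 + abs(parent.minus2ll)):
        raise RuntimeError(
            f"child -2LL ({child.minus2ll:.6f}) below parent ({parent.minus2ll:.6f}): "
            "optimizer failure in the parent fit"
        )
    delta = max(delta, 0.0)
    ddf = parent.n_free - child.n_free
    p = float(stats.chi2.sf(delta, ddf)) if ddf > 0 else 1.0
    dropped = set(parent.sources) - set(child.sources)
    return {
        "delta_m2ll": float(delta),
        "delta_df": ddf,
        "p": p,
        "aic_parent": parent.aic,
        "aic_child": child.aic,
        "preferred_by_aic": parent.model_name if parent.aic < child.aic else child.model_name,
        "boundary": bool(dropped),  # dropped variance sources sit on the 0 boundary
    }


def _standardized_vector(theta: np.ndarray, fit: TwinFit) -> np.ndarray:
    est, _ = _unpack(theta, fit.sources, "mean1" in fit.param_names)
    lams = [est.lam(_SOURCE_KEYS[s]) for s in fit.sources]
    var1 = sum(l[0, 0] ** 2 for l in lams)
    var2 = sum(l[1, 0] ** 2 + l[1, 1] ** 2 for l in lams)
    sd1, sd2 = np.sqrt(var1), np.sqrt(var2)
    out = []
    for s in fit.sources:
        l = est.lam(_SOURCE_KEYS[s])
        out += [l[0, 0] / sd1, l[1, 0] / sd2, l[1, 1] / sd2]
    return np.asarray(out)


def standardize(fit: TwinFit, alpha: float = 0.05) -> pd.DataFrame:
    """Standardized path coefficients with delta-method confidence intervals.

    Each loading is divided by the model-implied standard deviation of the
    trait it points to, so squared standardized paths sum to one per trait
    over the active sources.  CIs use the observed-information parameter
    covariance propagated through a numerical Jacobian; when that
    covariance is unavailable the interval columns are NaN.
    """
    if fit.estimates is None or fit.param_vector is None:
        raise ValueError("fit has no parameter vector")
    std = _standardized_vector(fit.param_vector, fit)
    names = [n for n in fit.param_names if not n.startswith("mean")]
    se = np.full(len(std), np.nan)
    if fit.param_cov is not None:
        jac = np.zeros((len(std), len(fit.param_vector)))
        h = 1e-6
        for j in range(len(fit.param_vector)):
            xp = fit.param_vector.copy()
            xm = fit.param_vector.copy()
            step = h * (1.0 + abs(xp[j]))
            xp[j] += step
            xm[j] -= step
            jac[:, j] = (_standardized_vector(xp, fit) - _standardized_vector(xm, fit)) / (2 * step)
        var = np.einsum("ij,jk,ik->i", jac, fit.param_cov, jac)
        se = np.sqrt(np.clip(var, 0.0, None))
    zc = stats.norm.isf(alpha / 2.0)
    return pd.DataFrame(
        {
            "path": names,
            "standardized": std,
            "se": se,
            "ci_low": std - zc * se,
            "ci_high": std + zc * se,
        }
    )


@dataclass
class Decomposition:
    """Per-source variance shares and correlation components."""

    variance_share_trait1: dict[str, float]
    variance_share_trait2: dict[str, float]
    covariance: dict[str, float]
    correlation_component: dict[str, float]
    total_correlation: float


def decompose(fit: TwinFit) -> Decomposition:
    """Partition trait variances and their correlation across sources.

    For a standardized model each source contributes ``x11**2`` to trait-1
    variance and ``x21**2 + x22**2`` to trait-2 variance; its covariance
    contribution is ``x11 * x21``, converted to a correlation component by
    dividing by the product of the two model-implied total standard
    deviations.  Shares sum to one per trait and correlation components
    sum to the model-implied phenotypic correlation exactly.
    """
    if fit.estimates is None:
        raise ValueError("fit has no estimates")
    est = fit.estimates
    var1 = {s: est.lam(_SOURCE_KEYS[s])[0, 0] ** 2 for s in fit.sources}
    var2 = {s: est.lam(_SOURCE_KEYS[s])[1, 0] ** 2 + est.lam(_SOURCE_KEYS[s])[1, 1] ** 2
            for s in fit.sources}
    cov = {s: est.lam(_SOURCE_KEYS[s])[0, 0] * est.lam(_SOURCE_KEYS[s])[1, 0]
           for s in fit.sources}
    tot1, tot2 = sum(var1.values()), sum(var2.values())
    if tot1 <= 0 or tot2 <= 0:
        raise ValueError("zero total variance for a trait")
    denom = np.sqrt(tot1) * np.sqrt(tot2)
    corr = {s: cov[s] / denom for s in fit.sources}
    return Decomposition(
        variance_share_trait1={s: var1[s] / tot1 for s in fit.sources},
        variance_share_trait2={s: var2[s] / tot2 for s in fit.sources},
        covariance=cov,
        correlation_component=corr,
        total_correlation=float(sum(corr.values())),
    )
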