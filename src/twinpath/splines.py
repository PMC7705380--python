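"""Restricted cubic splines and family-clustered outcome regression.

Each brain outcome is regressed on demographic covariates and three
physical-fitness predictors (endurance, grip strength, BMI), with
restricted cubic splines on age and the fitness variables (3 knots at the
10th/50th/90th percentiles) and a compound-symmetry (exchangeable)
within-family covariance fitted by REML.  The exchangeable structure is
implemented as a family random intercept, which is equivalent whenever the
within-family correlation is non-negative.

For each predictor the result carries both the coefficient on the linear
spline column (with its SE and z) and a joint Wald chi-square over all of
the predictor's spline columns, mapped to a z-equivalent through the
upper-tail chi2 -> normal quantile transform; screening can consume either
scalar.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "rcs_basis",
    "default_knots",
    "ModelSpec",
    "PredictorStats",
    "RegressionResult",
    "fit_clustered_outcome",
    "marginal_curve",
]


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis, truncated-power construction.

    For k knots the expansion has k-1 columns: the identity ``x`` followed
    by k-2 restricted cubic terms that are linear beyond the boundary
    knots (Harrell's normalization, dividing by ``(t_k - t_1)**2``).  The
    resulting function space is continuous with continuous first and
    second derivatives and exactly linear outside ``[t_1, t_k]``.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing (no duplicates)")
    t = knots
    k = len(t)
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    plus3 = lambda u: np.clip(u, 0.0, None) ** 3
    for j in range(k - 2):
        term = (
            plus3(x - t[j])
            - plus3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + plus3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


def default_knots(x, percentiles=(10.0, 50.0, 90.0)):
    """Knot locations at the 10th/50th/90th empirical percentiles.

    Uses linear-interpolation ("type 7") percentiles.  Returns ``None``
    with a logged warning when x has too few distinct values to place
    strictly increasing knots (the caller then falls back to a linear
    term).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(np.unique(x)) < 10:
        logger.warning("fewer than 10 distinct values; falling back to linear term")
        return None
    knots = np.percentile(x, percentiles)
    if np.any(np.diff(knots) <= 0):
        logger.warning("degenerate percentile knots %s; falling back to linear term", knots)
        return None
    return tuple(knots)


@dataclass(frozen=True)
class ModelSpec:
    """Right-hand side of the screening regression.

    ``spline_terms`` enter through a 3-knot restricted cubic spline,
    ``linear_terms`` as single numeric columns, ``categorical_terms`` as
    reference-coded indicators.  ``predictors`` names the fitness terms
    whose Wald statistics are reported (all must appear in one of the term
    lists); everything is entered simultaneously and retained regardless
    of significance.
    """

    spline_terms: tuple[str, ...] = ("age", "endurance", "grip", "bmi")
    linear_terms: tuple[str, ...] = ("gait_speed", "icv", "education", "income")
    categorical_terms: tuple[str, ...] = ("sex", "race")
    predictors: tuple[str, ...] = ("endurance", "grip", "bmi")

    def all_terms(self) -> tuple[str, ...]:
        return self.spline_terms + self.linear_terms + self.categorical_terms


def _build_design(
    table: pd.DataFrame,
    spec: ModelSpec,
    knots: dict[str, tuple | None] | None = None,
    levels: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple | None], dict[str, list[str]], dict[str, list[str]]]:
    """Design matrix, fitted knots, term -> column map, categorical levels."""
    if knots is None:
        knots = {}
        for name in spec.spline_terms:
            knots[name] = default_knots(table[name].to_numpy())
    if levels is None:
        levels = {
            name: sorted(pd.unique(table[name].astype(str)))
            for name in spec.categorical_terms
        }
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(table))}
    term_cols: dict[str, list[str]] = {}
    for name in spec.spline_terms:
        x = pd.to_numeric(table[name]).to_numpy(dtype=float)
        kn = knots.get(name)
        if kn is None:
            cols[name] = x
            term_cols[name] = [name]
        else:
            basis = rcs_basis(x, kn)
            names = [name] + [f"{name}_rcs{j}" for j in range(1, basis.shape[1])]
            for nm, col in zip(names, basis.T):
                cols[nm] = col
            term_cols[name] = names
    for name in spec.linear_terms:
        cols[name] = pd.to_numeric(table[name]).to_numpy(dtype=float)
        term_cols[name] = [name]
    for name in spec.categorical_terms:
        names = []
        for lev in levels[name][1:]:  # first level is the reference
            nm = f"{name}[{lev}]"
            cols[nm] = (table[name].astype(str) == lev).to_numpy(dtype=float)
            names.append(nm)
        term_cols[name] = names
    return pd.DataFrame(cols, index=table.index), knots, term_cols, levels


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pivoted QR flags which columns are linearly dependent on earlier ones
        _, _, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


@dataclass
class PredictorStats:
    """Wald statistics for one predictor's spline expansion."""

    linear_coef: float
    linear_se: float
    linear_z: float
    joint_chi2: float
    joint_df: int
    joint_z_equivalent: float


@dataclass
class RegressionResult:
    outcome_name: str
    predictors: dict[str, PredictorStats]
    residual_variance: float
    family_variance: float
    within_family_correlation: float
    n_obs: int
    n_families: int
    params: pd.Series = field(repr=False)
    cov_params: pd.DataFrame = field(repr=False)
    knots: dict[str, tuple | None] = field(repr=False)
    term_cols: dict[str, list[str]] = field(repr=False)
    levels: dict[str, list[str]] = field(repr=False)
    spec: ModelSpec = field(repr=False)
    reference_row: pd.DataFrame = field(repr=False)
    observed_range: dict[str, tuple[float, float]] = field(repr=False)
    reml_llf: float = np.nan

    def z_for(self, predictor: str, effect: str = "linear") -> float:
        ps = self.predictors[predictor]
        return ps.linear_z if effect == "linear" else ps.joint_z_equivalent


def _chi2_to_z(chi2_val: float, df: int) -> float:
    """Map a chi-square Wald statistic to the |z| with the same two-sided tail."""
    logp = stats.chi2.logsf(chi2_val, df)
    # z such that 2*(1 - Phi(z)) = p, computed in log space for tiny tails
    return float(stats.norm.isf(0.5 * np.exp(logp)))


def fit_clustered_outcome(
    table: pd.DataFrame,
    outcome_name: str,
    spec: ModelSpec | None = None,
) -> RegressionResult:
    """Fit one outcome's Gaussian model with exchangeable family clustering.

    REML estimation via a family random intercept; when every family has a
    single member the model reduces exactly to ordinary least squares with
    zero within-family correlation, and that path is used directly.
    """
    spec = spec or ModelSpec()
    if outcome_name not in table.columns:
        raise KeyError(f"outcome column {outcome_name!r} not in table")
    needed = list(spec.all_terms()) + [outcome_name, "family_id"]
    data = table.dropna(subset=[c for c in needed if c in table.columns])
    X, knots, term_cols, levels = _build_design(data, spec)
    _check_full_rank(X)
    y = pd.to_numeric(data[outcome_name]).to_numpy(dtype=float)
    groups = data["family_id"].to_numpy()
    n_fam = len(pd.unique(groups))

    # standardize non-intercept columns for conditioning (ICV and cubic
    # spline terms span ~10 orders of magnitude); mapped back below
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    centers["Intercept"] = 0.0
    scales[(scales == 0) | (X.columns == "Intercept")] = 1.0
    Xs = (X - centers) / scales

    if n_fam == len(data):
        ols = sm.OLS(y, Xs).fit()
        params_s, cov_s = ols.params, ols.cov_params()
        resid_var = float(ols.mse_resid)
        fam_var, icc, llf = 0.0, 0.0, float(ols.llf)
    else:
        mm = None
        last_exc: Exception | None = None
        for method in ("bfgs", "powell", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mm = sm.MixedLM(y, Xs, groups=groups).fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        if mm is None:
            raise RuntimeError(f"mixed-model fit failed for {outcome_name}: {last_exc}")
        params_s = mm.params[Xs.columns]
        cov_s = mm.cov_params().loc[Xs.columns, Xs.columns]
        resid_var = float(mm.scale)
        fam_var = float(mm.cov_re.iloc[0, 0])
        if fam_var + resid_var <= 0:
            raise ValueError("non-positive-definite covariance estimate")
        icc = fam_var / (fam_var + resid_var)
        llf = float(mm.llf)

    # back-transform: beta_j = beta_s_j / s_j; intercept absorbs the centers
    k = len(Xs.columns)
    A = np.zeros((k, k))
    i0 = list(Xs.columns).index("Intercept")
    for j, col in enumerate(Xs.columns):
        if j == i0:
            A[j, j] = 1.0
        else:
            A[j, j] = 1.0 / scales.iloc[j]
            A[i0, j] = -centers.iloc[j] / scales.iloc[j]
    params = pd.Series(A @ params_s.to_numpy(), index=Xs.columns)
    cov = pd.DataFrame(A @ cov_s.to_numpy() @ A.T, index=Xs.columns, columns=Xs.columns)

    pred_stats: dict[str, PredictorStats] = {}
    for pname in spec.predictors:
        cols = term_cols[pname]
        b = float(params[cols[0]])
        se = float(np.sqrt(cov.loc[cols[0], cols[0]]))
        bvec = params[cols].to_numpy()
        V = cov.loc[cols, cols].to_numpy()
        w = float(bvec @ np.linalg.solve(V, bvec))
        df = len(cols)
        pred_stats[pname] = PredictorStats(
            linear_coef=b,
            linear_se=se,
            linear_z=b / se,
            joint_chi2=w,
            joint_df=df,
            joint_z_equivalent=_chi2_to_z(w, df),
        )

    # reference row: continuous at median, categorical at mode
    ref = {}
    for name in spec.spline_terms + spec.linear_terms:
        ref[name] = float(pd.to_numeric(data[name]).median())
    for name in spec.categorical_terms:
        ref[name] = data[name].astype(str).mode().iloc[0]
    obs_range = {
        name: (float(pd.to_numeric(data[name]).min()), float(pd.to_numeric(data[name]).max()))
        for name in spec.spline_terms + spec.linear_terms
    }
    return RegressionResult(
        outcome_name=outcome_name,
        predictors=pred_stats,
        residual_variance=resid_var,
        family_variance=fam_var,
        within_family_correlation=icc,
        n_obs=len(data),
        n_families=n_fam,
        params=params,
        cov_params=cov,
        knots=knots,
        term_cols=term_cols,
        levels=levels,
        spec=spec,
        reference_row=pd.DataFrame([ref]),
        observed_range=obs_range,
        reml_llf=llf,
    )


def marginal_curve(
    fit: RegressionResult,
    predictor: str,
    grid,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted prediction curve over a predictor grid.

    All other predictors and covariates are held at reference values
    (continuous: median; categorical: mode); pointwise confidence
    intervals come from the delta method on the fixed-effect covariance.
    Grid points outside the observed predictor range are flagged as
    extrapolation with a logged warning.
    """
    grid = np.asarray(grid, dtype=float)
    if predictor not in fit.term_cols:
        raise KeyError(f"unknown predictor {predictor!r}")
    rows = pd.concat([fit.reference_row] * len(grid), ignore_index=True)
    rows[predictor] = grid
    X, _, _, _ = _build_design(rows, fit.spec, knots=fit.knots, levels=fit.levels)
    X = X[fit.params.index]
    pred = X.to_numpy() @ fit.params.to_numpy()
    var = np.einsum("ij,jk,ik->i", X.to_numpy(), fit.cov_params.to_numpy(), X.to_numpy())
    se = np.sqrt(np.clip(var, 0.0, None))
    zcrit = stats.norm.isf(alpha / 2.0)
    lo_obs, hi_obs = fit.observed_range[predictor]
    extrap = (grid < lo_obs) | (grid > hi_obs)
    if extrap.any():
        logger.warning(
            "%d of %d grid points for %s lie outside the observed range [%g, %g]",
            int(extrap.sum()), len(grid), predictor, lo_obs, hi_obs,
        )
    return pd.DataFrame(
        {
            "grid": grid,
            "predicted": pred,
            "ci_low": pred - zcrit * se,
            "ci_high": pred + zcrit * se,
            "extrapolated": extrap,
        }
    )
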