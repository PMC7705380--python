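"""Correlation-aware multiple-testing correction and screening.

Brain outcomes within a domain (e.g. white-matter FA tracts) are strongly
inter-correlated, so a raw Bonferroni count overcorrects.  The effective
number of independent tests is estimated from the eigenvalue spectrum of
the outcomes' correlation matrix; the family-wise alpha (0.05) is then
split equally across outcome domains and fitness predictors and divided by
the domain's effective test count, and the corrected two-sided alpha is
converted to a standard-normal |z| screening threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "effective_tests",
    "corrected_alpha",
    "z_threshold",
    "ThresholdSet",
    "make_thresholds",
    "screen",
]


def _check_correlation(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(0.5 * (corr + corr.T))
    if lam.min() < -1e-8:
        raise ValueError(f"correlation matrix not positive semi-definite (min eigenvalue {lam.min():.3g})")
    return np.clip(lam, 0.0, None)


def effective_tests(corr, method: str = "eigen_variance") -> float:
    """Effective number of independent tests among correlated outcomes.

    ``eigen_variance`` (default): ``m_eff = 1 + (M-1) * (1 - Var(lambda)/M)``
    with the eigenvalue variance using denominator M-1.  Yields M for
    independent outcomes, 1 for perfectly redundant ones, and non-integer
    values in between.  ``integer_partial``: sums, over eigenvalues,
    an indicator of lambda >= 1 plus the fractional part of lambda.
    """
    lam = _check_correlation(corr)
    m = len(lam)
    if m == 1:
        return 1.0
    if method == "eigen_variance":
        return float(1.0 + (m - 1) * (1.0 - np.var(lam, ddof=1) / m))
    if method == "integer_partial":
        # guard the floor against eigenvalues a rounding error below an integer
        lam = np.round(lam, 9)
        return float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))
    raise ValueError(f"unknown method {method!r}")


def corrected_alpha(
    m_eff: float,
    n_domains: int = 4,
    n_predictors: int = 3,
    family_alpha: float = 0.05,
) -> float:
    """Per-test alpha: family alpha split over domains, predictors and m_eff."""
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    return family_alpha / (n_domains * n_predictors * m_eff)


def z_threshold(alpha: float) -> float:
    """Two-sided |z| threshold for a given alpha: Phi^-1(1 - alpha/2)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.norm.isf(alpha / 2.0))


@dataclass(frozen=True)
class ThresholdSet:
    """Screening threshold for one outcome domain."""

    domain_name: str
    m_outcomes: int
    m_eff: float
    alpha_corrected: float
    z_threshold: float


def make_thresholds(
    table: pd.DataFrame,
    domains: dict[str, list[str]],
    method: str = "eigen_variance",
    n_predictors: int = 3,
    family_alpha: float = 0.05,
) -> dict[str, ThresholdSet]:
    """Per-domain thresholds from a cohort table's raw outcome columns.

    ``domains`` maps a domain name to its outcome column names; the number
    of domains used in the alpha allocation is ``len(domains)``.
    """
    out: dict[str, ThresholdSet] = {}
    for name, cols in domains.items():
        sub = table[list(cols)].dropna()
        if len(cols) == 1:
            meff = 1.0
        else:
            corr = np.corrcoef(sub.to_numpy(dtype=float), rowvar=False)
            meff = effective_tests(corr, method=method)
        alpha = corrected_alpha(meff, n_domains=len(domains),
                                n_predictors=n_predictors, family_alpha=family_alpha)
        out[name] = ThresholdSet(name, len(cols), meff, alpha, z_threshold(alpha))
    return out


def screen(
    results,
    thresholds: dict[str, ThresholdSet],
    outcome_domains: dict[str, str],
    effect: str = "linear",
) -> pd.DataFrame:
    """Significant (outcome, predictor) pairs, sorted by |z| descending.

    ``results`` is an iterable of RegressionResult; each outcome must be
    assigned to exactly one domain in ``outcome_domains``.  Ties in |z| are
    broken by outcome then predictor name for deterministic output.
    """
    rows = []
    for res in results:
        if res.outcome_name not in outcome_domains:
            raise ValueError(f"outcome {res.outcome_name!r} has no domain assignment")
        dom = outcome_domains[res.outcome_name]
        thr = thresholds[dom]
        for pname, ps in res.predictors.items():
            z = res.z_for(pname, effect)
            if abs(z) > thr.z_threshold:
                rows.append(
                    {
                        "outcome": res.outcome_name,
                        "predictor": pname,
                        "domain": dom,
                        "z": z,
                        "abs_z": abs(z),
                        "effect": ps.linear_coef,
                        "se": ps.linear_se,
                        "z_threshold": thr.z_threshold,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["outcome", "predictor", "domain", "z", "abs_z",
                       "effect", "se", "z_threshold"],
    )
    return out.sort_values(
        ["abs_z", "outcome", "predictor"], ascending=[False, True, True]
    ).reset_index(drop=True)
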