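"""Covariate residualization and sibling-pair assembly.

Before twin modelling, each trait is residualized on age (3-knot restricted
cubic spline), sex, race, education, income, and the age-by-sex interaction
with ordinary least squares, one model per trait over all individuals
entering the twin analyses.  Pairs are then assembled per family: MZ and DZ
twin pairs as recorded, and non-twin full-sibling pairs with an age gap
under 5 years (pairs at or above the gap are excluded).  In families
offering more than one eligible non-twin pair, the pair with the smallest
age gap is kept by default (ties go to the older pair), one pair per
family; a flag allows all disjoint pairs instead.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import default_knots, rcs_basis

logger = logging.getLogger(__name__)

__all__ = ["ResidualSpec", "residualize", "build_pairs", "pair_counts"]


@dataclass(frozen=True)
class ResidualSpec:
    """Covariate model for pre-twin-model residualization."""

    age: str = "age"
    sex: str = "sex"
    categorical: tuple[str, ...] = ("race",)
    ordinal: tuple[str, ...] = ("education", "income")
    age_spline: bool = True
    age_sex_interaction: bool = True


def _residual_design(table: pd.DataFrame, spec: ResidualSpec) -> np.ndarray:
    age = pd.to_numeric(table[spec.age]).to_numpy(dtype=float)
    sex = pd.to_numeric(table[spec.sex]).to_numpy(dtype=float)
    cols = [np.ones(len(table))]
    if spec.age_spline:
        kn = default_knots(age)
        cols.extend(rcs_basis(age, kn).T if kn is not None else [age])
    else:
        cols.append(age)
    cols.append(sex)
    if spec.age_sex_interaction:
        cols.append(age * sex)
    for name in spec.ordinal:
        cols.append(pd.to_numeric(table[name]).to_numpy(dtype=float))
    for name in spec.categorical:
        levels = sorted(pd.unique(table[name].astype(str)))
        for lev in levels[1:]:
            cols.append((table[name].astype(str) == lev).to_numpy(dtype=float))
    return np.column_stack(cols)


def residualize(
    table: pd.DataFrame,
    traits: list[str],
    spec: ResidualSpec | None = None,
) -> pd.DataFrame:
    """Replace each trait column by its OLS residual from the covariate model.

    Rows with missing covariates or traits are dropped (listwise) with a
    logged count.  Residuals have mean zero by construction.
    """
    spec = spec or ResidualSpec()
    needed = [spec.age, spec.sex, *spec.ordinal, *spec.categorical, *traits]
    data = table.dropna(subset=[c for c in needed if c in table.columns]).copy()
    n_dropped = len(table) - len(data)
    if n_dropped:
        logger.info("residualize: dropped %d rows with missing values", n_dropped)
    X = _residual_design(data, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate design in residualization")
    Y = data[traits].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    data[traits] = Y - X @ beta
    return data


def _eligible_sib_pairs(fam: pd.DataFrame, max_age_gap: float) -> list[tuple]:
    """Candidate (sib_i, sib_j) index pairs with age gap under the cap."""
    out = []
    for i, j in itertools.combinations(range(len(fam)), 2):
        gap = abs(fam["age"].iloc[i] - fam["age"].iloc[j])
        if gap < max_age_gap:
            out.append((i, j, gap))
    return out


def _order_pair(fam: pd.DataFrame, i: int, j: int) -> tuple[int, int]:
    """Sibling 1 is the older; ties broken by individual id."""
    ai, aj = fam["age"].iloc[i], fam["age"].iloc[j]
    if ai > aj:
        return i, j
    if aj > ai:
        return j, i
    return (i, j) if fam["individual_id"].iloc[i] <= fam["individual_id"].iloc[j] else (j, i)


def build_pairs(
    table: pd.DataFrame,
    trait1: str,
    trait2: str,
    max_age_gap: float = 5.0,
    all_disjoint: bool = False,
) -> pd.DataFrame:
    """Assemble per-pair trait 4-vectors grouped by pair type.

    MZ and DZ rows are the recorded twin pairs (twin_order 1 and 2);
    non-twin pairs are formed within families among zygosity ``NotTwin``
    members subject to the age-gap filter.  Returns one row per pair with
    columns family_id, pair_type, sib1/sib2 traits and ages.  Each
    individual appears in at most one row.
    """
    missing_zyg = table["zygosity"].isna().sum()
    if missing_zyg:
        logger.info("build_pairs: excluded %d individuals with missing zygosity", missing_zyg)
    data = table.dropna(subset=["zygosity", trait1, trait2, "age"])

    rows = []
    for fam_id, fam in data.groupby("family_id", sort=True):
        fam = fam.reset_index(drop=True)
        # recorded twin pairs
        twins = fam[fam["zygosity"].isin(["MZ", "DZ"])]
        if len(twins) == 2 and set(pd.to_numeric(twins["twin_order"])) == {1, 2}:
            twins = twins.sort_values("twin_order")
            s1, s2 = twins.iloc[0], twins.iloc[1]
            rows.append(_pair_row(fam_id, s1["zygosity"], s1, s2, trait1, trait2))
        elif len(twins) > 0 and len(twins) != 2:
            logger.warning("family %s has an incomplete twin pair; skipped", fam_id)
        # non-twin full siblings
        sibs = fam[fam["zygosity"] == "NotTwin"].reset_index(drop=True)
        if len(sibs) < 2:
            continue
        cand = _eligible_sib_pairs(sibs, max_age_gap)
        if not cand:
            continue
        # smallest gap first; ties resolved toward the older pair, then ids
        def sort_key(c):
            i, j, gap = c
            return (gap, -(sibs["age"].iloc[i] + sibs["age"].iloc[j]),
                    sibs["individual_id"].iloc[i])
        cand.sort(key=sort_key)
        if all_disjoint:
            used: set[int] = set()
            for i, j, _gap in cand:
                if i in used or j in used:
                    continue
                used.update((i, j))
                a, b = _order_pair(sibs, i, j)
                rows.append(_pair_row(fam_id, "NotTwin", sibs.iloc[a], sibs.iloc[b], trait1, trait2))
        else:
            i, j, _gap = cand[0]
            a, b = _order_pair(sibs, i, j)
            rows.append(_pair_row(fam_id, "NotTwin", sibs.iloc[a], sibs.iloc[b], trait1, trait2))

    cols = ["family_id", "pair_type", "sib1_trait1", "sib1_trait2",
            "sib2_trait1", "sib2_trait2", "age_sib1", "age_sib2"]
    out = pd.DataFrame(rows, columns=cols)
    logger.info("build_pairs: %s", pair_counts(out))
    return out


def _pair_row(fam_id, pair_type, s1, s2, trait1, trait2) -> dict:
    return {
        "family_id": fam_id,
        "pair_type": pair_type,
        "sib1_trait1": float(s1[trait1]),
        "sib1_trait2": float(s1[trait2]),
        "sib2_trait1": float(s2[trait1]),
        "sib2_trait2": float(s2[trait2]),
        "age_sib1": float(s1["age"]),
        "age_sib2": float(s2["age"]),
    }


def pair_counts(pair_table: pd.DataFrame) -> dict[str, int]:
    """Pairs per type, all three types always present."""
    counts = pair_table["pair_type"].value_counts().to_dict()
    return {t: int(counts.get(t, 0)) for t in ("MZ", "DZ", "NotTwin")}
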