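import numpy as np
import pandas as pd
import pytest

from twinpath import CholeskyParams, SimConfig, generate_cohort
from twinpath.simulate import simulate_pairs

#: AE truth used throughout the recovery studies
AE_TRUTH = CholeskyParams(a11=0.8, a21=-0.3, a22=0.7, e11=0.6, e21=-0.1, e22=0.65)


def make_pair_table(params, n_mz, n_dz, n_sib, rng) -> pd.DataFrame:
    """Pair table drawn directly from the structural model (no covariates)."""
    rows = []
    fam = 0
    for ptype, n in (("MZ", n_mz), ("DZ", n_dz), ("NotTwin", n_sib)):
        x = simulate_pairs(ptype, params, n, rng)
        for r in x:
            fam += 1
            rows.append(
                {
                    "family_id": f"F{fam}",
                    "pair_type": ptype,
                    "sib1_trait1": r[0],
                    "sib1_trait2": r[1],
                    "sib2_trait1": r[2],
                    "sib2_trait2": r[3],
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def ae_pairs() -> pd.DataFrame:
    """500 pairs per type from the AE truth; shared across tests."""
    rng = np.random.default_rng(2024)
    return make_pair_table(AE_TRUTH, 500, 500, 500, rng)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Modest cohort with a planted BMI effect and extra correlated outcomes."""
    cfg = SimConfig(
        n_mz_pairs=60,
        n_dz_pairs=60,
        n_sib_pairs=120,
        n_singletons=60,
        loadings=AE_TRUTH,
        covariate_effects={"bmi": (-0.06, 0.0)},
        n_extra_outcomes=6,
        extra_outcome_rho=0.4,
        seed=11,
    )
    return generate_cohort(cfg)
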