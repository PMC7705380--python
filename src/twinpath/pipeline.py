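"""End-to-end orchestration: simulate/load -> regress -> threshold ->
screen -> pair -> twin-model -> decompose.

Mirrors the two-step analysis design: a screening step that regresses every
brain outcome on covariates and fitness predictors with family-clustered
errors and keeps (outcome, predictor) pairs whose |z| clears the
domain-specific multiplicity threshold, followed by bivariate Cholesky twin
modelling of each surviving outcome against its predictor.  A run is fully
described by a :class:`RunConfig` (optionally parsed from YAML) and is
reproducible: identical config and seed give identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cholesky, multiplicity, pairs, simulate, splines

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]

_DEFAULT_TWIN_MODELS = (("A", "C", "Tw", "E"), ("A", "E"))


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "runs/run"
    seed: int = 0
    input_csv: str | None = None
    sim: simulate.SimConfig | None = None
    domains: dict[str, list[str]] = field(default_factory=dict)
    predictors: tuple[str, ...] = ("endurance", "grip", "bmi")
    model_spec: splines.ModelSpec | None = None
    multiplicity_method: str = "eigen_variance"
    effect: str = "linear"  # which scalar screening consumes: linear | joint
    family_alpha: float = 0.05
    twin_models: tuple[tuple[str, ...], ...] = _DEFAULT_TWIN_MODELS
    twin_force: list[tuple[str, str]] | None = None  # explicit (outcome, predictor) list
    max_age_gap: float = 5.0

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for dom, cols in self.domains.items():
            for c in cols:
                if c in seen:
                    raise ValueError(
                        f"outcome {c!r} mapped to two domains: {seen[c]!r} and {dom!r}"
                    )
                seen[c] = dom
        if self.effect not in ("linear", "joint"):
            raise ValueError("effect must be 'linear' or 'joint'")
        if self.input_csv is None and self.sim is None:
            raise ValueError("either input_csv or a simulation config is required")

    @property
    def outcome_domains(self) -> dict[str, str]:
        return {c: dom for dom, cols in self.domains.items() for c in cols}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and d["sim"] is not None:
            sim = dict(d["sim"])
            if "loadings" in sim:
                sim["loadings"] = simulate.CholeskyParams(**sim["loadings"])
            if "covariate_effects" in sim:
                sim["covariate_effects"] = {
                    k: tuple(v) if isinstance(v, (list, tuple)) else v
                    for k, v in sim["covariate_effects"].items()
                }
            if "age_range" in sim:
                sim["age_range"] = tuple(sim["age_range"])
            d["sim"] = simulate.SimConfig(**sim)
        if "model_spec" in d and d["model_spec"] is not None:
            d["model_spec"] = splines.ModelSpec(
                **{k: tuple(v) for k, v in d["model_spec"].items()}
            )
        for key in ("predictors",):
            if key in d:
                d[key] = tuple(d[key])
        if "twin_models" in d:
            d["twin_models"] = tuple(tuple(m) for m in d["twin_models"])
        if "twin_force" in d and d["twin_force"] is not None:
            d["twin_force"] = [tuple(x) for x in d["twin_force"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_jsonable(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Emits ``cohort.csv`` (when simulated), ``thresholds.json``,
    ``regression.csv``, ``covariance_params.json``, ``screened.csv``,
    marginal-curve CSVs for each screened hit, per-hit ``pairs_*.csv`` and
    ``twin_*.json``, a tidy ``twin_summary.csv``, and ``manifest.json``.
    Per-outcome failures are logged, recorded in the manifest, and skipped
    rather than aborting the run.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failures: list[dict] = []

    # --- stage 1: cohort ---------------------------------------------------
    if config.input_csv is not None:
        table = simulate.read_cohort(config.input_csv)
    else:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        table = simulate.generate_cohort(sim)
        simulate.write_cohort(table, out / "cohort.csv", config=sim)
    outcomes = [c for cols in config.domains.values() for c in cols]
    missing = [c for c in outcomes if c not in table.columns]
    if missing:
        raise ValueError(f"domain outcomes missing from cohort table: {missing}")

    # --- stage 2: multiplicity thresholds ----------------------------------
    thresholds = multiplicity.make_thresholds(
        table, config.domains, method=config.multiplicity_method,
        n_predictors=len(config.predictors), family_alpha=config.family_alpha,
    )
    (out / "thresholds.json").write_text(
        json.dumps({k: dataclasses.asdict(v) for k, v in thresholds.items()}, indent=2)
    )

    # --- stage 3: clustered spline regressions -----------------------------
    spec = config.model_spec or splines.ModelSpec(predictors=config.predictors)
    results = []
    reg_rows = []
    cov_params = {}
    for name in outcomes:
        try:
            res = splines.fit_clustered_outcome(table, name, spec)
        except Exception as exc:
            logger.warning("regression for %s failed: %s", name, exc)
            failures.append({"stage": "regression", "outcome": name, "error": str(exc)})
            continue
        results.append(res)
        cov_params[name] = {
            "residual_variance": res.residual_variance,
            "family_variance": res.family_variance,
            "within_family_correlation": res.within_family_correlation,
            "n_obs": res.n_obs,
            "n_families": res.n_families,
        }
        for pname, ps in res.predictors.items():
            reg_rows.append(
                {
                    "outcome": name,
                    "predictor": pname,
                    "effect": ps.linear_coef,
                    "se": ps.linear_se,
                    "z": ps.linear_z,
                    "joint_chi2": ps.joint_chi2,
                    "joint_df": ps.joint_df,
                    "joint_z": ps.joint_z_equivalent,
                }
            )
    reg = pd.DataFrame(reg_rows)
    reg.to_csv(out / "regression.csv", index=False)
    (out / "covariance_params.json").write_text(json.dumps(cov_params, indent=2))

    # --- stage 4: screening -------------------------------------------------
    hits = multiplicity.screen(results, thresholds, config.outcome_domains,
                               effect=config.effect)
    hits.to_csv(out / "screened.csv", index=False)
    by_outcome = {r.outcome_name: r for r in results}
    for _, hit in hits.iterrows():
        res = by_outcome[hit["outcome"]]
        lo, hi = res.observed_range[hit["predictor"]]
        curve = splines.marginal_curve(res, hit["predictor"], np.linspace(lo, hi, 50))
        curve.to_csv(out / f"marginal_{hit['outcome']}_{hit['predictor']}.csv", index=False)

    # --- stage 5: pairs + twin models ---------------------------------------
    targets = (config.twin_force if config.twin_force is not None
               else list(hits[["outcome", "predictor"]].itertuples(index=False, name=None)))
    tidy_rows = []
    for outcome, predictor in targets:
        try:
            resid = pairs.residualize(table, [outcome, predictor])
            ptab = pairs.build_pairs(resid, outcome, predictor, max_age_gap=config.max_age_gap)
            ptab.to_csv(out / f"pairs_{outcome}_{predictor}.csv", index=False)
            (out / f"pairs_{outcome}_{predictor}_counts.json").write_text(
                json.dumps(pairs.pair_counts(ptab), indent=2)
            )
            summary = cholesky.summarize_pairs(ptab)
            assumptions = cholesky.assumption_tests(summary)
            fits = {}
            for sources in config.twin_models:
                fit = cholesky.fit_model(summary, sources=sources, seed=config.seed)
                fits[fit.model_name] = fit
            names = list(fits)
            comparisons = [
                {"parent": names[i], "child": names[i + 1],
                 **cholesky.compare_models(fits[names[i]], fits[names[i + 1]])}
                for i in range(len(names) - 1)
                if fits[names[i + 1]].n_free <= fits[names[i]].n_free
            ]
            final = fits[names[-1]]
            std = cholesky.standardize(final)
            dec = cholesky.decompose(final)
            payload = {
                "outcome": outcome,
                "predictor": predictor,
                "pair_counts": pairs.pair_counts(ptab),
                "assumption_tests": assumptions.to_dict(orient="records"),
                "models": {
                    nm: {
                        "sources": list(f.sources),
                        "minus2ll": f.minus2ll,
                        "n_free": f.n_free,
                        "aic": f.aic,
                        "converged": bool(f.converged),
                        "estimates": f.estimates.as_dict(),
                        "means": list(map(float, f.means)),
                    }
                    for nm, f in fits.items()
                },
                "comparisons": comparisons,
                "standardized_paths": std.to_dict(orient="records"),
                "decomposition": dataclasses.asdict(dec),
            }
            (out / f"twin_{outcome}_{predictor}.json").write_text(
                json.dumps(payload, indent=2, default=float)
            )
            row = {"outcome": outcome, "predictor": predictor,
                   "model": final.model_name,
                   "total_correlation": dec.total_correlation}
            for s in final.sources:
                row[f"var1_{s}"] = dec.variance_share_trait1[s]
                row[f"var2_{s}"] = dec.variance_share_trait2[s]
                row[f"cor_{s}"] = dec.correlation_component[s]
            tidy_rows.append(row)
        except Exception as exc:
            logger.warning("twin model for (%s, %s) failed: %s", outcome, predictor, exc)
            failures.append({"stage": "twin", "outcome": outcome,
                             "predictor": predictor, "error": str(exc)})
    pd.DataFrame(tidy_rows).to_csv(out / "twin_summary.csv", index=False)

    manifest = {
        "config_hash": _config_hash(config),
        "config": config.to_jsonable(),
        "seed": config.seed,
        "versions": _versions(),
        "started_unix": t0,
        "elapsed_s": time.time() - t0,
        "n_outcomes": len(outcomes),
        "n_screened_hits": int(len(hits)),
        "failures": failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
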