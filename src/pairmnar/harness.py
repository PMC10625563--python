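"""Monte-Carlo studies: size/power of the Stage-I test and bias/coverage of
the Stage-II estimator against naive complete-case least squares.

Every study is a pure function of its master seed: replication seeds are
drawn once from a generator keyed on the master seed, each replication
simulates a complete cohort, thins it with the scenario's reporting
mechanism, and runs the estimator(s) under study.  Replication failures are
caught and counted; a study aborts if more than 5% of replications fail.
Estimator comparisons happen on the tilt (density-ratio) scale: the naive
least-squares coefficients are divided by the true total outcome variance
σ² + τ², which is known in simulation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ModelSpec, PairMnarError, StudyError, build_analysis_table
from .stage1 import ExpFamSpec, mnar_test
from .stage2 import fit_pairwise
from .synthetic import SimulationConfig, apply_missingness, simulate_complete_cohort

logger = logging.getLogger("pairmnar")

_MAX_FAILURE_FRACTION = 0.05


@dataclass
class StudyReport:
    """Tabular study results plus a full echo of the scenario grid."""

    kind: str                      # "size_power" or "estimator"
    table: pd.DataFrame
    scenarios: dict[str, dict]     # scenario name -> config as plain dict
    master_seed: int | None
    alpha: float | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "kind": self.kind,
            "master_seed": self.master_seed,
            "alpha": self.alpha,
            "scenarios": self.scenarios,
        }


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["model"] = dataclasses.asdict(config.model)
    return d


def _rep_seeds(config: SimulationConfig, master_seed: int | None) -> np.ndarray:
    seed = config.seed if master_seed is None else master_seed
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=(config.replications, 2))


def _check_failures(name: str, failures: list[str], reps: int) -> None:
    if failures:
        logger.warning(
            "scenario %r: %d/%d replications failed (first: %s)",
            name, len(failures), reps, failures[0],
        )
    if len(failures) > _MAX_FAILURE_FRACTION * reps:
        raise StudyError(
            f"scenario {name!r}: {len(failures)}/{reps} replications failed"
        )


def run_size_power_study(
    scenarios: dict[str, SimulationConfig],
    stage1_spec: ModelSpec,
    fam: ExpFamSpec | None = None,
    alpha: float = 0.05,
    summary: str = "subject_mean",
    milestone_day: int | None = None,
    intercept_method: str = "median",
    master_seed: int | None = None,
) -> StudyReport:
    """Empirical rejection rate of the Stage-I test per scenario.

    Under null scenarios (MCAR, or selection through covariates only) the
    rejection rate estimates the type-I error; under outcome-dependent
    scenarios it estimates power.  The binomial standard error of each rate
    is reported alongside.
    """
    fam = fam or ExpFamSpec()
    rows = []
    for name, config in scenarios.items():
        if config.replications < 1:
            raise StudyError(f"scenario {name!r} has no replications")
        seeds = _rep_seeds(config, master_seed)
        pvals, tvals, dfs, failures = [], [], [], []
        for r in range(config.replications):
            try:
                data = simulate_complete_cohort(config, seed=int(seeds[r, 0]))
                data = apply_missingness(data, config.mechanism, int(seeds[r, 1]))
                res = mnar_test(
                    data,
                    stage1_spec,
                    fam=fam,
                    summary=summary,
                    milestone_day=milestone_day,
                    intercept_method=intercept_method,
                )
                pvals.append(res.p_value)
                tvals.append(res.T)
                dfs.append(res.df)
            except (PairMnarError, np.linalg.LinAlgError) as exc:
                failures.append(f"{type(exc).__name__}: {exc}")
        _check_failures(name, failures, config.replications)
        pvals = np.asarray(pvals)
        rate = float(np.mean(pvals < alpha))
        rows.append(
            {
                "scenario": name,
                "mechanism": config.mechanism.kind,
                "replications": config.replications,
                "failures": len(failures),
                "rejection_rate": rate,
                "rejection_se": float(
                    np.sqrt(rate * (1 - rate) / max(len(pvals), 1))
                ),
                "mean_T": float(np.mean(tvals)),
                "mean_df": float(np.mean(dfs)),
            }
        )
    return StudyReport(
        kind="size_power",
        table=pd.DataFrame(rows),
        scenarios={k: _config_dict(v) for k, v in scenarios.items()},
        master_seed=master_seed,
        alpha=alpha,
    )


def _naive_ols(table) -> tuple[np.ndarray, np.ndarray]:
    """Complete-case least squares on the observed rows; classical SEs."""
    X, y = table.X, table.y
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


def run_estimator_study(
    scenarios: dict[str, SimulationConfig],
    master_seed: int | None = None,
    pair_subsample_fraction: float | None = None,
) -> StudyReport:
    """Bias / SD / RMSE / 95% CI coverage of the pairwise estimator versus
    naive complete-case least squares on the identical observed rows.

    Both methods are scored against the tilt-scale truth β/(σ² + τ²); the
    naive coefficients are rescaled by the known variance so the comparison
    isolates selection bias rather than scale.  RMSE uses the population
    variance, so RMSE² = bias² + SD² holds exactly.
    """
    rows = []
    for name, config in scenarios.items():
        seeds = _rep_seeds(config, master_seed)
        truth = config.tilt_truth
        var_total = config.noise_sd**2 + config.random_effect_sd**2
        m = config.model.m
        pw_est = np.full((config.replications, m), np.nan)
        pw_cover = np.full((config.replications, m), np.nan)
        nv_est = np.full((config.replications, m), np.nan)
        nv_cover = np.full((config.replications, m), np.nan)
        failures = []
        spec_with_icpt = dataclasses.replace(config.model, include_intercept=True)
        for r in range(config.replications):
            try:
                data = simulate_complete_cohort(config, seed=int(seeds[r, 0]))
                data = apply_missingness(data, config.mechanism, int(seeds[r, 1]))
                table = build_analysis_table(data, spec_with_icpt)
                fit = fit_pairwise(
                    table,
                    pair_subsample_fraction=pair_subsample_fraction,
                    seed=int(seeds[r, 1]),
                )
                pw_est[r] = fit.beta
                pw_cover[r] = np.abs(fit.beta - truth) <= 1.96 * fit.se
                beta_ols, se_ols = _naive_ols(table)
                nv_est[r] = beta_ols[1:] / var_total
                nv_cover[r] = (
                    np.abs(beta_ols[1:] / var_total - truth)
                    <= 1.96 * se_ols[1:] / var_total
                )
            except (PairMnarError, np.linalg.LinAlgError) as exc:
                failures.append(f"{type(exc).__name__}: {exc}")
        _check_failures(name, failures, config.replications)
        ok = ~np.isnan(pw_est[:, 0])
        for method, est, cover in (
            ("pairwise", pw_est[ok], pw_cover[ok]),
            ("naive_complete_case", nv_est[ok], nv_cover[ok]),
        ):
            bias = est.mean(axis=0) - truth
            sd = est.std(axis=0, ddof=0)
            rmse = np.sqrt(np.mean((est - truth) ** 2, axis=0))
            for k, colname in enumerate(config.model.covariate_names):
                rows.append(
                    {
                        "scenario": name,
                        "mechanism": config.mechanism.kind,
                        "method": method,
                        "coefficient": colname,
                        "truth_tilt": float(truth[k]),
                        "bias": float(bias[k]),
                        "sd": float(sd[k]),
                        "rmse": float(rmse[k]),
                        "mc_se": float(sd[k] / np.sqrt(ok.sum())),
                        "coverage_95": float(np.mean(cover[:, k])),
                        "replications": int(ok.sum()),
                        "failures": len(failures),
                    }
                )
    return StudyReport(
        kind="estimator",
        table=pd.DataFrame(rows),
        scenarios={k: _config_dict(v) for k, v in scenarios.items()},
        master_seed=master_seed,
    )
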