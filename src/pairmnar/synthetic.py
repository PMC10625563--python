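"""Synthetic weight-loss cohorts with controllable reporting mechanisms.

The generator emulates a three-arm incentive trial: ~189 participants
randomized ~1:2:2 (control : direct payment : lottery), daily home weights
over a scheduled follow-up window, and baseline characteristics drawn to
match the published cohort summaries (age ≈ N(49.0, 10.5²), 91.6% female,
BMI ≈ N(36.7, 4.2²) truncated to the 30–45 eligibility window, baseline
weight ≈ N(198.9, 32.9²) lb).

Outcomes follow a Gaussian linear model on the weight-change scale,

    y_ij = α + x_ijᵀ β + b_i + ε_ij,    b_i ~ N(0, τ²),  ε_ij ~ N(0, σ²),

with the design x_ij assembled by the same builder the estimators use, so
``true_beta`` is exactly the mean-scale estimand of the analysis model.
With σ = 1 and τ = 0 (the defaults for estimator tests) the mean-scale
coefficients coincide numerically with the density-ratio (tilt) scale that
the pairwise estimator identifies; in general the tilt estimand is
β / (σ² + τ²).

Reporting is then thinned by one of three mechanisms:

* ``MCAR`` — every row kept independently with constant probability;
* ``MAR`` — keep probability logistic in baseline covariates only;
* ``MNAR_PRODUCT`` — keep probability is a *product* of a covariate-only
  logistic factor and an outcome-only logistic factor
  σ(x_coefs·x̃_i)·σ(γ0 + γ1·y_ij), the separable form under which the
  pairwise conditional likelihood is exactly valid;
* ``MNAR_JOINT`` — a deliberately non-separable mechanism (logistic with an
  outcome-by-age interaction) for robustness experiments only.

The covariate vector x̃_i of the selection model is (1, age−49, sex,
BMI−36.7): age and BMI are centered at the fixed population constants so the
selection probability is a function of the subject alone, independent of who
else is in the sample.  Each subject draws selection from an independent
substream keyed by (seed, subject id), so relabeling subjects commutes with
applying missingness.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    ConfigError,
    LongitudinalDataset,
    ModelSpec,
    Subject,
    build_analysis_table,
)

# population constants used to center the selection covariates
_AGE_CENTER = 49.0
_BMI_CENTER = 36.7

MECHANISMS = ("MCAR", "MAR", "MNAR_PRODUCT", "MNAR_JOINT")


def _sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class MissingnessMechanism:
    """Parametric description of the reporting (selection) process.

    ``x_coefs`` acts on (1, age−49, sex, BMI−36.7); ``y_coefs`` = (γ0, γ1)
    acts on the outcome (weight change, lb).
    """

    kind: str = "MCAR"
    p_const: float | None = None
    x_coefs: tuple[float, ...] | None = None
    y_coefs: tuple[float, float] | None = None
    joint_interaction: float = 0.0   # MNAR_JOINT only: coefficient on y·(age−49)

    def __post_init__(self):
        if self.kind not in MECHANISMS:
            raise ConfigError(f"unknown mechanism kind {self.kind!r}")
        if self.kind == "MCAR":
            if self.p_const is None or not (0.0 < self.p_const <= 1.0):
                raise ConfigError("MCAR requires 0 < p_const <= 1")
        else:
            if self.x_coefs is None or len(self.x_coefs) != 4:
                raise ConfigError(
                    f"{self.kind} requires x_coefs of length 4 "
                    "(intercept, age-49, sex, bmi-36.7)"
                )
        if self.kind in ("MNAR_PRODUCT", "MNAR_JOINT") and self.y_coefs is None:
            raise ConfigError(f"{self.kind} requires y_coefs = (gamma0, gamma1)")

    def keep_probability(self, subject: Subject, y: np.ndarray) -> np.ndarray:
        """Per-row probability that subject's outcomes y are reported."""
        y = np.asarray(y, dtype=float)
        if self.kind == "MCAR":
            return np.full(y.shape, float(self.p_const))
        xtil = np.array(
            [
                1.0,
                subject.age - _AGE_CENTER,
                float(subject.sex),
                subject.baseline_bmi - _BMI_CENTER,
            ]
        )
        eta_x = float(np.dot(self.x_coefs, xtil))
        if self.kind == "MAR":
            return np.full(y.shape, float(_sigmoid(np.array([eta_x]))[0]))
        g0, g1 = self.y_coefs
        if self.kind == "MNAR_PRODUCT":
            return _sigmoid(np.full(y.shape, eta_x)) * _sigmoid(g0 + g1 * y)
        # MNAR_JOINT: single logistic with an x-by-y interaction (non-product)
        return _sigmoid(
            eta_x + g0 + g1 * y + self.joint_interaction * y * (subject.age - _AGE_CENTER)
        )


@dataclass(frozen=True)
class SimulationConfig:
    """A complete description of one simulation scenario."""

    n_subjects: int = 189
    schedule_length: int = 30
    model: ModelSpec = field(default_factory=ModelSpec)
    # mean-scale coefficients aligned with model.covariate_names; defaults are
    # the trial-shaped effects (sex, BMI, age, time/month, arm-by-time)
    true_beta: tuple[float, ...] = (-0.246, -0.002, 0.013, -0.582, -0.616, -0.512)
    true_intercept: float = 0.0
    noise_sd: float = 1.0
    random_effect_sd: float = 0.0
    mechanism: MissingnessMechanism = field(
        default_factory=lambda: MissingnessMechanism(kind="MCAR", p_const=0.7)
    )
    seed: int = 0
    replications: int = 1

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.schedule_length < 1:
            raise ConfigError("schedule_length must be >= 1")
        if not (self.noise_sd > 0):
            raise ConfigError("noise_sd must be > 0")
        if self.random_effect_sd < 0:
            raise ConfigError("random_effect_sd must be >= 0")
        if self.replications < 1:
            raise ConfigError("replications must be >= 1")
        if len(self.true_beta) != self.model.m:
            raise ConfigError(
                f"true_beta has length {len(self.true_beta)} but the model "
                f"has {self.model.m} covariates"
            )

    @property
    def tilt_truth(self) -> np.ndarray:
        """The density-ratio-scale estimand of the pairwise estimator."""
        return np.asarray(self.true_beta) / (
            self.noise_sd**2 + self.random_effect_sd**2
        )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_subjects(config: SimulationConfig, rng: np.random.Generator) -> list[Subject]:
    n = config.n_subjects
    arms = rng.choice(
        ["control", "direct_payment", "lottery"], size=n, p=[0.2, 0.4, 0.4]
    )
    age = np.clip(rng.normal(49.0, 10.5, size=n), 18.0, None)
    sex = (rng.random(n) < 0.916).astype(int)
    # truncated normal via resampling: BMI eligibility window is (30, 45)
    bmi = rng.normal(36.7, 4.2, size=n)
    bad = (bmi <= 30.0) | (bmi >= 45.0)
    while bad.any():
        bmi[bad] = rng.normal(36.7, 4.2, size=int(bad.sum()))
        bad = (bmi <= 30.0) | (bmi >= 45.0)
    weight = np.clip(rng.normal(198.9, 32.9, size=n), 90.0, None)
    return [
        Subject(
            subject_id=f"S{i:04d}",
            arm=str(arms[i]),
            age=float(age[i]),
            sex=int(sex[i]),
            baseline_bmi=float(bmi[i]),
            baseline_weight=float(weight[i]),
        )
        for i in range(n)
    ]


def simulate_complete_cohort(
    config: SimulationConfig, seed: int | None = None
) -> LongitudinalDataset:
    """Generate a fully observed cohort; a pure function of the seed.

    Every subject has one row per scheduled day with ``observed=True``.  The
    daily weight is ``baseline_weight + y_ij`` with the Gaussian linear
    outcome model described in the module docstring; the design matrix is
    produced by :func:`pairmnar.data_model.build_analysis_table`, so the
    generating coefficients line up with the analysis model column for
    column (including the centering of age and BMI on this cohort).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([int(seed), _COHORT_SUBSTREAM])
    subjects = _draw_subjects(config, rng)
    n, L = config.n_subjects, config.schedule_length

    # scaffold dataset with placeholder weights to reuse the design builder
    series = pd.DataFrame(
        {
            "subject_id": np.repeat([s.subject_id for s in subjects], L),
            "day": np.tile(np.arange(L), n),
            "observed": True,
            "weight": np.repeat([s.baseline_weight for s in subjects], L),
        }
    )
    scaffold = LongitudinalDataset(
        subjects=subjects, series=series, schedule_length=L
    )
    table = build_analysis_table(scaffold, config.model.without_intercept())

    b = rng.normal(0.0, config.random_effect_sd, size=n)
    eps = rng.normal(0.0, config.noise_sd, size=n * L)
    y = (
        config.true_intercept
        + table.X @ np.asarray(config.true_beta, dtype=float)
        + b[table.subject_index]
        + eps
    )
    series = series.copy()
    series["weight"] = series["weight"].to_numpy() + y
    return LongitudinalDataset(subjects=subjects, series=series, schedule_length=L)


# seed policy: one master seed; the cohort draw and the missingness draws
# use disjoint, documented substreams of it
_COHORT_SUBSTREAM = 1
_MISSING_SUBSTREAM = 2


def _subject_stream(seed: int, subject_id: str) -> np.random.Generator:
    key = zlib.crc32(subject_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng([int(seed), _MISSING_SUBSTREAM, key])


def apply_missingness(
    data: LongitudinalDataset, mech: MissingnessMechanism, seed: int
) -> LongitudinalDataset:
    """Redraw every row's observed flag under the selection mechanism.

    Requires a fully observed input.  Each subject's keep/drop draws come
    from an independent substream keyed by (seed, subject id), taken in day
    order, so permuting subject labels commutes with applying missingness.
    Weights on dropped rows are removed.  Pure function of the seed.
    """
    if not data.series["observed"].all():
        raise ConfigError("apply_missingness requires a fully observed dataset")
    smap = data.subject_map()
    series = data.series.sort_values(["subject_id", "day"]).reset_index(drop=True)

    observed = np.ones(len(series), dtype=bool)
    weight = series["weight"].to_numpy(dtype=float).copy()
    baseline = np.array([smap[s].baseline_weight for s in series["subject_id"]])
    outcome = weight - baseline

    for sid, idx in series.groupby("subject_id", sort=False).indices.items():
        sub = smap[sid]
        order = np.argsort(series["day"].to_numpy()[idx])
        idx = np.asarray(idx)[order]
        p = mech.keep_probability(sub, outcome[idx])
        rng = _subject_stream(seed, sid)
        keep = rng.random(len(idx)) < p
        observed[idx] = keep
        weight[idx[~keep]] = np.nan

    out = series.copy()
    out["observed"] = observed
    out["weight"] = weight
    return LongitudinalDataset(
        subjects=list(data.subjects), series=out, schedule_length=data.schedule_length
    )
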