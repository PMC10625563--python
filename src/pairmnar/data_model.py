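"""Domain types and table construction for daily weigh-in longitudinal data.

The data are long-format: one row per subject-day, with subject-level
baseline covariates (age, sex, baseline BMI, baseline weight) repeated on
each row, and a daily weight that is present only on days the subject
actually reported.  An empty weight cell encodes a missing report.  The
analysis outcome is the weight change from baseline, ``y_ij = weight_ij -
baseline_weight_i``, so negative values mean weight loss.

This module owns the validated in-memory containers (:class:`Subject`,
:class:`LongitudinalDataset`), CSV input/output, and the design-matrix
assembly (:func:`build_analysis_table`) shared by both analysis stages.
Covariates listed in ``ModelSpec.center_list`` are mean-centered using one
value per subject (the subject-level mean over subjects contributing at
least one observed row), so centering does not depend on how many days each
subject reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("pairmnar")

ARMS = ("control", "direct_payment", "lottery")

#: canonical column names of the long-format CSV
LONG_COLUMNS = (
    "subject_id",
    "arm",
    "age",
    "sex",
    "baseline_bmi",
    "baseline_weight",
    "day",
    "weight",
)

#: covariates that are constant within a subject
SUBJECT_LEVEL_COVARIATES = ("sex", "age", "baseline_bmi", "baseline_weight")

#: covariates derived from the day index and arm assignment
TIME_COVARIATES = ("time", "lottery_time", "direct_payment_time")


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class PairMnarError(Exception):
    """Base class for errors raised by this package."""


class SchemaError(PairMnarError):
    """A required column is missing or has an unusable type."""


class IntegrityError(PairMnarError):
    """The data violate a structural invariant (e.g. duplicated days)."""


class EmptyDataError(PairMnarError):
    """No observed rows are available for analysis."""


class InsufficientDataError(PairMnarError):
    """Too few records/subjects to run the requested estimator."""


class UnidentifiedModelError(PairMnarError):
    """The requested parameters are not identified by the data."""


class ConvergenceError(PairMnarError):
    """An iterative fit failed to converge."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class DegenerateTestError(PairMnarError):
    """The test statistic's weighting matrix has rank zero."""


class ConfigError(PairMnarError):
    """An invalid configuration was supplied."""


class StudyError(PairMnarError):
    """Too many replications of a simulation study failed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Subject:
    """One trial participant with baseline characteristics.

    ``sex`` is coded 1 = female.  Weights are in pounds, BMI in kg/m².
    """

    subject_id: str
    arm: str
    age: float
    sex: int
    baseline_bmi: float
    baseline_weight: float

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValueError(
                f"unknown arm label {self.arm!r} for subject "
                f"{self.subject_id!r}; expected one of {ARMS}"
            )
        if not (self.age > 0):
            raise ValueError(f"age must be positive (subject {self.subject_id!r})")
        if int(self.sex) not in (0, 1):
            raise ValueError(f"sex must be 0/1 (subject {self.subject_id!r})")
        if not (self.baseline_bmi > 0):
            raise ValueError(
                f"baseline_bmi must be positive (subject {self.subject_id!r})"
            )
        if not (self.baseline_weight > 0):
            raise ValueError(
                f"baseline_weight must be positive (subject {self.subject_id!r})"
            )


@dataclass
class LongitudinalDataset:
    """Subjects plus their per-day observation series.

    ``series`` is a DataFrame with columns ``subject_id`` (str), ``day``
    (int, 0-based days since enrollment), ``observed`` (bool) and ``weight``
    (float lb, NaN exactly when ``observed`` is False).  The schedule is the
    half-open day range ``[0, schedule_length)``.
    """

    subjects: list[Subject]
    series: pd.DataFrame
    schedule_length: int

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        s = self.series
        required = {"subject_id", "day", "observed", "weight"}
        missing = required - set(s.columns)
        if missing:
            raise SchemaError(f"series is missing columns: {sorted(missing)}")
        ids = {sub.subject_id for sub in self.subjects}
        unknown = set(s["subject_id"]) - ids
        if unknown:
            raise IntegrityError(
                f"series references unknown subjects: {sorted(unknown)[:5]}"
            )
        if s.duplicated(["subject_id", "day"]).any():
            dup = s[s.duplicated(["subject_id", "day"])].iloc[0]
            raise IntegrityError(
                f"duplicated (subject, day) pair: ({dup['subject_id']!r}, {dup['day']})"
            )
        day = s["day"].to_numpy()
        if len(day) and (day.min() < 0 or day.max() >= self.schedule_length):
            raise IntegrityError(
                f"day indices must lie in [0, {self.schedule_length})"
            )
        obs = s["observed"].to_numpy(dtype=bool)
        w = s["weight"].to_numpy(dtype=float)
        if np.isnan(w[obs]).any():
            raise IntegrityError("observed rows must carry a weight")
        if obs.size and np.isfinite(w[~obs]).any():
            raise IntegrityError("unobserved rows must not carry a weight")

    # -- convenience ------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_map(self) -> dict[str, Subject]:
        return {s.subject_id: s for s in self.subjects}

    def observed_counts(self) -> pd.Series:
        """K_i: number of observed days per subject (0 for silent subjects)."""
        counts = (
            self.series[self.series["observed"]]
            .groupby("subject_id")
            .size()
        )
        return counts.reindex(
            [s.subject_id for s in self.subjects], fill_value=0
        )

    def copy(self) -> "LongitudinalDataset":
        return LongitudinalDataset(
            subjects=list(self.subjects),
            series=self.series.copy(),
            schedule_length=self.schedule_length,
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the regression and how they are prepared.

    ``time_unit`` rescales the integer day index before it is used as the
    ``time`` covariate; the default 1/30 expresses time in months so that
    per-unit-time coefficients stay on an interpretable scale.
    """

    covariate_names: tuple[str, ...] = (
        "sex",
        "baseline_bmi",
        "age",
        "time",
        "lottery_time",
        "direct_payment_time",
    )
    center_list: tuple[str, ...] = ("age", "baseline_bmi")
    include_intercept: bool = True
    time_unit: float = 1.0 / 30.0

    def __post_init__(self):
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        object.__setattr__(self, "center_list", tuple(self.center_list))
        if not self.covariate_names:
            raise ConfigError("covariate_names must be non-empty")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ConfigError("covariate_names contains duplicates")
        known = set(SUBJECT_LEVEL_COVARIATES) | set(TIME_COVARIATES)
        unknown = set(self.covariate_names) - known
        if unknown:
            raise ConfigError(
                f"unknown covariates {sorted(unknown)}; available: {sorted(known)}"
            )
        bad_center = set(self.center_list) - set(SUBJECT_LEVEL_COVARIATES)
        if bad_center:
            raise ConfigError(
                f"only subject-level covariates can be centered, got {sorted(bad_center)}"
            )

    @property
    def m(self) -> int:
        """Covariate dimension (intercept excluded)."""
        return len(self.covariate_names)

    def without_intercept(self) -> "ModelSpec":
        return replace(self, include_intercept=False)


@dataclass
class AnalysisTable:
    """Stacked observed rows (y_ij, x_ij) ready for estimation.

    ``subject_index`` maps each row to ``0..n_subjects-1`` (subjects with at
    least one observed row, in dataset order); ``K`` holds the per-subject
    row counts aligned with ``subject_ids``.
    """

    y: np.ndarray                 # (N,) outcome: weight change from baseline, lb
    X: np.ndarray                 # (N, p) design matrix
    columns: tuple[str, ...]      # length p, may start with "intercept"
    subject_index: np.ndarray     # (N,) int
    day: np.ndarray               # (N,) int
    subject_ids: tuple[str, ...]  # length n_subjects
    K: np.ndarray                 # (n_subjects,) int

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

def read_long_csv(
    path,
    schema: dict[str, str] | None = None,
    schedule_length: int | None = None,
) -> LongitudinalDataset:
    """Read a long-format CSV into a validated :class:`LongitudinalDataset`.

    Parameters
    ----------
    path : path-like
        CSV with a header row and one row per subject-day.  Baseline columns
        are repeated on every row of a subject.  An empty ``weight`` field
        encodes a missing report.
    schema : dict, optional
        Mapping from canonical column names (see :data:`LONG_COLUMNS`) to the
        names actually used in the file.
    schedule_length : int, optional
        Number of scheduled days; defaults to ``max(day) + 1``.
    """
    schema = schema or {}
    colmap = {name: schema.get(name, name) for name in LONG_COLUMNS}
    df = pd.read_csv(path)
    missing = [file_col for file_col in colmap.values() if file_col not in df.columns]
    if missing:
        raise SchemaError(f"input file is missing required columns: {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    df["subject_id"] = df["subject_id"].astype(str)
    if df.duplicated(["subject_id", "day"]).any():
        dup = df[df.duplicated(["subject_id", "day"])].iloc[0]
        raise IntegrityError(
            f"duplicated (subject, day) pair in input: "
            f"({dup['subject_id']!r}, {dup['day']})"
        )

    subjects = []
    for sid, grp in df.groupby("subject_id", sort=False):
        row = grp.iloc[0]
        try:
            subjects.append(
                Subject(
                    subject_id=str(sid),
                    arm=str(row["arm"]),
                    age=float(row["age"]),
                    sex=int(row["sex"]),
                    baseline_bmi=float(row["baseline_bmi"]),
                    baseline_weight=float(row["baseline_weight"]),
                )
            )
        except ValueError as exc:
            raise IntegrityError(str(exc)) from exc

    weight = pd.to_numeric(df["weight"], errors="coerce")
    series = pd.DataFrame(
        {
            "subject_id": df["subject_id"].to_numpy(),
            "day": df["day"].astype(int).to_numpy(),
            "observed": weight.notna().to_numpy(),
            "weight": weight.to_numpy(dtype=float),
        }
    )
    if schedule_length is None:
        schedule_length = int(series["day"].max()) + 1 if len(series) else 1
    return LongitudinalDataset(
        subjects=subjects, series=series, schedule_length=schedule_length
    )


def write_long_csv(data: LongitudinalDataset, path) -> None:
    """Write the long-format CSV; numeric fields round-trip bit-exactly."""
    smap = data.subject_map()
    s = data.series
    out = pd.DataFrame(
        {
            "subject_id": s["subject_id"],
            "arm": [smap[i].arm for i in s["subject_id"]],
            "age": [smap[i].age for i in s["subject_id"]],
            "sex": [smap[i].sex for i in s["subject_id"]],
            "baseline_bmi": [smap[i].baseline_bmi for i in s["subject_id"]],
            "baseline_weight": [smap[i].baseline_weight for i in s["subject_id"]],
            "day": s["day"],
            "weight": s["weight"],
        }
    )
    # pandas writes the shortest decimal string that round-trips to the same
    # float64, so read_long_csv(write_long_csv(ds)) is field-for-field exact
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# design-matrix assembly
# ---------------------------------------------------------------------------

def _subject_covariate(subject: Subject, name: str) -> float:
    if name == "sex":
        return float(subject.sex)
    if name == "age":
        return float(subject.age)
    if name == "baseline_bmi":
        return float(subject.baseline_bmi)
    if name == "baseline_weight":
        return float(subject.baseline_weight)
    raise KeyError(name)


def build_analysis_table(data: LongitudinalDataset, spec: ModelSpec) -> AnalysisTable:
    """Assemble outcome and design matrix from the observed rows.

    The outcome is the reported weight minus the subject's baseline weight.
    Covariates in ``spec.center_list`` are centered at the mean over subjects
    contributing at least one observed row (one value per subject, so the
    centering is invariant to per-subject observation counts).  Arm-by-time
    interactions use the control arm as the reference.
    """
    smap = data.subject_map()
    obs = data.series[data.series["observed"]].reset_index(drop=True)
    if len(obs) == 0:
        raise EmptyDataError("no observed rows in the dataset")

    for sub in data.subjects:
        for fieldname in ("age", "sex", "baseline_bmi", "baseline_weight"):
            if not np.isfinite(getattr(sub, fieldname)):
                raise ValueError(
                    f"subject {sub.subject_id!r} has missing baseline "
                    f"covariate {fieldname!r}"
                )

    contributing = set(obs["subject_id"])
    subject_ids = tuple(
        s.subject_id for s in data.subjects if s.subject_id in contributing
    )
    silent = [s.subject_id for s in data.subjects if s.subject_id not in contributing]
    if silent:
        logger.warning(
            "%d subject(s) have no observed rows and contribute no analysis "
            "rows: %s%s",
            len(silent), silent[:5], "..." if len(silent) > 5 else "",
        )
    sidx = {sid: k for k, sid in enumerate(subject_ids)}

    # subject-level centering means (one value per contributing subject)
    center_means = {
        name: float(
            np.mean([_subject_covariate(smap[sid], name) for sid in subject_ids])
        )
        for name in spec.center_list
    }

    row_sid = obs["subject_id"].to_numpy()
    subject_index = np.array([sidx[s] for s in row_sid], dtype=np.intp)
    day = obs["day"].to_numpy(dtype=np.intp)
    weight = obs["weight"].to_numpy(dtype=float)
    baseline = np.array([smap[s].baseline_weight for s in row_sid])
    y = weight - baseline

    time = day.astype(float) * spec.time_unit
    arm = np.array([smap[s].arm for s in row_sid])

    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.include_intercept:
        cols.append(np.ones(len(obs)))
        names.append("intercept")
    for name in spec.covariate_names:
        if name == "time":
            col = time
        elif name == "lottery_time":
            col = (arm == "lottery").astype(float) * time
        elif name == "direct_payment_time":
            col = (arm == "direct_payment").astype(float) * time
        else:
            col = np.array([_subject_covariate(smap[s], name) for s in row_sid])
            if name in center_means:
                col = col - center_means[name]
        cols.append(col)
        names.append(name)

    X = np.column_stack(cols)
    K = np.bincount(subject_index, minlength=len(subject_ids)).astype(np.intp)
    return AnalysisTable(
        y=y,
        X=X,
        columns=tuple(names),
        subject_index=subject_index,
        day=day,
        subject_ids=subject_ids,
        K=K,
    )
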