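"""Pairwise composite conditional likelihood for outcome-dependent reporting.

The marginal model is a semiparametric exponential tilt (density-ratio)
model: f(y | x) ∝ exp(βᵀx·y) g(y), with g an unspecified baseline density.
For two observations from *different* subjects, conditioning on the order
statistics (min, max) of the pair makes the baseline density — and, under a
separable selection process P(report | y, x) = a(x)·q(y), the whole
reporting mechanism — cancel from the conditional probability, leaving

    P(pair as observed | order stats, x₁, x₂; β)
        = 1 / (1 + exp(−(βᵀ(x₁ − x₂))·(y₁ − y₂))),

a logistic function of a β-linear exponent.  Summing the log of this kernel
over every cross-subject observation pair gives a concave composite
log-likelihood; its maximizer estimates β on the tilt scale (for Gaussian
outcomes with variance σ², tilt β = mean-scale β / σ²).  Constants cancel
in x₁ − x₂, so there is no intercept at this stage.

Because the composite likelihood is not a true likelihood and pairs sharing
a subject are dependent, standard errors use the Godambe sandwich
H⁻¹ V H⁻¹ with per-subject score sums (each pair's score attributed to both
of its member subjects) as the clustered variability estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .data_model import (
    AnalysisTable,
    InsufficientDataError,
    UnidentifiedModelError,
    ConvergenceError,
)

logger = logging.getLogger("pairmnar")

_DEFAULT_BLOCK = 1 << 18


# ---------------------------------------------------------------------------
# pair kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTerm:
    """One cross-subject observation pair (y₁, x₁) vs (y₂, x₂)."""

    y1: float
    y2: float
    x1: tuple[float, ...]
    x2: tuple[float, ...]

    @property
    def y_min(self) -> float:
        return min(self.y1, self.y2)

    @property
    def y_max(self) -> float:
        return max(self.y1, self.y2)


def pair_log_probability(term: PairTerm, beta) -> float:
    """Log conditional probability of one pair given its order statistics.

    Equals −log(1 + exp(−(βᵀ(x₁−x₂))·(y₁−y₂))), evaluated stably; a tied
    pair (y₁ = y₂) contributes log(1/2).
    """
    beta = np.asarray(beta, dtype=float)
    x1 = np.asarray(term.x1, dtype=float)
    x2 = np.asarray(term.x2, dtype=float)
    if x1.shape != x2.shape or x1.shape != beta.shape:
        raise ValueError("beta and covariate vectors must share one dimension")
    vals = np.concatenate([[term.y1, term.y2], x1, x2, beta])
    if not np.all(np.isfinite(vals)):
        raise ValueError("pair_log_probability requires finite inputs")
    u = float(beta @ (x1 - x2)) * (term.y1 - term.y2)
    return float(-np.logaddexp(0.0, -u))


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------

@dataclass
class PairIndex:
    """Row-index arrays of the enumerated cross-subject pairs."""

    a: np.ndarray            # (n_pairs,) row index of the first observation
    b: np.ndarray            # (n_pairs,) row index of the second observation
    n_pairs: int
    n_subject_pairs: int     # number of unordered subject pairs represented
    subsample_fraction: float | None = None


def enumerate_pairs(
    table: AnalysisTable,
    pair_subsample_fraction: float | None = None,
    seed: int | None = None,
) -> PairIndex:
    """All cross-subject observation pairs, each unordered pair once.

    Within-subject pairs are excluded; n_pairs = Σ_{i<i′} K_i K_i′.  With
    ``pair_subsample_fraction`` < 1 a seeded uniform subsample of *subject*
    pairs is enumerated instead (the supported scaling path for cohorts
    whose full pair set is too large).
    """
    subj = table.subject_index
    n_contrib = int((table.K > 0).sum())
    if n_contrib < 2:
        raise InsufficientDataError(
            "pairwise likelihood needs at least 2 subjects with observations"
        )

    if pair_subsample_fraction is not None and pair_subsample_fraction < 1.0:
        if not (0.0 < pair_subsample_fraction <= 1.0):
            raise ValueError("pair_subsample_fraction must be in (0, 1]")
        rng = np.random.default_rng(seed)
        sa, sb = np.triu_indices(table.n_subjects, k=1)
        m_total = len(sa)
        take = max(1, int(np.ceil(pair_subsample_fraction * m_total)))
        chosen = rng.choice(m_total, size=take, replace=False)
        rows_by_subject = [
            np.flatnonzero(subj == i) for i in range(table.n_subjects)
        ]
        a_parts, b_parts = [], []
        for k in chosen:
            ra, rb = rows_by_subject[sa[k]], rows_by_subject[sb[k]]
            if len(ra) == 0 or len(rb) == 0:
                continue
            a_parts.append(np.repeat(ra, len(rb)))
            b_parts.append(np.tile(rb, len(ra)))
        if not a_parts:
            raise InsufficientDataError("subject-pair subsample contains no pairs")
        a = np.concatenate(a_parts)
        b = np.concatenate(b_parts)
        return PairIndex(
            a=a, b=b, n_pairs=len(a), n_subject_pairs=take,
            subsample_fraction=pair_subsample_fraction,
        )

    a, b = np.triu_indices(table.n_rows, k=1)
    keep = subj[a] != subj[b]
    a, b = a[keep], b[keep]
    n_subject_pairs = n_contrib * (n_contrib - 1) // 2
    return PairIndex(a=a, b=b, n_pairs=len(a), n_subject_pairs=n_subject_pairs)


# ---------------------------------------------------------------------------
# composite likelihood: value, gradient, Hessian
# ---------------------------------------------------------------------------

def composite_loglik(
    table: AnalysisTable,
    beta,
    pairs: PairIndex | None = None,
    block_size: int = _DEFAULT_BLOCK,
):
    """log L(β) with exact analytic gradient and Hessian.

    Each pair contributes log σ(u) with u = (βᵀ(x₁−x₂))(y₁−y₂); gradient
    terms are σ(−u)·(x₁−x₂)Δy and the Hessian is −Σ σ(u)σ(−u)·vvᵀ with
    v = (x₁−x₂)Δy, so the objective is globally concave.  Evaluation is
    blocked over the pair arrays; results do not depend on the block size
    (all accumulation in float64 sums of per-block float64 sums).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (table.X.shape[1],):
        raise ValueError(
            f"beta has shape {beta.shape}, design has {table.X.shape[1]} columns"
        )
    if pairs is None:
        pairs = enumerate_pairs(table)
    m = table.X.shape[1]
    ll = 0.0
    grad = np.zeros(m)
    hess = np.zeros((m, m))
    for start in range(0, pairs.n_pairs, block_size):
        sl = slice(start, min(start + block_size, pairs.n_pairs))
        a, b = pairs.a[sl], pairs.b[sl]
        v = (table.X[a] - table.X[b]) * (table.y[a] - table.y[b])[:, None]
        u = v @ beta
        ll += float(-np.logaddexp(0.0, -u).sum())
        s = special.expit(-u)                      # σ(−u)
        grad += v.T @ s
        w = s * special.expit(u)                   # σ(u)σ(−u)
        hess -= (v * w[:, None]).T @ v
    return ll, grad, hess


def _pair_scores_by_subject(
    table: AnalysisTable,
    beta,
    pairs: PairIndex,
    block_size: int = _DEFAULT_BLOCK,
) -> np.ndarray:
    """S_i: sum of pair-score contributions over pairs containing subject i.

    Each pair's score counts once into each of its two member subjects.
    """
    beta = np.asarray(beta, dtype=float)
    m = table.X.shape[1]
    S = np.zeros((table.n_subjects, m))
    subj = table.subject_index
    for start in range(0, pairs.n_pairs, block_size):
        sl = slice(start, min(start + block_size, pairs.n_pairs))
        a, b = pairs.a[sl], pairs.b[sl]
        v = (table.X[a] - table.X[b]) * (table.y[a] - table.y[b])[:, None]
        sc = v * special.expit(-(v @ beta))[:, None]
        for k in range(m):
            S[:, k] += np.bincount(subj[a], weights=sc[:, k], minlength=table.n_subjects)
            S[:, k] += np.bincount(subj[b], weights=sc[:, k], minlength=table.n_subjects)
    return S


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class Stage2Result:
    """Pairwise composite likelihood fit on the tilt (density-ratio) scale."""

    beta: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    z_p_values: np.ndarray
    n_pairs: int
    loglik: float
    converged: bool
    iterations: int
    columns: tuple[str, ...]

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "effect_size": self.beta,
                "se": self.se,
                "p_value": self.z_p_values,
            },
            index=list(self.columns),
        )


def _drop_intercept(table: AnalysisTable) -> AnalysisTable:
    if "intercept" not in table.columns:
        return table
    keep = [k for k, c in enumerate(table.columns) if c != "intercept"]
    logger.info("dropping intercept column: constants cancel in pair differences")
    return AnalysisTable(
        y=table.y,
        X=table.X[:, keep],
        columns=tuple(table.columns[k] for k in keep),
        subject_index=table.subject_index,
        day=table.day,
        subject_ids=table.subject_ids,
        K=table.K,
    )


def _check_identified(table: AnalysisTable, pairs: PairIndex) -> None:
    """Raise unless the pair-difference design has full column rank."""
    if table.X.shape[1] == 0:
        raise UnidentifiedModelError(
            "no covariates left after dropping the intercept; the pairwise "
            "objective is constant"
        )
    v = (table.X[pairs.a] - table.X[pairs.b]) * (
        table.y[pairs.a] - table.y[pairs.b]
    )[:, None]
    gram = v.T @ v
    d = np.sqrt(np.diag(gram))
    scale = d.max() if d.size else 0.0
    if scale == 0.0:
        raise UnidentifiedModelError(
            "pairwise objective is flat: every pair difference is zero "
            "(constant outcome or constant covariates)"
        )
    dead = [c for c, dk in zip(table.columns, d) if dk <= 1e-12 * scale]
    if dead:
        raise UnidentifiedModelError(
            f"columns with no cross-subject contrast: {dead}"
        )
    eigvals = np.linalg.eigvalsh(gram)
    if eigvals[0] <= 1e-12 * eigvals[-1]:
        raise UnidentifiedModelError(
            f"pair-difference design is collinear among columns {list(table.columns)}"
        )


def fit_pairwise(
    table: AnalysisTable,
    max_iter: int = 50,
    tol: float = 1e-8,
    init=None,
    pair_subsample_fraction: float | None = None,
    seed: int | None = None,
    compute_cov: bool = True,
    cov_method: str = "sandwich",
    block_size: int = _DEFAULT_BLOCK,
) -> Stage2Result:
    """Maximize the pairwise composite log-likelihood by Newton's method.

    The objective is concave, so Newton from β = 0 with step halving
    converges to the unique maximum whenever the pair-difference design has
    full column rank.  Convergence is declared when the scaled gradient
    max-norm (‖g‖∞ / n_pairs) drops below ``tol`` or the relative objective
    change does.  Standard errors come from :func:`sandwich_cov` by default;
    ``cov_method="jackknife"`` uses exact delete-one-subject refits instead,
    which track the uncertainty better when one covariate's cross-subject
    contrast rests on a handful of subjects (e.g. a rare binary covariate).
    """
    if cov_method not in ("sandwich", "jackknife"):
        raise ValueError("cov_method must be 'sandwich' or 'jackknife'")
    table = _drop_intercept(table)
    pairs = enumerate_pairs(
        table, pair_subsample_fraction=pair_subsample_fraction, seed=seed
    )
    _check_identified(table, pairs)
    m = table.X.shape[1]
    beta = np.zeros(m) if init is None else np.asarray(init, dtype=float).copy()

    ll, grad, hess = composite_loglik(table, beta, pairs, block_size)
    trace = [(0, ll, float(np.abs(grad).max()))]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(-hess, grad)
        # step halving on the concave objective
        lam = 1.0
        for _ in range(40):
            cand = beta + lam * step
            ll_new, grad_new, hess_new = composite_loglik(
                table, cand, pairs, block_size
            )
            if ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                break
            lam *= 0.5
        rel_change = abs(ll_new - ll) / max(1.0, abs(ll))
        beta, grad, hess = cand, grad_new, hess_new
        ll_prev, ll = ll, ll_new
        trace.append((it, ll, float(np.abs(grad).max())))
        if np.abs(grad).max() / max(pairs.n_pairs, 1) < tol or rel_change < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"pairwise fit did not converge in {max_iter} Newton iterations",
            trace=trace,
        )

    if compute_cov:
        if cov_method == "jackknife":
            cov = jackknife_cov(table, beta, pairs=pairs, block_size=block_size)
        else:
            cov = sandwich_cov(table, beta, pairs=pairs, block_size=block_size)
        se = np.sqrt(np.diag(cov))
        z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    else:
        cov = np.full((m, m), np.nan)
        se = np.full(m, np.nan)
        pvals = np.full(m, np.nan)

    return Stage2Result(
        beta=beta,
        cov=cov,
        se=se,
        z_p_values=pvals,
        n_pairs=pairs.n_pairs,
        loglik=ll,
        converged=converged,
        iterations=it,
        columns=table.columns,
    )


def sandwich_cov(
    table: AnalysisTable,
    beta,
    pairs: PairIndex | None = None,
    block_size: int = _DEFAULT_BLOCK,
) -> np.ndarray:
    """Godambe sandwich H⁻¹ V H⁻¹ clustered by subject.

    H is minus the Hessian of log L at β̂; V = Σ_i S_i S_iᵀ where S_i sums
    the pair scores of every pair containing subject i (the empirical
    projection of the U-statistic score onto subjects, which accounts for
    the dependence of pairs sharing a subject).
    """
    table = _drop_intercept(table)
    if pairs is None:
        pairs = enumerate_pairs(table)
    _, _, hess = composite_loglik(table, beta, pairs, block_size)
    H = -hess
    S = _pair_scores_by_subject(table, beta, pairs, block_size)
    V = S.T @ S
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise UnidentifiedModelError(
            "sensitivity matrix is singular at the supplied beta"
        ) from exc
    return Hinv @ V @ Hinv


def jackknife_cov(
    table: AnalysisTable,
    beta,
    pairs: PairIndex | None = None,
    block_size: int = _DEFAULT_BLOCK,
    max_iter: int = 25,
) -> np.ndarray:
    """Delete-one-subject jackknife covariance of the pairwise estimator.

    For every subject, the composite likelihood is re-maximized exactly on
    the pairs not involving that subject (Newton warm-started at the full
    estimate), and the Tukey jackknife covariance of the leave-one-out
    estimates is returned.  More expensive than the Godambe sandwich but
    markedly better calibrated when a covariate's identification rests on
    few subjects; see the methods note.
    """
    table = _drop_intercept(table)
    beta = np.asarray(beta, dtype=float)
    if pairs is None:
        pairs = enumerate_pairs(table)
    subj = table.subject_index
    G = table.n_subjects
    loo = np.empty((G, beta.size))
    for i in range(G):
        keep = (subj[pairs.a] != i) & (subj[pairs.b] != i)
        sub = PairIndex(
            a=pairs.a[keep], b=pairs.b[keep], n_pairs=int(keep.sum()),
            n_subject_pairs=max(pairs.n_subject_pairs - (G - 1), 1),
        )
        b_i = beta.copy()
        ll, grad, hess = composite_loglik(table, b_i, sub, block_size)
        for _ in range(max_iter):
            step = np.linalg.solve(-hess, grad)
            b_i = b_i + step
            ll_new, grad, hess = composite_loglik(table, b_i, sub, block_size)
            if abs(ll_new - ll) <= 1e-10 * max(1.0, abs(ll)):
                break
            ll = ll_new
        loo[i] = b_i
    centered = loo - loo.mean(axis=0)
    return (G - 1) / G * (centered.T @ centered)
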