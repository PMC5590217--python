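"""Conditional logistic regression for 1:M matched strata.

The conditional likelihood of a matched stratum with case row x1 and
control rows x2..x(M+1) is

    exp(theta . x1) / sum_{j=1}^{M+1} exp(theta . xj),

i.e. a within-stratum softmax that eliminates stratum intercepts.
Pooled strata (sums of design rows over g matched sets) plug into the
same likelihood unchanged, which is what makes aggregate-only data
analyzable at a coordinating center.

Maximization is Newton-Raphson with analytic gradient and Hessian and
step-halving; the likelihood is concave, so with p of order 10 this
converges in a handful of iterations.  All within-stratum exponentials
go through log-sum-exp with max-subtraction -- pooled covariates are g
times larger in scale, so naive exponentials would overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2, norm

from .matched_data import MatchedStratum, ModelSpec, design_matrix
from .pooling import PooledStratum

__all__ = [
    "CLStratum",
    "FitResult",
    "NonIdentifiableError",
    "strata_from_matched",
    "strata_from_pooled",
    "loglik",
    "score_and_hessian",
    "fit",
    "wald_ci",
    "lrt",
    "aic",
]


class NonIdentifiableError(ValueError):
    """No within-stratum contrast in some direction: the MLE is undefined."""


@dataclass(frozen=True)
class CLStratum:
    """One likelihood term: a case row and M control rows of length p."""

    case_row: np.ndarray
    control_rows: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        p = len(self.case_row)
        if not self.control_rows:
            raise ValueError("at least one control row required")
        if any(len(r) != p for r in self.control_rows):
            raise ValueError("case and control rows must share length")

    @property
    def m(self) -> int:
        return len(self.control_rows)


@dataclass(frozen=True)
class FitResult:
    estimates: np.ndarray
    covariance: np.ndarray
    standard_errors: np.ndarray
    loglik: float
    n_strata: int
    converged: bool
    n_iter: int
    term_names: tuple[str, ...]

    @property
    def p(self) -> int:
        return len(self.estimates)

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.estimates)


# ---------------------------------------------------------------------------
# constructors


def strata_from_matched(strata: Sequence[MatchedStratum], spec: ModelSpec) -> list[CLStratum]:
    """Design rows for individual-level (unpooled) matched strata."""
    X = design_matrix(strata, spec)
    return [
        CLStratum(case_row=X[i, 0], control_rows=tuple(X[i, 1:]))
        for i in range(X.shape[0])
    ]


def strata_from_pooled(pooled: Iterable[PooledStratum]) -> list[CLStratum]:
    """Pooled aggregates mapped onto likelihood strata, order preserved."""
    return [
        CLStratum(case_row=ps.case_aggregate, control_rows=ps.control_aggregates)
        for ps in pooled
    ]


def _pack(strata: Sequence[CLStratum]) -> list[np.ndarray]:
    """Stack strata into (n, M+1, p) blocks, one block per distinct M."""
    if not strata:
        raise ValueError("no strata")
    p = len(strata[0].case_row)
    groups: dict[int, list[np.ndarray]] = {}
    for s in strata:
        if len(s.case_row) != p:
            raise ValueError("strata disagree on number of terms")
        rows = np.vstack([s.case_row, *s.control_rows])
        groups.setdefault(s.m, []).append(rows)
    return [np.asarray(g) for g in groups.values()]


# ---------------------------------------------------------------------------
# likelihood, score, information


def _block_loglik(theta: np.ndarray, X: np.ndarray) -> float:
    eta = X @ theta  # (n, M+1); index 0 is the case
    return float(np.sum(eta[:, 0] - logsumexp(eta, axis=1)))


def loglik(theta: np.ndarray, strata: Sequence[CLStratum]) -> float:
    """Conditional log-likelihood, log-sum-exp stabilized."""
    theta = np.asarray(theta, dtype=float)
    blocks = _pack(strata)
    if theta.shape != (blocks[0].shape[2],):
        raise ValueError(
            f"theta has length {theta.size}, rows have length {blocks[0].shape[2]}"
        )
    return sum(_block_loglik(theta, X) for X in blocks)


def score_and_hessian(
    theta: np.ndarray, strata: Sequence[CLStratum]
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient and Hessian of the conditional log-likelihood.

    Per stratum the gradient is (case row minus the softmax-weighted mean
    row) and the Hessian is minus the softmax-weighted covariance of the
    rows, so the Hessian is symmetric negative semidefinite everywhere.
    """
    theta = np.asarray(theta, dtype=float)
    blocks = _pack(strata)
    p = blocks[0].shape[2]
    if theta.shape != (p,):
        raise ValueError(f"theta has length {theta.size}, rows have length {p}")
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for X in blocks:
        eta = X @ theta
        w = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))  # (n, M+1)
        mu = np.einsum("nj,njp->np", w, X)  # within-stratum mean row
        grad += np.sum(X[:, 0, :] - mu, axis=0)
        s2 = np.einsum("nj,njp,njq->pq", w, X, X)
        hess -= s2 - mu.T @ mu
    hess = 0.5 * (hess + hess.T)  # enforce exact symmetry
    return grad, hess


# ---------------------------------------------------------------------------
# fitting


def fit(
    strata: Sequence[CLStratum],
    term_names: Sequence[str] | None = None,
    grad_tol: float = 1e-8,
    rel_ll_tol: float = 1e-12,
    max_iter: int = 100,
    theta_bound: float = 1e3,
) -> FitResult:
    """Maximum likelihood via Newton-Raphson with step-halving from 0.

    Raises :class:`NonIdentifiableError` when some direction has no
    within-stratum contrast (zero information at the origin).  Complete
    separation -- estimates drifting without bound or a non-invertible
    Hessian away from the origin -- yields ``converged=False`` rather
    than a clipped answer.
    """
    blocks = _pack(strata)
    p = blocks[0].shape[2]
    n = sum(X.shape[0] for X in blocks)
    names = tuple(term_names) if term_names is not None else tuple(f"x{i}" for i in range(p))
    if len(names) != p:
        raise ValueError("term_names length must match row length")

    theta = np.zeros(p)
    grad, hess = score_and_hessian(theta, strata)
    # information at the origin is the pooled within-stratum covariance;
    # a (near-)zero eigenvalue means some term never varies within strata
    eig = np.linalg.eigvalsh(-hess)
    if eig[-1] <= 0 or eig[0] <= 1e-10 * max(eig[-1], 1.0):
        raise NonIdentifiableError(
            "no within-stratum contrast in some direction; "
            "conditional MLE is not identified"
        )
    eig0_min = eig[0]

    ll = loglik(theta, strata)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break  # information lost along the path: separation
        # step-halving keeps the ascent monotone
        t, ll_new = 1.0, -np.inf
        for _ in range(40):
            cand = theta + t * step
            ll_new = loglik(cand, strata)
            if ll_new >= ll - 1e-14 * abs(ll):
                break
            t *= 0.5
        theta = theta + t * step
        if np.max(np.abs(theta)) > theta_bound:
            break  # drifting without bound: separation
        ll_prev, ll = ll, ll_new
        grad, hess = score_and_hessian(theta, strata)
        if np.max(np.abs(grad)) < grad_tol or abs(ll - ll_prev) < rel_ll_tol * (abs(ll) + 1.0):
            converged = True
            break

    if converged:
        # under (quasi-)separation the score vanishes at a finite iterate
        # while the likelihood supremum is only approached; the tell is the
        # observed information collapsing relative to the origin
        eig_hat = np.linalg.eigvalsh(-hess)
        if (
            np.max(np.abs(theta)) > theta_bound
            or eig_hat[0] <= 0
            or eig_hat[0] < 1e-6 * eig0_min
        ):
            converged = False
    if converged:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(cov))
    else:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
    return FitResult(
        estimates=theta,
        covariance=cov,
        standard_errors=se,
        loglik=ll,
        n_strata=n,
        converged=converged,
        n_iter=it,
        term_names=names,
    )


# ---------------------------------------------------------------------------
# inference


def wald_ci(result: FitResult, level: float = 0.95) -> np.ndarray:
    """Per-term Wald intervals, shape (p, 2): estimate +/- z * SE."""
    if not result.converged:
        raise ValueError("confidence intervals require a converged fit")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 * (1.0 + level))
    half = z * result.standard_errors
    return np.column_stack([result.estimates - half, result.estimates + half])


def lrt(fit_full: FitResult, fit_reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood ratio test of nested models fit to the same strata."""
    if not set(fit_reduced.term_names) <= set(fit_full.term_names):
        raise ValueError(
            "reduced model terms must be a subset of the full model terms"
        )
    if fit_full.n_strata != fit_reduced.n_strata:
        raise ValueError("models were fit to different numbers of strata")
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    df = fit_full.p - fit_reduced.p
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(chi2.sf(stat, df))


def aic(result: FitResult) -> float:
    """Akaike information criterion: -2 loglik + 2 p."""
    if not result.converged:
        raise ValueError("AIC requires a converged fit")
    return -2.0 * result.loglik + 2.0 * result.p
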