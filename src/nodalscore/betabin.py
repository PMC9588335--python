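"""Beta-binomial model of positive-node counts.

The number of positive nodes ``k`` among ``n`` examined is modelled as
binomial with a per-patient success probability ``p`` drawn from a
Beta(alpha, beta) law; integrating ``p`` out gives the beta-binomial

    P(k | n) = C(n, k) * B(k + alpha, n - k + beta) / B(alpha, beta).

Two quantities drive the nodal staging score downstream:

* the false-negative staging probability ``p0(n) = P(0 | n)`` — the chance
  that a truly node-positive patient shows no positive node among ``n``
  examined, and
* the shape parameters ``(alpha, beta)`` fitted by maximum likelihood on
  node-positive patients only, i.e. with a zero-truncated likelihood
  conditioned on ``k >= 1``.

All probability evaluation is done in log space through ``gammaln`` /
``betaln`` for numerical stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, gammaln

__all__ = [
    "BetaBinParams",
    "FitResult",
    "betabin_pmf",
    "betabin_logpmf",
    "staging_fn_prob",
    "truncated_loglik",
    "untruncated_loglik",
    "fit_truncated",
]


@dataclass(frozen=True)
class BetaBinParams:
    """Shape parameters of the beta-binomial positive-node model.

    Both shapes must be finite and strictly positive.  The latent
    per-patient binomial probability is integrated out analytically and is
    not stored.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"{name} must be a finite positive real, got {v!r}"
                )
        object.__setattr__(self, "alpha", float(self.alpha))
        object.__setattr__(self, "beta", float(self.beta))


@dataclass(frozen=True)
class FitResult:
    """Outcome of the zero-truncated maximum-likelihood fit."""

    params: BetaBinParams
    loglik: float
    converged: bool
    n_patients: int
    iterations: int
    stderr_alpha: float | None = None
    stderr_beta: float | None = None
    message: str = ""


def _validate_kn(k: np.ndarray, n: np.ndarray, *, min_k: int = 0) -> None:
    if np.any(n < 1):
        raise ValueError("examined-node count n must be >= 1")
    if np.any(k < min_k):
        raise ValueError(f"positive-node count k must be >= {min_k}")
    if np.any(k > n):
        raise ValueError("positive-node count k cannot exceed examined count n")


def betabin_logpmf(k, n, params: BetaBinParams):
    """Log of the beta-binomial pmf, elementwise over ``k`` and ``n``."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k < 0) or np.any(n < 1) or np.any(k > n):
        raise ValueError("require 0 <= k <= n and n >= 1")
    a, b = params.alpha, params.beta
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )


def betabin_pmf(k, n, params: BetaBinParams):
    """Beta-binomial probability mass P(k positive | n examined)."""
    return np.exp(betabin_logpmf(k, n, params))


def staging_fn_prob(n, params: BetaBinParams):
    """False-negative staging probability p0(n).

    The probability that a truly node-positive patient shows zero positive
    nodes among ``n`` examined:

        p0(n) = B(alpha, beta + n) / B(alpha, beta)
              = prod_{i=0}^{n-1} (beta + i) / (alpha + beta + i).

    Strictly decreasing in ``n``; ``p0(0) = 1`` (no nodes examined means
    staging is always negative).  Accepts scalars or arrays.
    """
    n_arr = np.asarray(n)
    if np.any(n_arr < 0):
        raise ValueError("examined-node count n must be >= 0")
    a, b = params.alpha, params.beta
    out = np.exp(betaln(a, b + n_arr.astype(float)) - betaln(a, b))
    if np.ndim(n) == 0:
        return float(out)
    return out


def _as_kn_arrays(records: Iterable[tuple[int, int]] | np.ndarray):
    arr = np.asarray(list(records) if not isinstance(records, np.ndarray) else records)
    if arr.size == 0:
        raise ValueError("no records supplied")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("records must be (k, n) pairs")
    return arr[:, 0].astype(float), arr[:, 1].astype(float)


def truncated_loglik(params: BetaBinParams, records) -> float:
    """Zero-truncated log-likelihood over (k, n) pairs with k >= 1.

    Each node-positive patient contributes
    ``log P(k | n) - log(1 - p0(n))``: the fitting set is conditioned on
    observing at least one positive node, so the zero class is removed from
    the sample space.
    """
    k, n = _as_kn_arrays(records)
    _validate_kn(k, n, min_k=1)
    logpmf = betabin_logpmf(k, n, params)
    p0 = staging_fn_prob(n, params)
    # complementary accumulation when p0 ~ 1: expm1 of the log keeps
    # 1 - p0 accurate for tiny alpha
    a, b = params.alpha, params.beta
    log_p0 = betaln(a, b + n) - betaln(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        log1m_p0 = np.where(
            p0 > 0.99, np.log(-np.expm1(log_p0)), np.log1p(-p0)
        )
    # each term is a conditional log-probability, hence <= 0
    return float(np.sum(np.minimum(logpmf - log1m_p0, 0.0)))


def untruncated_loglik(params: BetaBinParams, records) -> float:
    """Plain beta-binomial log-likelihood (no zero-truncation).

    Diagnostic only: fitting node-positive patients requires the truncated
    form in :func:`truncated_loglik`.
    """
    k, n = _as_kn_arrays(records)
    _validate_kn(k, n, min_k=0)
    return float(np.sum(betabin_logpmf(k, n, params)))


def _moment_start(k: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Method-of-moments start from the per-patient positive fractions.

    Ignores truncation — it only needs to land in the right basin.
    """
    r = k / n
    m, v = float(np.mean(r)), float(np.var(r))
    if v <= 1e-12 or not 0 < m < 1:
        return 1.0, 1.0
    c = m * (1 - m) / v - 1
    if c <= 0:
        return 1.0, 1.0
    return max(m * c, 1e-2), max((1 - m) * c, 1e-2)


_LOG_BOUND = 12.0  # |log shape| cap; beyond this the surface is flat


def fit_truncated(
    records,
    *,
    starts: Sequence[tuple[float, float]] | None = None,
    gtol: float = 1e-8,
    compute_stderr: bool = True,
) -> FitResult:
    """Maximize the zero-truncated likelihood over (alpha, beta).

    Optimization runs unconstrained in ``(log alpha, log beta)`` (L-BFGS-B
    with wide box bounds) from three starts: method-of-moments, (1, 1) and
    an overdispersed fallback.  The result is invariant to record order and
    to duplicating every record.

    Raises ``ValueError`` when every record has ``n = 1``: those patients
    carry no information about the shapes (P(k=1 | k>=1, n=1) = 1 for any
    parameters), so the likelihood is flat and the fit non-identifiable.
    """
    k, n = _as_kn_arrays(records)
    _validate_kn(k, n, min_k=1)
    if len(k) < 2:
        raise ValueError("need at least 2 records to fit")
    if np.all(n == 1):
        raise ValueError(
            "all records have n=1: zero-truncated likelihood is flat, "
            "parameters are non-identifiable"
        )

    # aggregate duplicate (k, n) pairs: likelihood is a weighted sum
    pairs, counts = np.unique(np.column_stack([k, n]), axis=0, return_counts=True)
    ku, nu, w = pairs[:, 0], pairs[:, 1], counts.astype(float)

    def neg_loglik(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        p = BetaBinParams(a, b)
        logpmf = betabin_logpmf(ku, nu, p)
        log_p0 = betaln(a, b + nu) - betaln(a, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            log1m_p0 = np.where(
                log_p0 > -0.0101,
                np.log(-np.expm1(log_p0)),
                np.log1p(-np.exp(log_p0)),
            )
        terms = w * (logpmf - log1m_p0)
        if not np.all(np.isfinite(terms)):
            # extreme shapes where 1 - p0 underflows: likelihood ~ 0
            return 1e300
        return -float(np.sum(terms))

    if starts is None:
        starts = [_moment_start(k, n), (1.0, 1.0), (2.0, 0.5)]

    best = None
    for a0, b0 in starts:
        res = minimize(
            neg_loglik,
            x0=np.log([a0, b0]),
            method="L-BFGS-B",
            bounds=[(-_LOG_BOUND, _LOG_BOUND)] * 2,
            options={"gtol": gtol, "ftol": 1e-14, "maxiter": 500},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("optimizer failed from every start")

    theta = best.x
    at_boundary = bool(np.any(np.abs(theta) >= _LOG_BOUND - 1e-3))
    converged = bool(best.success) and not at_boundary
    alpha, beta = np.exp(theta)
    params = BetaBinParams(alpha, beta)
    message = best.message if isinstance(best.message, str) else str(best.message)
    if at_boundary:
        message = "estimate at parameter-space boundary (degenerate data?); " + message
        warnings.warn(message, RuntimeWarning, stacklevel=2)

    se_a = se_b = None
    if compute_stderr and converged:
        se_a, se_b = _observed_info_stderr(neg_loglik, theta)

    return FitResult(
        params=params,
        loglik=-float(best.fun),
        converged=converged,
        n_patients=int(len(k)),
        iterations=int(best.nit),
        stderr_alpha=se_a,
        stderr_beta=se_b,
        message=message,
    )


def _observed_info_stderr(neg_loglik, theta: np.ndarray, h: float = 1e-4):
    """Delta-method standard errors for (alpha, beta) from the observed
    information of the log-parameterized negative log-likelihood."""
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            e_i = np.eye(2)[i] * h
            e_j = np.eye(2)[j] * h
            H[i, j] = (
                neg_loglik(theta + e_i + e_j)
                - neg_loglik(theta + e_i - e_j)
                - neg_loglik(theta - e_i + e_j)
                + neg_loglik(theta - e_i - e_j)
            ) / (4 * h * h)
    try:
        cov_log = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None, None
    if np.any(np.diag(cov_log) <= 0):
        return None, None
    # var(shape) = shape^2 * var(log shape)
    se = np.exp(theta) * np.sqrt(np.diag(cov_log))
    return float(se[0]), float(se[1])
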