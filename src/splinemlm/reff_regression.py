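"""Mutually adjusted regression coefficients among random effects.

The individual-level covariance matrix G of a fitted growth model encodes
every association between baseline levels (random intercepts) and period
rates of change (random slopes).  Regressing one random effect on a set of
p others amounts to solving the normal equations

    Sigma beta = sigma_0,

where Sigma is the p x p covariance of the predictor effects and sigma_0
the p-vector of covariances between the outcome effect and each predictor.
With a single predictor this reduces to beta = cov / var.

Standard errors for beta come from three methods:

1. *Moment*: treat the entries of G as sample moments of n observed
   random-effect vectors, giving the textbook multiple-regression formula
   SE_j = sqrt(s^2 d_j / (n - p - 1)), with s^2 the residual variance
   sigma_00 - sigma_0' Sigma^-1 sigma_0 and d_j the j-th diagonal of
   Sigma^-1.  This ignores that G is itself estimated, so its intervals
   are too narrow.
2. *Delta*: first-order propagation of the sampling covariance Gamma of
   the unique entries of G through the map G -> beta, using the analytic
   differential d beta = Sigma^-1 (d sigma_0 - d Sigma beta).
3. *Simulation*: draw q realisations of vech(G) from N(vech(G-hat), Gamma),
   re-solve for beta in each, and report the mean and percentile interval.

All coefficients are computed and stored in natural units; per-unit
reporting rescales (e.g. per 10 kg, per 0.4 kg/week) are applied only when
formatting tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import RandomEffectIndex, vech_indices, vech_position

__all__ = [
    "AdjustmentQuery",
    "AdjustedRegression",
    "coefficients",
    "se_method1",
    "se_method2_delta",
    "se_method3_simulate",
    "correlation_matrix",
    "adjusted_regression",
]


@dataclass(frozen=True)
class AdjustmentQuery:
    """Which random effect to regress on which others.

    ``scale_factors`` maps predictor effects to reporting multipliers:
    a factor c reports the outcome difference per c natural units of that
    predictor (coefficient times c).  Scaling never enters estimation.
    """

    outcome: RandomEffectIndex
    predictors: tuple
    scale_factors: Mapping | None = None

    def __post_init__(self) -> None:
        preds = tuple(self.predictors)
        object.__setattr__(self, "predictors", preds)
        if len(preds) < 1:
            raise ValueError("need at least one predictor")
        if len(set(preds)) != len(preds):
            raise ValueError("predictors must be distinct")
        if self.outcome in preds:
            raise ValueError("outcome cannot be among the predictors")

    @property
    def p(self) -> int:
        return len(self.predictors)


def _resolve(effects: Sequence[RandomEffectIndex], query: AdjustmentQuery):
    pos = {e: i for i, e in enumerate(effects)}
    try:
        o = pos[query.outcome]
        P = [pos[e] for e in query.predictors]
    except KeyError as e:
        raise KeyError(f"random effect {e.args[0]} not in this model") from None
    return o, P


def _sigma_blocks(G: np.ndarray, o: int, P: list):
    Sigma = G[np.ix_(P, P)]
    sigma0 = G[P, o]
    return Sigma, sigma0


def _solve_checked(Sigma: np.ndarray, sigma0: np.ndarray, query: AdjustmentQuery):
    cond = np.linalg.cond(Sigma)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"predictor covariance matrix is singular or near-singular "
            f"(condition number {cond:.2e}); predictors "
            f"{[str(e) for e in query.predictors]} are collinear"
        )
    return np.linalg.solve(Sigma, sigma0)


def coefficients(
    G: np.ndarray, query: AdjustmentQuery, effects: Sequence[RandomEffectIndex]
) -> np.ndarray:
    """Solve Sigma beta = sigma_0 for the mutually adjusted coefficients.

    Returns the coefficients in natural units, ordered as
    ``query.predictors``.
    """
    o, P = _resolve(effects, query)
    Sigma, sigma0 = _sigma_blocks(np.asarray(G, dtype=float), o, P)
    return _solve_checked(Sigma, sigma0, query)


def se_method1(
    G: np.ndarray,
    query: AdjustmentQuery,
    effects: Sequence[RandomEffectIndex],
    n: int,
) -> np.ndarray:
    """Moment-based standard errors (as if G were sample moments of n draws).

    Matches an ordinary multiple-regression fit exactly when G holds the
    ddof=1 sample covariance of a concrete sample of n random-effect
    vectors.
    """
    o, P = _resolve(effects, query)
    p = len(P)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n = {n}, p = {p})")
    G = np.asarray(G, dtype=float)
    Sigma, sigma0 = _sigma_blocks(G, o, P)
    beta = _solve_checked(Sigma, sigma0, query)
    s2 = G[o, o] - sigma0 @ beta
    if s2 < -1e-10 * max(G[o, o], 1.0):
        raise ValueError(
            f"negative residual variance ({s2:.3e}); G is not positive "
            "semidefinite on the queried block"
        )
    s2 = max(s2, 0.0)
    d = np.diag(np.linalg.inv(Sigma))
    return np.sqrt(s2 * d / (n - p - 1))


def _beta_jacobian(
    G: np.ndarray, o: int, P: list, beta: np.ndarray
) -> np.ndarray:
    """Jacobian of beta wrt vech(G) (all M(M+1)/2 unique entries).

    Uses d beta = Sigma^-1 (d sigma_0 - d Sigma beta) entry by entry; the
    derivative is zero for entries not touching the outcome/predictor block.
    """
    M = G.shape[0]
    Sigma, _ = _sigma_blocks(G, o, P)
    Sigma_inv = np.linalg.inv(Sigma)
    p = len(P)
    V = M * (M + 1) // 2
    J = np.zeros((p, V))
    posP = {idx: a for a, idx in enumerate(P)}
    for k, (i, j) in enumerate(vech_indices(M)):
        dsigma0 = np.zeros(p)
        dSigma = np.zeros((p, p))
        # d sigma_0: entries (pred, outcome)
        if i == o and j in posP:
            dsigma0[posP[j]] += 1.0
        elif j == o and i in posP:
            dsigma0[posP[i]] += 1.0
        elif i == o and j == o:
            pass  # outcome variance does not enter beta
        # d Sigma: entries (pred, pred)
        if i in posP and j in posP:
            a, b = posP[i], posP[j]
            dSigma[a, b] += 1.0
            if a != b:
                dSigma[b, a] += 1.0
        if dsigma0.any() or dSigma.any():
            J[:, k] = Sigma_inv @ (dsigma0 - dSigma @ beta)
    return J


def _ensure_psd(Gamma: np.ndarray, what: str = "Gamma") -> np.ndarray:
    Gamma = 0.5 * (Gamma + Gamma.T)
    w = np.linalg.eigvalsh(Gamma)
    if w[0] < -1e-10 * max(w[-1], 1.0):
        warnings.warn(
            f"{what} is not positive semidefinite (min eigenvalue {w[0]:.2e}); "
            "projecting to the nearest PSD matrix by eigenvalue clipping"
        )
        vals, vecs = np.linalg.eigh(Gamma)
        Gamma = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        Gamma = 0.5 * (Gamma + Gamma.T)
    return Gamma


def se_method2_delta(
    G: np.ndarray,
    Gamma: np.ndarray,
    query: AdjustmentQuery,
    effects: Sequence[RandomEffectIndex],
) -> np.ndarray:
    """Delta-method standard errors: sqrt(diag(J Gamma J')) with J the
    analytic Jacobian of beta with respect to vech(G)."""
    G = np.asarray(G, dtype=float)
    M = G.shape[0]
    V = M * (M + 1) // 2
    Gamma = np.asarray(Gamma, dtype=float)
    if Gamma.shape != (V, V):
        raise ValueError(f"Gamma must be {V}x{V} (vech of G), got {Gamma.shape}")
    Gamma = _ensure_psd(Gamma)
    o, P = _resolve(effects, query)
    Sigma, sigma0 = _sigma_blocks(G, o, P)
    beta = _solve_checked(Sigma, sigma0, query)
    J = _beta_jacobian(G, o, P, beta)
    cov_beta = J @ Gamma @ J.T
    return np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))


def se_method3_simulate(
    G: np.ndarray,
    Gamma: np.ndarray,
    query: AdjustmentQuery,
    effects: Sequence[RandomEffectIndex],
    q: int = 10_000,
    seed: int | None = None,
    ci_percentiles: tuple = (2.5, 97.5),
):
    """Simulation-based inference for the adjusted coefficients.

    Draws ``q`` realisations of vech(G) from N(vech(G-hat), Gamma), re-solves
    Sigma beta = sigma_0 for each, and summarises by the elementwise mean
    (``beta_sim``) and percentile confidence limits.  Draws in which the
    realised predictor block is not positive definite are skipped and
    counted; more than 50% skips aborts, since then the normal approximation
    to the sampling distribution of the (co)variances is untrustworthy (a
    large-sample method).

    Returns ``(beta_sim, (lo, hi), n_skipped)``.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    if q < 1000:
        warnings.warn(f"q = {q} is small; percentile intervals will be noisy")
    G = np.asarray(G, dtype=float)
    M = G.shape[0]
    V = M * (M + 1) // 2
    Gamma = _ensure_psd(np.asarray(Gamma, dtype=float))
    o, P = _resolve(effects, query)
    nu = np.array([G[i, j] for i, j in vech_indices(M)])

    rng = np.random.default_rng(seed)
    vals, vecs = np.linalg.eigh(Gamma)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    draws = nu[None, :] + rng.standard_normal((q, V)) @ L.T  # (q, V)

    # rebuild the (outcome + predictors) submatrix per draw
    sub = [o] + P
    k = len(sub)
    Gsub = np.empty((q, k, k))
    for a in range(k):
        for b in range(a, k):
            col = vech_position(M, sub[a], sub[b])
            Gsub[:, a, b] = Gsub[:, b, a] = draws[:, col]
    Sig = Gsub[:, 1:, 1:]
    sig0 = Gsub[:, 1:, 0]
    # PD check on the predictor block via eigenvalues
    w = np.linalg.eigvalsh(Sig)
    ok = w[:, 0] > 1e-12 * np.maximum(w[:, -1], 1.0)
    n_skipped = int(q - ok.sum())
    if n_skipped > q / 2:
        raise RuntimeError(
            f"{n_skipped}/{q} draws produced a non-PD predictor covariance; "
            "Gamma is too large relative to G for the multivariate-normal "
            "approximation (simulation inference needs large samples)"
        )
    betas = np.linalg.solve(Sig[ok], sig0[ok][:, :, None])[:, :, 0]  # (q_ok, p)
    beta_sim = betas.mean(axis=0)
    lo, hi = np.percentile(betas, ci_percentiles, axis=0)
    return beta_sim, (lo, hi), n_skipped


def correlation_matrix(G: np.ndarray) -> np.ndarray:
    """Correlations implied by a covariance matrix; unit diagonal.

    Zero (or negative) variances make the corresponding correlations
    undefined; those entries are returned as NaN with a warning.
    """
    G = np.asarray(G, dtype=float)
    d = np.diag(G).copy()
    bad = d <= 0
    if bad.any():
        warnings.warn(
            f"zero or negative variance at position(s) {np.flatnonzero(bad).tolist()}; "
            "correlations there are undefined (NaN)"
        )
        d = np.where(bad, np.nan, d)
    s = np.sqrt(d)
    C = G / np.outer(s, s)
    np.fill_diagonal(C, np.where(bad, np.nan, 1.0))
    return C


@dataclass
class AdjustedRegression:
    """Adjusted coefficients with per-method standard errors and CIs."""

    query: AdjustmentQuery
    effects: list
    beta: np.ndarray
    se: dict = field(default_factory=dict)  # method -> p-vector
    ci: dict = field(default_factory=dict)  # method -> (lo, hi)
    beta_sim: np.ndarray | None = None
    n: int | None = None
    q: int | None = None
    seed: int | None = None
    n_skipped: int = 0

    def table(self, level: float = 0.95) -> pd.DataFrame:
        """Reporting table; scale factors from the query are applied here."""
        factors = np.ones(self.query.p)
        if self.query.scale_factors:
            for a, e in enumerate(self.query.predictors):
                factors[a] = self.query.scale_factors.get(e, 1.0)
        rows = []
        for a, e in enumerate(self.query.predictors):
            row = {"predictor": str(e), "beta": self.beta[a] * factors[a]}
            for method, se in self.se.items():
                lo, hi = self.ci[method]
                row[f"se_{method}"] = se[a] * factors[a]
                row[f"lo_{method}"] = lo[a] * factors[a]
                row[f"hi_{method}"] = hi[a] * factors[a]
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def query_p(self) -> int:
        return self.query.p


def adjusted_regression(
    fitted,
    query: AdjustmentQuery,
    methods: Sequence[str] = ("moment", "delta", "simulate"),
    q: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
) -> AdjustedRegression:
    """Run the full adjusted-regression analysis on a fitted model.

    ``fitted`` is a :class:`~splinemlm.mlm_core.FittedMLM` (anything with
    ``G``, ``gamma``, ``effects`` and ``n_individuals`` works).
    """
    G, Gamma, effects = fitted.G, fitted.gamma, fitted.effects
    beta = coefficients(G, query, effects)
    z = stats.norm.ppf(0.5 + level / 2)
    out = AdjustedRegression(query=query, effects=list(effects), beta=beta, n=fitted.n_individuals)
    if "moment" in methods:
        se1 = se_method1(G, query, effects, n=fitted.n_individuals)
        out.se["moment"] = se1
        out.ci["moment"] = (beta - z * se1, beta + z * se1)
    if "delta" in methods:
        se2 = se_method2_delta(G, Gamma, query, effects)
        out.se["delta"] = se2
        out.ci["delta"] = (beta - z * se2, beta + z * se2)
    if "simulate" in methods:
        pcts = (100 * (0.5 - level / 2), 100 * (0.5 + level / 2))
        beta_sim, (lo, hi), n_skipped = se_method3_simulate(
            G, Gamma, query, effects, q=q, seed=seed, ci_percentiles=pcts
        )
        out.beta_sim = beta_sim
        out.q = q
        out.seed = seed
        out.n_skipped = n_skipped
        # a symmetric-equivalent SE from the percentile interval width
        out.se["simulate"] = (hi - lo) / (2 * z)
        out.ci["simulate"] = (lo, hi)
    return out
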