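"""Maximum-likelihood fitting of multivariate linear-spline multilevel models.

The model: repeated measurements of one or more responses are nested in
individuals.  For individual k the stacked observation vector is

    y_k = X_k beta + Z_k u_k + e_k,
    u_k ~ N(0, G),   e_k ~ N(0, R_k),

where X_k holds per-response intercept, spline-basis and covariate columns,
Z_k holds the intercept indicator and spline basis of each row's response,
G is the individual-level covariance of the random intercepts and period
slopes of all responses, and R_k is the occasion-level residual covariance:
each row gets its response's residual variance, and two rows of different
responses measured at the same occasion time share a cross-response
residual covariance (homogeneous over time).

Estimation is straight ML.  The likelihood is profiled over the fixed
effects (GLS given the variance parameters), and the free unique entries of
G — entries fixed to zero by a :class:`~splinemlm.hypotheses.ConstraintSet`
stay hard zeros — plus the unique entries of the occasion-level covariance
are optimised by L-BFGS-B with an analytic score.  Positive-definiteness is
enforced implicitly: parameter values for which any individual's marginal
covariance fails its Cholesky factorisation are rejected with a penalty, so
the line search backtracks into the feasible region.

The sampling covariance Gamma of the (co)variance estimates — needed by the
delta-method and simulation standard errors for derived regression
coefficients — is the inverse observed information of the profile
likelihood at the optimum, obtained by central differences of the analytic
score, reported on the raw covariance scale.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effects import (
    RandomEffectIndex,
    effect_order,
    vech_indices,
    vech_position,
)
from .hypotheses import ConstraintSet
from .spline_basis import SplineSpec, evaluate_basis

__all__ = [
    "LongData",
    "ModelSpec",
    "FittedMLM",
    "LRTResult",
    "CovarianceNotPD",
    "log_likelihood",
    "fit",
    "lrt",
    "lrt_from_deviances",
    "predict_random_effects",
    "individual_moments",
]

_PENALTY = 1e12


class CovarianceNotPD(ArithmeticError):
    """A covariance matrix required to be positive definite is not."""


# ---------------------------------------------------------------------------
# data containers


@dataclass
class LongData:
    """Tidy long-format repeated measures: one row per
    (individual, occasion time, response).

    ``df`` must have columns ``individual``, ``time``, ``response``,
    ``value``; any further columns are individual-level (time-constant)
    covariates.
    """

    df: pd.DataFrame

    REQUIRED = ("individual", "time", "response", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"LongData missing required columns {missing}")
        dup = self.df.duplicated(subset=["individual", "time", "response"])
        if dup.any():
            bad = self.df.loc[dup, ["individual", "time", "response"]].head()
            raise ValueError(
                f"duplicate (individual, time, response) rows, e.g.\n{bad}"
            )
        for c in self.covariate_names:
            per_ind = self.df.groupby("individual", sort=False)[c].nunique(dropna=False)
            if (per_ind > 1).any():
                bad_ids = per_ind[per_ind > 1].index[:5].tolist()
                raise ValueError(
                    f"covariate {c!r} varies within individual(s) {bad_ids}; "
                    "covariates must be time-constant"
                )

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in self.REQUIRED]

    @property
    def responses(self) -> list[str]:
        return sorted(self.df["response"].unique())

    @property
    def n_individuals(self) -> int:
        return self.df["individual"].nunique()

    @classmethod
    def from_csv(cls, path, **kwargs) -> "LongData":
        return cls(pd.read_csv(path, **kwargs))

    def to_csv(self, path, **kwargs) -> None:
        self.df.to_csv(path, index=False, **kwargs)

    def fingerprint(self) -> str:
        cols = list(self.REQUIRED) + self.covariate_names
        sub = self.df[cols].sort_values(["individual", "response", "time"])
        h = hashlib.sha256()
        h.update(pd.util.hash_pandas_object(sub.reset_index(drop=True), index=False).values.tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: spline layout per response, covariate terms, constraints.

    ``covariates`` may be a flat sequence (the same confounders enter every
    response's fixed part, the common case) or a mapping response -> names.
    Covariates shift the intercept only; covariate-by-spline interactions
    are not fitted.
    """

    responses: tuple[SplineSpec, ...]
    covariates: tuple = ()
    constraints: ConstraintSet = field(default_factory=ConstraintSet)

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", tuple(self.responses))
        names = [s.response_name for s in self.responses]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate response names {names}")
        self.constraints.validate(self.responses)

    def covariates_for(self, response: str) -> tuple[str, ...]:
        if isinstance(self.covariates, Mapping):
            return tuple(self.covariates.get(response, ()))
        return tuple(self.covariates)

    @property
    def effects(self) -> list[RandomEffectIndex]:
        return effect_order(self.responses)

    @property
    def n_effects(self) -> int:
        return len(self.effects)

    def spec_for(self, response: str) -> SplineSpec:
        for s in self.responses:
            if s.response_name == response:
                return s
        raise KeyError(f"unknown response {response!r}")

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "responses": [s.to_dict() for s in self.responses],
                "covariates": (
                    {k: list(v) for k, v in self.covariates.items()}
                    if isinstance(self.covariates, Mapping)
                    else list(self.covariates)
                ),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# design assembly


@dataclass
class _Group:
    """Individuals sharing one observation count, stacked for batched algebra."""

    Z: np.ndarray  # (B, n, M)
    X: np.ndarray  # (B, n, P)
    y: np.ndarray  # (B, n)
    Pidx: np.ndarray  # (B, n, n) int, index into vech(S) or -1
    ids: list


@dataclass
class _Design:
    groups: list
    effects: list
    fixed_names: list
    resp_names: list
    n_individuals: int
    n_obs: int

    @property
    def M(self) -> int:
        return len(self.effects)

    @property
    def n_resp(self) -> int:
        return len(self.resp_names)

    @property
    def n_svech(self) -> int:
        r = self.n_resp
        return r * (r + 1) // 2


def _individual_design(
    mspec: ModelSpec,
    resp_names: list,
    fixed_slices: dict,
    eff_slices: dict,
    P: int,
    M: int,
    times: dict,
    values: dict,
    cov_values: dict,
    label="",
):
    """Build X, Z, y, Pidx for one individual.

    Rows are ordered response-major (responses in spec order, times
    ascending within response); ``times[resp]`` / ``values[resp]`` give that
    individual's schedule.
    """
    rows_X, rows_Z, rows_y, rows_resp, rows_time = [], [], [], [], []
    for ri, resp in enumerate(resp_names):
        t = np.asarray(times.get(resp, ()), dtype=float)
        if t.size == 0:
            continue
        order = np.argsort(t, kind="stable")
        t = t[order]
        v = np.asarray(values[resp], dtype=float)[order]
        sspec = mspec.spec_for(resp)
        try:
            basis = evaluate_basis(sspec, t)
        except ValueError as e:
            raise ValueError(f"individual {label!r}: {e}") from None
        nr = t.size
        X = np.zeros((nr, P))
        sl = fixed_slices[resp]
        X[:, sl.start] = 1.0
        X[:, sl.start + 1 : sl.start + 1 + sspec.n_splines] = basis
        for ci, cname in enumerate(mspec.covariates_for(resp)):
            X[:, sl.start + 1 + sspec.n_splines + ci] = cov_values[cname]
        Z = np.zeros((nr, M))
        esl = eff_slices[resp]
        Z[:, esl.start] = 1.0
        Z[:, esl.start + 1 : esl.start + 1 + sspec.n_splines] = basis
        rows_X.append(X)
        rows_Z.append(Z)
        rows_y.append(v)
        rows_resp.append(np.full(nr, ri))
        rows_time.append(t)
    X = np.vstack(rows_X)
    Z = np.vstack(rows_Z)
    y = np.concatenate(rows_y)
    resp_idx = np.concatenate(rows_resp)
    t_all = np.concatenate(rows_time)
    n = y.size
    n_resp = len(resp_names)
    Pidx = np.full((n, n), -1, dtype=np.int32)
    same_time = t_all[:, None] == t_all[None, :]
    for a in range(n):
        for b in range(n):
            if a == b:
                Pidx[a, a] = vech_position(n_resp, resp_idx[a], resp_idx[a])
            elif resp_idx[a] != resp_idx[b] and same_time[a, b]:
                Pidx[a, b] = vech_position(n_resp, resp_idx[a], resp_idx[b])
    return X, Z, y, Pidx


def _build_design(mspec: ModelSpec, data: LongData) -> _Design:
    resp_names = [s.response_name for s in mspec.responses]
    present = set(data.df["response"].unique())
    for r in resp_names:
        if r not in present:
            raise ValueError(f"response {r!r} never observed in the data")
    extra = present - set(resp_names)
    if extra:
        warnings.warn(f"responses {sorted(extra)} in the data are ignored by this model")

    # fixed-effect layout: per response intercept, slopes, covariates
    fixed_names, fixed_slices = [], {}
    for s in mspec.responses:
        start = len(fixed_names)
        fixed_names.append(f"{s.response_name}:intercept")
        fixed_names.extend(
            f"{s.response_name}:slope{l}" for l in range(1, s.n_splines + 1)
        )
        covs = mspec.covariates_for(s.response_name)
        for c in covs:
            if c not in data.covariate_names:
                raise KeyError(f"covariate {c!r} not found in the data")
            fixed_names.append(f"{s.response_name}:{c}")
        fixed_slices[s.response_name] = slice(start, len(fixed_names))
    P = len(fixed_names)

    effects = mspec.effects
    M = len(effects)
    eff_slices, pos = {}, 0
    for s in mspec.responses:
        eff_slices[s.response_name] = slice(pos, pos + 1 + s.n_splines)
        pos += 1 + s.n_splines

    df = data.df[data.df["response"].isin(resp_names)]
    cov_cols = sorted(set().union(*(mspec.covariates_for(r) for r in resp_names))) if resp_names else []
    for c in cov_cols:
        if df[c].isna().any():
            raise ValueError(f"covariate {c!r} has missing values; complete cases required")

    per_size: dict[int, list] = {}
    for ind, sub in df.groupby("individual", sort=True):
        times = {r: g["time"].to_numpy() for r, g in sub.groupby("response")}
        values = {r: g["value"].to_numpy() for r, g in sub.groupby("response")}
        cov_values = {c: sub[c].iloc[0] for c in cov_cols}
        X, Z, y, Pidx = _individual_design(
            mspec, resp_names, fixed_slices, eff_slices, P, M, times, values, cov_values, label=ind
        )
        per_size.setdefault(y.size, []).append((ind, X, Z, y, Pidx))

    groups = []
    n_obs = 0
    for n, items in sorted(per_size.items()):
        ids = [it[0] for it in items]
        X = np.stack([it[1] for it in items])
        Z = np.stack([it[2] for it in items])
        y = np.stack([it[3] for it in items])
        Pidx = np.stack([it[4] for it in items])
        groups.append(_Group(Z=Z, X=X, y=y, Pidx=Pidx, ids=ids))
        n_obs += n * len(items)
    n_individuals = sum(len(g.ids) for g in groups)
    max_n = max((g.y.shape[1] for g in groups), default=0)
    if max_n < M:
        warnings.warn(
            f"every individual has fewer observations ({max_n}) than random "
            f"effects ({M}); the individual-level covariance is weakly identified"
        )
    return _Design(
        groups=groups,
        effects=effects,
        fixed_names=fixed_names,
        resp_names=resp_names,
        n_individuals=n_individuals,
        n_obs=n_obs,
    )


# ---------------------------------------------------------------------------
# likelihood machinery


def _marginal_covs(design: _Design, G: np.ndarray, Svech: np.ndarray):
    """Per-group marginal covariances V = Z G Z' + R; raises LinAlgError if
    any individual's V is not PD."""
    out = []
    for g in design.groups:
        R = np.where(g.Pidx >= 0, Svech[np.clip(g.Pidx, 0, None)], 0.0)
        ZG = g.Z @ G
        V = ZG @ g.Z.transpose(0, 2, 1) + R
        L = np.linalg.cholesky(V)  # PD check; raises LinAlgError
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        W = np.linalg.inv(V)
        W = 0.5 * (W + W.transpose(0, 2, 1))
        out.append((W, logdet))
    return out


@dataclass
class _Eval:
    loglik: float
    beta: np.ndarray
    grad_G: np.ndarray | None  # (M, M) d loglik / dG (symmetric storage)
    grad_S: np.ndarray | None  # (n_svech,)
    XtWX: np.ndarray


def _evaluate(design: _Design, G: np.ndarray, Svech: np.ndarray, want_grad: bool) -> _Eval:
    WLs = _marginal_covs(design, G, Svech)
    P = len(design.fixed_names)
    XtWX = np.zeros((P, P))
    XtWy = np.zeros(P)
    logdet_sum = 0.0
    for (W, logdet), g in zip(WLs, design.groups):
        WX = np.einsum("bij,bjp->bip", W, g.X)
        XtWX += np.einsum("bip,biq->pq", g.X, WX)
        XtWy += np.einsum("bip,bi->p", WX, g.y)
        logdet_sum += logdet
    XtWX = 0.5 * (XtWX + XtWX.T)
    beta = np.linalg.solve(XtWX, XtWy)

    quad = 0.0
    M = design.M
    A_sum = np.zeros((M, M))
    B_sum = np.zeros((M, M))
    grad_S = np.zeros(design.n_svech)
    for (W, _), g in zip(WLs, design.groups):
        r = g.y - np.einsum("bip,p->bi", g.X, beta)
        Wr = np.einsum("bij,bj->bi", W, r)
        quad += float(np.einsum("bi,bi->", r, Wr))
        if want_grad:
            WZ = np.einsum("bij,bjm->bim", W, g.Z)
            A_sum += np.einsum("bim,bin->mn", g.Z, WZ)
            b = np.einsum("bim,bi->bm", g.Z, Wr)  # (B, M)
            B_sum += np.einsum("bm,bn->mn", b, b)
            T = W - Wr[:, :, None] * Wr[:, None, :]
            mask = g.Pidx >= 0
            grad_S += np.bincount(
                g.Pidx[mask].ravel(), weights=T[mask].ravel(), minlength=design.n_svech
            )
    loglik = -0.5 * (design.n_obs * np.log(2.0 * np.pi) + logdet_sum + quad)
    grad_G = None
    if want_grad:
        D = A_sum - B_sum
        grad_G = -D.copy()
        np.fill_diagonal(grad_G, -0.5 * np.diag(D))
        grad_S = -0.5 * grad_S
    else:
        grad_S = None
    return _Eval(loglik=loglik, beta=beta, grad_G=grad_G, grad_S=grad_S, XtWX=XtWX)


def log_likelihood(
    mspec: ModelSpec,
    data: LongData,
    fixed,
    G: np.ndarray,
    R: np.ndarray,
) -> float:
    """Log-likelihood of the model at given parameter values.

    ``fixed`` is either an array in the design's fixed-effect order or a
    mapping from fixed-effect name (e.g. ``"weight:slope2"``) to value.
    ``G`` is the M x M individual-level covariance, ``R`` the occasion-level
    covariance across responses (scalar variance for a univariate model is
    accepted as a 1 x 1 matrix).

    Raises :class:`CovarianceNotPD` when some individual's marginal
    covariance is not positive definite — an evaluation failure an optimizer
    can recover from.
    """
    design = _build_design(mspec, data)
    G = np.asarray(G, dtype=float)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if G.shape != (design.M, design.M):
        raise ValueError(f"G must be {design.M}x{design.M}, got {G.shape}")
    if R.shape != (design.n_resp, design.n_resp):
        raise ValueError(f"R must be {design.n_resp}x{design.n_resp}, got {R.shape}")
    if isinstance(fixed, Mapping):
        beta = np.array([fixed[name] for name in design.fixed_names], dtype=float)
    else:
        beta = np.asarray(fixed, dtype=float)
        if beta.shape != (len(design.fixed_names),):
            raise ValueError(
                f"fixed effects must have length {len(design.fixed_names)} "
                f"(order {design.fixed_names})"
            )
    Svech = np.array([R[i, j] for i, j in vech_indices(design.n_resp)])
    try:
        WLs = _marginal_covs(design, G, Svech)
    except np.linalg.LinAlgError:
        raise CovarianceNotPD(
            "some individual's marginal covariance Z G Z' + R is not positive definite"
        ) from None
    total = 0.0
    for (W, logdet), g in zip(WLs, design.groups):
        r = g.y - np.einsum("bip,p->bi", g.X, beta)
        quad = float(np.einsum("bi,bij,bj->", r, W, r))
        n = g.y.shape[1] * g.y.shape[0]
        total += -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
    return total


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class FittedMLM:
    """A fitted multivariate linear-spline multilevel model."""

    spec: ModelSpec
    effects: list
    fixed_names: list
    beta: np.ndarray
    fixed_se: np.ndarray
    G: np.ndarray
    G_se: np.ndarray
    R: np.ndarray  # occasion-level covariance across responses
    deviance: float
    gamma: np.ndarray  # V x V, V = M(M+1)/2 over vech(G); constrained rows zero
    n_individuals: int
    n_obs: int
    converged: bool
    n_iter: int
    grad_norm: float
    message: str = ""
    data_fingerprint: str = ""

    @property
    def constraints(self) -> ConstraintSet:
        return self.spec.constraints

    @property
    def loglik(self) -> float:
        return -0.5 * self.deviance

    def fixed_effects_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.fixed_names, "estimate": self.beta, "se": self.fixed_se}
        )

    def correlation_matrix(self) -> np.ndarray:
        from .reff_regression import correlation_matrix

        return correlation_matrix(self.G)

    def summary(self) -> str:
        lines = [
            f"Multivariate linear-spline MLM: {len(self.spec.responses)} responses, "
            f"{self.n_individuals} individuals, {self.n_obs} observations",
            f"deviance (-2 logLik): {self.deviance:.3f}   "
            f"converged: {self.converged} ({self.n_iter} iterations, "
            f"|grad| {self.grad_norm:.2e})",
            f"constrained covariances: {len(self.constraints)}",
            "",
            "Fixed effects:",
            self.fixed_effects_table().to_string(index=False, float_format="%.4f"),
            "",
            "Individual-level covariance G (SEs on the diagonal scale):",
        ]
        eff_names = [str(e) for e in self.effects]
        gdf = pd.DataFrame(self.G, index=eff_names, columns=eff_names)
        lines.append(gdf.to_string(float_format="%.4f"))
        lines.append("")
        lines.append("Occasion-level covariance R:")
        rdf = pd.DataFrame(self.R, index=self.spec_resp_names(), columns=self.spec_resp_names())
        lines.append(rdf.to_string(float_format="%.4f"))
        return "\n".join(lines)

    def spec_resp_names(self) -> list:
        return [s.response_name for s in self.spec.responses]

    # --- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        def eff_dict(e: RandomEffectIndex):
            return {"response": e.response, "kind": e.kind, "period": e.period}

        payload = {
            "responses": [s.to_dict() for s in self.spec.responses],
            "covariates": (
                {k: list(v) for k, v in self.spec.covariates.items()}
                if isinstance(self.spec.covariates, Mapping)
                else list(self.spec.covariates)
            ),
            "constraints": [
                [eff_dict(a), eff_dict(b)] for a, b in self.constraints.sorted_pairs(self.spec.responses)
            ],
            "constraints_label": self.constraints.label,
            "fixed_names": self.fixed_names,
            "beta": self.beta.tolist(),
            "fixed_se": self.fixed_se.tolist(),
            "G": self.G.tolist(),
            "G_se": self.G_se.tolist(),
            "R": self.R.tolist(),
            "deviance": self.deviance,
            "gamma": self.gamma.tolist(),
            "n_individuals": self.n_individuals,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "message": self.message,
            "data_fingerprint": self.data_fingerprint,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FittedMLM":
        d = json.loads(text)
        responses = tuple(SplineSpec.from_dict(s) for s in d["responses"])
        covs = d["covariates"]
        pairs = frozenset(
            frozenset(
                RandomEffectIndex(e["response"], e["kind"], e["period"]) for e in pair
            )
            for pair in d["constraints"]
        )
        cset = ConstraintSet(pairs, label=d.get("constraints_label", ""))
        mspec = ModelSpec(
            responses=responses,
            covariates=covs if not isinstance(covs, dict) else covs,
            constraints=cset,
        )
        return cls(
            spec=mspec,
            effects=effect_order(responses),
            fixed_names=d["fixed_names"],
            beta=np.array(d["beta"]),
            fixed_se=np.array(d["fixed_se"]),
            G=np.array(d["G"]),
            G_se=np.array(d["G_se"]),
            R=np.array(d["R"]),
            deviance=d["deviance"],
            gamma=np.array(d["gamma"]),
            n_individuals=d["n_individuals"],
            n_obs=d["n_obs"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            grad_norm=d["grad_norm"],
            message=d.get("message", ""),
            data_fingerprint=d.get("data_fingerprint", ""),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "FittedMLM":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# fitting


def _init_values(design: _Design, mspec: ModelSpec):
    """OLS-based starting values: per-response least squares for scale,
    between/within residual variance split for G diagonal and R."""
    M = design.M
    G0 = np.zeros((M, M))
    n_resp = design.n_resp
    S0 = np.zeros((n_resp, n_resp))
    # assemble all rows per response across groups
    for ri, resp in enumerate(design.resp_names):
        ys, zs, ind_ids = [], [], []
        counter = 0
        for g in design.groups:
            icol = _resp_intercept_col(design, mspec, resp)
            for b in range(g.y.shape[0]):
                sel = g.Z[b, :, icol] == 1.0
                counter += 1
                if sel.any():
                    ys.append(g.y[b, sel])
                    zs.append(g.Z[b][np.ix_(sel, _resp_effect_cols(design, mspec, resp))])
                    ind_ids.append(np.full(sel.sum(), counter))
        y = np.concatenate(ys)
        Zr = np.vstack(zs)
        ids = np.concatenate(ind_ids)
        coef, *_ = np.linalg.lstsq(Zr, y, rcond=None)
        resid = y - Zr @ coef
        # between-individual vs within-individual residual variance
        dfm = pd.DataFrame({"id": ids, "e": resid})
        means = dfm.groupby("id")["e"].mean()
        vb = float(np.var(means.to_numpy())) if len(means) > 1 else 0.0
        vw = float(np.var((dfm["e"] - dfm["id"].map(means)).to_numpy()))
        vb = max(vb, 0.05 * (vb + vw), 1e-4)
        vw = max(vw, 0.05 * (vb + vw), 1e-4)
        cols = _resp_effect_cols(design, mspec, resp)
        span = mspec.spec_for(resp).horizon - mspec.spec_for(resp).baseline
        G0[cols[0], cols[0]] = vb
        for c in cols[1:]:
            G0[c, c] = max(4.0 * vb / span**2, 1e-6)
        S0[ri, ri] = vw
    return G0, S0


def _resp_intercept_col(design: _Design, mspec: ModelSpec, resp: str) -> int:
    pos = 0
    for s in mspec.responses:
        if s.response_name == resp:
            return pos
        pos += 1 + s.n_splines
    raise KeyError(resp)


def _resp_effect_cols(design: _Design, mspec: ModelSpec, resp: str) -> list[int]:
    start = _resp_intercept_col(design, mspec, resp)
    return list(range(start, start + 1 + mspec.spec_for(resp).n_splines))


def _free_vech(design: _Design, mspec: ModelSpec):
    """Indices into vech(G) that are free (not fixed to zero), and the
    constrained (i, j) effect-index pairs."""
    M = design.M
    eff_pos = {e: i for i, e in enumerate(design.effects)}
    constrained = set()
    for p in mspec.constraints.pairs:
        a, b = sorted((eff_pos[e] for e in p))
        constrained.add((a, b))
    free = [
        k for k, (i, j) in enumerate(vech_indices(M)) if (i, j) not in constrained
    ]
    return free, constrained


def fit(
    mspec: ModelSpec,
    data: LongData,
    init=None,
    maxiter: int = 1000,
    ftol: float = 1e-9,
    gtol: float = 1e-5,
    prefit_diagonal: bool = True,
    compute_gamma: bool = True,
) -> FittedMLM:
    """Fit the model by maximum likelihood.

    The fixed effects are profiled out (GLS), so only the free unique
    entries of G and the occasion-level covariance are optimised.  With
    ``prefit_diagonal`` (default) a cheap diagonal-G pre-optimisation
    supplies starting values for the full problem — the staged strategy of
    adding covariance structure to an already-converged simpler model,
    which markedly helps convergence for large G.

    ``init`` may be a ``(G0, R0)`` tuple overriding the automatic starts.
    """
    design = _build_design(mspec, data)
    M = design.M
    vech = vech_indices(M)
    V = len(vech)
    free, constrained = _free_vech(design, mspec)
    n_sv = design.n_svech
    sv_idx = vech_indices(design.n_resp)

    if init is not None:
        G0, S0 = np.asarray(init[0], dtype=float).copy(), np.atleast_2d(np.asarray(init[1], dtype=float)).copy()
    else:
        G0, S0 = _init_values(design, mspec)
    for (i, j) in constrained:
        G0[i, j] = G0[j, i] = 0.0

    # scales for conditioning: geometric means of initial diagonals
    dG = np.sqrt(np.clip(np.diag(G0), 1e-8, None))
    scale_G = np.array([dG[i] * dG[j] for i, j in vech])
    dS = np.sqrt(np.clip(np.diag(S0), 1e-8, None))
    scale_S = np.array([dS[i] * dS[j] for i, j in sv_idx])
    scales = np.concatenate([scale_G[free], scale_S])

    def unpack(theta):
        G = np.zeros((M, M))
        gv = np.zeros(V)
        gv[free] = theta[: len(free)]
        for k, (i, j) in enumerate(vech):
            G[i, j] = G[j, i] = gv[k]
        Svech = theta[len(free) :]
        return G, Svech

    def pack(G, S):
        gv = np.array([G[i, j] for i, j in vech])
        sv = np.array([S[i, j] for i, j in sv_idx])
        return np.concatenate([gv[free], sv])

    nfev = [0]

    def objective(theta_scaled, want_grad=True):
        nfev[0] += 1
        theta = theta_scaled * scales
        G, Svech = unpack(theta)
        try:
            ev = _evaluate(design, G, Svech, want_grad=want_grad)
        except np.linalg.LinAlgError:
            return _PENALTY, np.zeros_like(theta_scaled)
        if not np.isfinite(ev.loglik):
            return _PENALTY, np.zeros_like(theta_scaled)
        f = -ev.loglik
        if not want_grad:
            return f, None
        gG = np.array([ev.grad_G[i, j] for i, j in vech])[free]
        grad = -np.concatenate([gG, ev.grad_S])
        return f, grad * scales

    def raw_grad(theta_raw):
        """Score (gradient of loglik) at raw parameters; LinAlgError if infeasible."""
        G, Svech = unpack(theta_raw)
        ev = _evaluate(design, G, Svech, want_grad=True)
        gG = np.array([ev.grad_G[i, j] for i, j in vech])[free]
        return np.concatenate([gG, ev.grad_S])

    if prefit_diagonal and init is None and len(free) > M:
        # stage 1: variances only (all free covariances pinned at zero)
        diag_free = [k for k in free if vech[k][0] == vech[k][1]]
        x0 = pack(G0, S0) / scales

        def obj_diag(x_small):
            x = np.zeros_like(x0)
            x[: len(free)][[free.index(k) for k in diag_free]] = x_small[: len(diag_free)]
            x[len(free) :] = x_small[len(diag_free) :]
            f, g = objective(x)
            gd = np.concatenate(
                [g[: len(free)][[free.index(k) for k in diag_free]], g[len(free) :]]
            )
            return f, gd

        x_small0 = np.concatenate(
            [x0[: len(free)][[free.index(k) for k in diag_free]], x0[len(free) :]]
        )
        res0 = optimize.minimize(
            obj_diag, x_small0, jac=True, method="L-BFGS-B",
            options={"maxiter": 200, "ftol": 1e-10, "gtol": 1e-4},
        )
        x0 = np.zeros_like(x0)
        x0[: len(free)][[free.index(k) for k in diag_free]] = res0.x[: len(diag_free)]
        x0[len(free) :] = res0.x[len(diag_free) :]
    else:
        x0 = pack(G0, S0) / scales

    res = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 4 * maxiter, "ftol": ftol, "gtol": gtol, "maxls": 60},
    )
    theta_hat = res.x * scales
    G_hat, Svech_hat = unpack(theta_hat)
    ev = _evaluate(design, G_hat, Svech_hat, want_grad=True)
    deviance = -2.0 * ev.loglik
    beta = ev.beta
    fixed_cov = np.linalg.inv(ev.XtWX)
    fixed_se = np.sqrt(np.clip(np.diag(fixed_cov), 0.0, None))
    R_hat = np.zeros((design.n_resp, design.n_resp))
    for k, (i, j) in enumerate(sv_idx):
        R_hat[i, j] = R_hat[j, i] = Svech_hat[k]

    converged = bool(res.success and res.fun < _PENALTY / 2)
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    if not converged:
        warnings.warn(
            f"optimizer did not report convergence: {res.message} "
            f"(best-so-far parameters returned; |grad|={grad_norm:.2e})"
        )

    gamma = np.zeros((V, V))
    G_se = np.full((M, M), np.nan)
    if compute_gamma:
        gamma_theta = _observed_info_inverse(raw_grad, theta_hat, scales)
        nf = len(free)
        gamma_free = gamma_theta[:nf, :nf]
        for a, ka in enumerate(free):
            for b, kb in enumerate(free):
                gamma[ka, kb] = gamma_free[a, b]
        for k, (i, j) in enumerate(vech):
            se = np.sqrt(gamma[k, k]) if gamma[k, k] > 0 else 0.0
            G_se[i, j] = G_se[j, i] = se

    return FittedMLM(
        spec=mspec,
        effects=design.effects,
        fixed_names=design.fixed_names,
        beta=beta,
        fixed_se=fixed_se,
        G=G_hat,
        G_se=G_se,
        R=R_hat,
        deviance=float(deviance),
        gamma=gamma,
        n_individuals=design.n_individuals,
        n_obs=design.n_obs,
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        message=str(res.message),
        data_fingerprint=data.fingerprint() + "/" + mspec.fingerprint(),
    )


def _observed_info_inverse(raw_grad, theta_hat, scales, rel_step: float = 1e-4):
    """Inverse observed information by central differences of the analytic
    score, on the raw parameter scale."""
    k = theta_hat.size
    H = np.zeros((k, k))
    for j in range(k):
        h = rel_step * scales[j]
        tp = theta_hat.copy()
        tm = theta_hat.copy()
        tp[j] += h
        tm[j] -= h
        try:
            gp = raw_grad(tp)
        except np.linalg.LinAlgError:
            gp = None
        try:
            gm = raw_grad(tm)
        except np.linalg.LinAlgError:
            gm = None
        g0 = None
        if gp is None or gm is None:
            g0 = raw_grad(theta_hat)
        if gp is not None and gm is not None:
            H[:, j] = -(gp - gm) / (2 * h)
        elif gp is not None:
            H[:, j] = -(gp - g0) / h
        elif gm is not None:
            H[:, j] = -(g0 - gm) / h
        else:  # pragma: no cover - pathological
            H[:, j] = np.nan
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn(
            "observed information is not positive definite; using a "
            "pseudo-inverse for the sampling covariance"
        )
        w, U = np.linalg.eigh(H)
        w = np.where(w > 1e-10 * np.max(np.abs(w)), w, np.inf)
        cov = (U / w) @ U.T
    return 0.5 * (cov + cov.T)


# ---------------------------------------------------------------------------
# likelihood-ratio test


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float

    def __iter__(self):
        return iter((self.chi2, self.df, self.p))

    def __str__(self) -> str:
        p = "< 0.001" if self.p < 0.001 else f"{self.p:.3f}"
        return f"chi2 = {self.chi2:.3f}, df = {self.df}, p = {p}"


def lrt_from_deviances(dev_full: float, dev_restricted: float, df: int) -> LRTResult:
    """Likelihood-ratio test from two deviances (-2 logLik) of nested fits.

    ``df`` is the number of covariances constrained to zero in the
    restricted model beyond the full one.  A negative chi-square indicates
    numerical non-convergence of one of the fits; it is reported with p = 1
    and a warning.
    """
    chi2 = dev_restricted - dev_full
    if df < 0:
        raise ValueError("df must be nonnegative")
    if chi2 < 0:
        warnings.warn(
            f"restricted deviance below full deviance (chi2 = {chi2:.4f}); "
            "this indicates non-convergence of the full fit"
        )
        return LRTResult(chi2=float(chi2), df=df, p=1.0)
    if df == 0:
        return LRTResult(chi2=float(chi2), df=0, p=1.0)
    p = float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=float(chi2), df=df, p=p)


def lrt(full: FittedMLM, restricted: FittedMLM) -> LRTResult:
    """Likelihood-ratio test of a covariance-restricted model against the
    full model fitted to the same data."""
    if full.data_fingerprint != restricted.data_fingerprint:
        raise ValueError("models were fitted to different data or model specs")
    if not (full.constraints.issubset(restricted.constraints)
            and len(restricted.constraints) > len(full.constraints)):
        raise ValueError(
            "restricted model's constraints must strictly contain the full model's"
        )
    df = len(restricted.constraints) - len(full.constraints)
    return lrt_from_deviances(full.deviance, restricted.deviance, df)


# ---------------------------------------------------------------------------
# prediction and moments


def predict_random_effects(fitted: FittedMLM, data: LongData) -> pd.DataFrame:
    """Empirical-Bayes predictions (BLUPs) of each individual's random effects.

    u_k = G Z_k' V_k^{-1} (y_k - X_k beta).  These predictions are shrunken
    towards zero in proportion to each individual's information, so their
    empirical covariance understates G; use the model-estimated G, not these,
    to quantify population associations between intercepts and slopes.
    """
    design = _build_design(fitted.spec, data)
    Svech = np.array(
        [fitted.R[i, j] for i, j in vech_indices(design.n_resp)]
    )
    WLs = _marginal_covs(design, fitted.G, Svech)
    rows, ids = [], []
    for (W, _), g in zip(WLs, design.groups):
        r = g.y - np.einsum("bip,p->bi", g.X, fitted.beta)
        Wr = np.einsum("bij,bj->bi", W, r)
        u = np.einsum("mn,bin,bi->bm", fitted.G, g.Z, Wr)
        rows.append(u)
        ids.extend(g.ids)
    U = np.vstack(rows)
    return pd.DataFrame(U, columns=[str(e) for e in fitted.effects], index=ids)


def individual_moments(
    fitted: FittedMLM, schedule: Mapping
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied marginal mean and covariance of one individual's
    stacked observation vector, for a given measurement schedule.

    ``schedule`` maps response name -> occasion times.  Rows are ordered
    response-major (responses in spec order, times ascending), covariates at
    their reference (zero) values.
    """
    mspec = fitted.spec
    resp_names = [s.response_name for s in mspec.responses]
    fixed_slices = {}
    pos = 0
    for s in mspec.responses:
        ncov = len(mspec.covariates_for(s.response_name))
        fixed_slices[s.response_name] = slice(pos, pos + 1 + s.n_splines + ncov)
        pos += 1 + s.n_splines + ncov
    P = pos
    eff_slices, epos = {}, 0
    for s in mspec.responses:
        eff_slices[s.response_name] = slice(epos, epos + 1 + s.n_splines)
        epos += 1 + s.n_splines
    M = epos
    times = {r: np.asarray(t, dtype=float) for r, t in schedule.items()}
    values = {r: np.zeros_like(t) for r, t in times.items()}
    cov_values = {c: 0.0 for r in resp_names for c in mspec.covariates_for(r)}
    X, Z, _, Pidx = _individual_design(
        mspec, resp_names, fixed_slices, eff_slices, P, M, times, values, cov_values
    )
    Svech = np.array([fitted.R[i, j] for i, j in vech_indices(len(resp_names))])
    R = np.where(Pidx >= 0, Svech[np.clip(Pidx, 0, None)], 0.0)
    mean = X @ fitted.beta
    cov = Z @ fitted.G @ Z.T + R
    return mean, cov
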