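"""Independent brute-force oracles used by several test modules.

These deliberately avoid the package's likelihood machinery: each
individual's mean vector and covariance matrix are assembled entry by entry
from the model definition and handed to a generic multivariate-normal
density.
"""

import numpy as np
from scipy.stats import multivariate_normal

from splinemlm.spline_basis import evaluate_basis


def brute_force_loglik(mspec, data, fixed, G, R) -> float:
    """Stacked-normal log-likelihood via explicit per-individual matrices.

    ``fixed`` maps fixed-effect name -> value (same naming as the design:
    'resp:intercept', 'resp:slopeL', 'resp:covname').
    """
    G = np.asarray(G, dtype=float)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    specs = {s.response_name: s for s in mspec.responses}
    resp_order = [s.response_name for s in mspec.responses]
    r_pos = {r: i for i, r in enumerate(resp_order)}
    # effect block offsets
    offs, pos = {}, 0
    for s in mspec.responses:
        offs[s.response_name] = pos
        pos += 1 + s.n_splines
    M = pos

    total = 0.0
    for _, sub in data.df[data.df["response"].isin(resp_order)].groupby("individual"):
        rows = sorted(
            sub.itertuples(), key=lambda r: (r_pos[r.response], r.time)
        )
        n = len(rows)
        mu = np.zeros(n)
        Z = np.zeros((n, M))
        for i, r in enumerate(rows):
            s = specs[r.response]
            b = evaluate_basis(s, float(r.time))
            mu[i] = fixed[f"{r.response}:intercept"] + sum(
                fixed[f"{r.response}:slope{l+1}"] * b[l] for l in range(s.n_splines)
            )
            for c in mspec.covariates_for(r.response):
                mu[i] += fixed[f"{r.response}:{c}"] * getattr(r, c)
            o = offs[r.response]
            Z[i, o] = 1.0
            Z[i, o + 1 : o + 1 + s.n_splines] = b
        V = Z @ G @ Z.T
        for i, ri in enumerate(rows):
            for j, rj in enumerate(rows):
                if i == j:
                    V[i, i] += R[r_pos[ri.response], r_pos[ri.response]]
                elif ri.response != rj.response and ri.time == rj.time:
                    V[i, j] += R[r_pos[ri.response], r_pos[rj.response]]
        y = np.array([r.value for r in rows])
        total += multivariate_normal.logpdf(y, mu, V)
    return float(total)


def random_tiny_instance(rng):
    """A random small model + dataset + parameter set for oracle checks.

    Returns (mspec, data, fixed_dict, G, R).  Occasion times are partly
    shared across responses so the cross-response residual covariance path
    is exercised.
    """
    import pandas as pd

    import splinemlm as sm

    n_resp = int(rng.integers(1, 3))
    specs = []
    for i in range(n_resp):
        n_knots = int(rng.integers(0, 3))
        pts = np.sort(rng.choice(np.arange(1.0, 10.0), size=n_knots, replace=False))
        specs.append(
            sm.SplineSpec(f"r{i}", baseline=0.0, knots=tuple(pts), horizon=10.0)
        )
    mspec = sm.ModelSpec(responses=tuple(specs))
    M = sum(s.n_splines + 1 for s in specs)
    A = rng.standard_normal((M, M + 2))
    G = A @ A.T / (M + 2)
    B = rng.standard_normal((n_resp, n_resp + 2))
    R = B @ B.T / (n_resp + 2) + 0.5 * np.eye(n_resp)
    fixed = {}
    for s in specs:
        fixed[f"{s.response_name}:intercept"] = float(rng.normal(0, 2))
        for l in range(1, s.n_splines + 1):
            fixed[f"{s.response_name}:slope{l}"] = float(rng.normal(0, 1))
    rows = []
    n_ind = int(rng.integers(1, 4))
    for k in range(n_ind):
        times = np.sort(rng.choice(np.arange(0.0, 10.5, 0.5), size=4, replace=False))
        for i, s in enumerate(specs):
            # share some times across responses, keep others distinct
            keep = rng.random(4) < 0.8
            if not keep.any():
                keep[0] = True
            for t in times[keep]:
                rows.append(
                    {
                        "individual": k,
                        "time": float(t),
                        "response": s.response_name,
                        "value": float(rng.normal(0, 3)),
                    }
                )
    data = sm.LongData(pd.DataFrame(rows))
    return mspec, data, fixed, G, R
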