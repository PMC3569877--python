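"""Latent growth-curve (SEM) view of the multilevel spline model.

For a balanced grid of occasion times, the multilevel model is a latent
growth curve model: one intercept factor per response with unit loadings,
one slope factor per spline period with loadings equal to the spline basis
evaluated at each grid time, factor covariance identified with G, and the
occasion-level covariance as the residual structure (cross-response
residual covariance only within the same grid time).  The two views share
their parameters, so the SEM-implied moments must reproduce the model's
marginal moments exactly; :func:`check_equivalence` verifies this on a
fitted model.  No second estimator is involved — the check is structural.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .effects import effect_order
from .spline_basis import SplineSpec, evaluate_basis

__all__ = ["SemLayout", "build_layout", "implied_moments", "check_equivalence"]


@dataclass
class SemLayout:
    """Factor-loading layout of the SEM parameterisation on a time grid.

    ``loadings[resp]`` is a T x (m+1) matrix (intercept column of ones,
    slope column l = basis component l at each grid time); ``usable[resp]``
    flags grid times at or after that response's baseline — earlier cells
    carry no measurement model.
    """

    grid: np.ndarray
    responses: list
    loadings: dict
    usable: dict
    effects: list

    @property
    def n_factors(self) -> int:
        return len(self.effects)


def build_layout(specs: Sequence[SplineSpec], grid) -> SemLayout:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid times must be strictly increasing")
    loadings, usable = {}, {}
    for spec in specs:
        ok = grid >= spec.baseline
        lam = np.zeros((grid.size, spec.n_splines + 1))
        lam[:, 0] = 1.0
        if ok.any():
            lam[ok, 1:] = evaluate_basis(spec, grid[ok])
        lam[~ok] = np.nan  # unusable cells flagged
        loadings[spec.response_name] = lam
        usable[spec.response_name] = ok
    return SemLayout(
        grid=grid,
        responses=[s.response_name for s in specs],
        loadings=loadings,
        usable=usable,
        effects=effect_order(specs),
    )


def implied_moments(
    layout: SemLayout,
    fixed: Mapping,
    G: np.ndarray,
    R: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """SEM-implied mean and covariance of the stacked measurement vector.

    ``fixed[resp]`` holds the factor means (intercept, slopes) of that
    response; covariates, if any, are at reference level.  The stacked
    vector is response-major over each response's usable grid times:
    mean = Lambda nu and cov = Lambda G Lambda' + R-expansion, with the
    cross-response residual covariance only between cells sharing a grid
    time.
    """
    G = np.asarray(G, dtype=float)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    n_resp = len(layout.responses)
    if R.shape != (n_resp, n_resp):
        raise ValueError(f"R must be {n_resp}x{n_resp}, got {R.shape}")
    blocks, times, counts = [], [], []
    M = layout.n_factors
    pos = 0
    Lambda_rows = []
    for resp in layout.responses:
        lam = layout.loadings[resp]
        ok = layout.usable[resp]
        m1 = lam.shape[1]
        block = np.zeros((int(ok.sum()), M))
        block[:, pos : pos + m1] = lam[ok]
        Lambda_rows.append(block)
        nu = np.asarray(fixed[resp], dtype=float)
        if nu.shape != (m1,):
            raise ValueError(
                f"fixed effects for {resp!r} must have length {m1}, got {nu.shape}"
            )
        blocks.append(lam[ok] @ nu)
        times.append(layout.grid[ok])
        counts.append(int(ok.sum()))
        pos += m1
    Lambda = np.vstack(Lambda_rows)
    mean = np.concatenate(blocks)
    cov = Lambda @ G @ Lambda.T
    # residual expansion
    t_all = np.concatenate(times)
    r_idx = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    same_time = t_all[:, None] == t_all[None, :]
    for a in range(n_resp):
        for b in range(n_resp):
            mask = (r_idx[:, None] == a) & (r_idx[None, :] == b) & same_time
            if a == b:
                mask &= np.eye(t_all.size, dtype=bool)
            cov = cov + np.where(mask, R[a, b], 0.0)
    return mean, cov


def check_equivalence(fitted, layout: SemLayout | None = None, grid=None) -> dict:
    """Verify that SEM-implied moments reproduce the fitted model's marginal
    moments on a balanced grid.

    Both formulas share the fitted parameters, so discrepancies should sit
    at numerical precision; a large discrepancy indicates an indexing or
    loading error, not a statistical difference.  Returns a report dict
    with the maximum absolute mean and covariance discrepancies.
    """
    from .mlm_core import individual_moments

    specs = fitted.spec.responses
    if layout is None:
        if grid is None:
            lo = min(s.baseline for s in specs)
            hi = max(s.horizon for s in specs)
            grid = np.arange(np.floor(lo), np.floor(hi) + 1.0)
        layout = build_layout(specs, grid)
    fixed = {}
    pos = 0
    for s in specs:
        m1 = 1 + s.n_splines
        fixed[s.response_name] = fitted.beta[pos : pos + m1]
        pos += m1 + len(fitted.spec.covariates_for(s.response_name))
    sem_mean, sem_cov = implied_moments(layout, fixed, fitted.G, fitted.R)
    schedule = {
        s.response_name: layout.grid[layout.usable[s.response_name]] for s in specs
    }
    mlm_mean, mlm_cov = individual_moments(fitted, schedule)
    return {
        "max_abs_mean_diff": float(np.max(np.abs(sem_mean - mlm_mean))),
        "max_abs_cov_diff": float(np.max(np.abs(sem_cov - mlm_cov))),
        "n_cells": int(sem_mean.size),
        "grid": layout.grid,
    }
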