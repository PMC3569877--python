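"""Synthetic unbalanced bivariate longitudinal data with known truth.

The generator emulates the structure of antenatal-care records: ~10
irregularly timed visits per woman at integer gestational weeks 8-43 (range
1-18, mildly enriched late in pregnancy), two responses (weight in kg and
mean arterial pressure in mmHg) measured at shared visits, piecewise-linear
population trajectories, individual-level random intercepts and period
slopes drawn from a 9 x 9 covariance taken from a published analysis of a
large pregnancy cohort (projected to the nearest positive-definite matrix,
since printed rounded entries need not be PD), and bivariate occasion-level
noise.  Every draw is deterministic under the seed, and the true
per-individual random effects are returned for oracle tests.

Also provides small data-preparation utilities: mean arterial pressure from
systolic/diastolic readings, and random thinning to at most one measurement
per time window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .effects import effect_order
from .mlm_core import LongData, ModelSpec
from .spline_basis import SplineSpec, evaluate_basis

__all__ = [
    "GeneratorSpec",
    "generate",
    "map_from_bp",
    "thin_to_window",
    "nearest_pd",
    "WEIGHT_SPEC",
    "MAP_SPEC",
    "REFERENCE_G",
    "default_generator",
]

WEIGHT_SPEC = SplineSpec("weight", baseline=8.0, knots=(18.0, 29.0), horizon=44.0)
MAP_SPEC = SplineSpec("map", baseline=8.0, knots=(18.0, 29.0, 36.0), horizon=44.0)

# Individual-level covariance of (weight intercept, 3 weight slopes,
# MAP intercept, 4 MAP slopes) estimated in a cohort of 9,429 pregnancies;
# used as the default generator truth and as a worked-example input.
# Units: kg and mmHg for intercepts, kg/week and mmHg/week for slopes.
REFERENCE_G = np.array(
    [
        [119.611, -0.585, -0.317, 0.044, 25.574, 0.387, -0.530, 0.196, -0.435],
        [-0.585, 0.050, 0.011, 0.005, -0.113, 0.001, 0.012, -0.012, 0.003],
        [-0.317, 0.011, 0.033, 0.018, -0.124, 0.006, 0.011, 0.000, 0.006],
        [0.044, 0.005, 0.018, 0.044, -0.018, 0.006, 0.006, 0.021, 0.027],
        [25.574, -0.113, -0.124, -0.018, 36.579, -1.071, -0.278, 0.127, -0.176],
        [0.387, 0.001, 0.006, 0.006, -1.071, 0.180, -0.035, -0.029, 0.015],
        [-0.530, 0.012, 0.011, 0.006, -0.278, -0.035, 0.113, -0.042, -0.012],
        [0.196, -0.012, 0.000, 0.021, 0.127, -0.029, -0.042, 0.352, -0.108],
        [-0.435, 0.003, 0.006, 0.027, -0.176, 0.015, -0.012, -0.108, 1.314],
    ]
)


def nearest_pd(A: np.ndarray, floor: float = 1e-8) -> tuple[np.ndarray, float]:
    """Nearest symmetric positive-definite matrix by eigenvalue clipping.

    Returns the projected matrix and the largest absolute entry change, so
    callers can log how far the input was from PD.
    """
    A = 0.5 * (np.asarray(A, dtype=float) + np.asarray(A, dtype=float).T)
    vals, vecs = np.linalg.eigh(A)
    clipped = np.clip(vals, floor, None)
    B = (vecs * clipped) @ vecs.T
    B = 0.5 * (B + B.T)
    return B, float(np.max(np.abs(B - A)))


@dataclass
class GeneratorSpec:
    """Everything needed to simulate one dataset.

    Defaults reproduce the pregnancy weight/MAP structure: population
    trajectories shaped like observed cohort averages (weight rising
    0.3-0.5 kg/week, MAP dipping early then rising late), the reference
    9 x 9 G as truth, and a visit process with median ~10 visits per woman
    over integer weeks 8-43.
    """

    n_individuals: int = 500
    specs: tuple = (WEIGHT_SPEC, MAP_SPEC)
    fixed_effects: Mapping = field(
        default_factory=lambda: {
            "weight": np.array([65.0, 0.33, 0.50, 0.45]),
            "map": np.array([85.0, -0.30, 0.10, 0.55, 0.60]),
        }
    )
    G_true: np.ndarray | None = None  # default: PD-projected REFERENCE_G
    R_true: np.ndarray = field(
        default_factory=lambda: np.array([[1.6, 0.3], [0.3, 24.0]])
    )
    visit_count_mean: float = 10.0
    visit_count_sd: float = 3.5
    visit_count_range: tuple = (1, 18)
    visit_weeks: tuple = (8, 43)
    late_enrichment: float = 0.03  # relative weight increase per week
    drop_prob: Mapping = field(default_factory=dict)  # response -> P(missing at a visit)
    covariate_model: Mapping = field(default_factory=dict)
    # covariate_model: name -> {"sd": float, "effects": {response: coef}}
    seed: int = 0

    def resolved_G(self) -> np.ndarray:
        if self.G_true is not None:
            return np.asarray(self.G_true, dtype=float)
        G, delta = nearest_pd(REFERENCE_G)
        if delta > 1e-6:
            warnings.warn(f"reference G projected to PD (max entry change {delta:.2e})")
        return G

    def model_spec(self, constraints=None) -> ModelSpec:
        from .hypotheses import ConstraintSet

        return ModelSpec(
            responses=self.specs,
            covariates=tuple(self.covariate_model.keys()),
            constraints=constraints if constraints is not None else ConstraintSet(),
        )


def default_generator(n_individuals: int = 500, seed: int = 0, **kwargs) -> GeneratorSpec:
    """The standard study conditions with only size and seed varying."""
    return GeneratorSpec(n_individuals=n_individuals, seed=seed, **kwargs)


def _psd_factor(A: np.ndarray) -> np.ndarray:
    """Factor L with L L' = A for positive SEMI-definite A (zero allowed)."""
    vals, vecs = np.linalg.eigh(np.atleast_2d(A))
    if vals[0] < -1e-10 * max(vals[-1], 1.0):
        raise ValueError("covariance matrix has negative eigenvalues")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def generate(gspec: GeneratorSpec) -> tuple[LongData, pd.DataFrame]:
    """Simulate a dataset; returns (data, truth).

    ``truth`` has one row per individual with the drawn random effects
    (columns named after the effects) plus any covariate values — the
    oracle against which recovery of G and of adjusted regressions can be
    judged.
    """
    rng = np.random.default_rng(gspec.seed)
    effects = effect_order(gspec.specs)
    M = len(effects)
    G = gspec.resolved_G()
    if G.shape != (M, M):
        raise ValueError(f"G_true must be {M}x{M}, got {G.shape}")
    R = np.atleast_2d(np.asarray(gspec.R_true, dtype=float))
    n_resp = len(gspec.specs)
    if R.shape != (n_resp, n_resp):
        raise ValueError(f"R_true must be {n_resp}x{n_resp}")
    resp_names = [s.response_name for s in gspec.specs]

    L_G = _psd_factor(G)
    L_R = _psd_factor(R)

    lo_w, hi_w = gspec.visit_weeks
    weeks = np.arange(lo_w, hi_w + 1)
    week_p = 1.0 + gspec.late_enrichment * (weeks - weeks[0])
    week_p = week_p / week_p.sum()
    lo_c, hi_c = gspec.visit_count_range
    hi_c = min(hi_c, weeks.size)

    # covariates
    cov_names = list(gspec.covariate_model.keys())
    cov_vals = {
        name: rng.normal(0.0, spec["sd"], size=gspec.n_individuals)
        for name, spec in gspec.covariate_model.items()
    }

    U = rng.standard_normal((gspec.n_individuals, M)) @ L_G.T

    rows = []
    eff_slices, pos = {}, 0
    for s in gspec.specs:
        eff_slices[s.response_name] = slice(pos, pos + 1 + s.n_splines)
        pos += 1 + s.n_splines

    for k in range(gspec.n_individuals):
        n_visits = int(np.clip(np.rint(rng.normal(gspec.visit_count_mean, gspec.visit_count_sd)), lo_c, hi_c))
        times = np.sort(rng.choice(weeks, size=n_visits, replace=False, p=week_p))
        eps = rng.standard_normal((n_visits, n_resp)) @ L_R.T
        for ri, s in enumerate(gspec.specs):
            keep = rng.random(n_visits) >= gspec.drop_prob.get(s.response_name, 0.0)
            t = times[keep]
            if t.size == 0:
                continue
            basis = evaluate_basis(s, t.astype(float))
            fe = np.asarray(gspec.fixed_effects[s.response_name], dtype=float)
            mean = fe[0] + basis @ fe[1:]
            for name in cov_names:
                coef = gspec.covariate_model[name]["effects"].get(s.response_name, 0.0)
                mean = mean + coef * cov_vals[name][k]
            u = U[k, eff_slices[s.response_name]]
            vals = mean + u[0] + basis @ u[1:] + eps[keep, ri]
            for tt, vv in zip(t, vals):
                row = {"individual": k, "time": float(tt), "response": s.response_name, "value": float(vv)}
                for name in cov_names:
                    row[name] = float(cov_vals[name][k])
                rows.append(row)

    df = pd.DataFrame(rows)
    truth = pd.DataFrame(U, columns=[str(e) for e in effects])
    truth.insert(0, "individual", np.arange(gspec.n_individuals))
    for name in cov_names:
        truth[name] = cov_vals[name]
    return LongData(df), truth


def map_from_bp(systolic, diastolic):
    """Mean arterial pressure from systolic and diastolic blood pressure:
    one third systolic plus two thirds diastolic (mmHg)."""
    s = np.asarray(systolic, dtype=float)
    d = np.asarray(diastolic, dtype=float)
    if np.any(d <= 0) or np.any(s < d):
        warnings.warn("expected systolic >= diastolic > 0; check input readings")
    out = s / 3.0 + 2.0 * d / 3.0
    return float(out) if out.ndim == 0 else out


def thin_to_window(data: LongData, window: float, seed: int, anchor: float = 0.0) -> LongData:
    """Keep at most one measurement per individual x response x time window.

    Windows are consecutive half-open spans of length ``window`` anchored at
    ``anchor``; within each occupied window one row is retained uniformly at
    random (deterministic under ``seed``).  Guards against individuals with
    many closely spaced measurements dominating a fit.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rng = np.random.default_rng(seed)
    df = data.df.copy()
    win = np.floor((df["time"].to_numpy(dtype=float) - anchor) / window).astype(int)
    df["_w"] = win
    keep_idx = []
    for _, sub in df.groupby(["individual", "response", "_w"], sort=True):
        if len(sub) == 1:
            keep_idx.append(sub.index[0])
        else:
            keep_idx.append(rng.choice(sub.index.to_numpy()))
    out = df.loc[sorted(keep_idx)].drop(columns="_w").reset_index(drop=True)
    return LongData(out)
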