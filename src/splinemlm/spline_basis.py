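"""Linear-spline bases for piecewise-linear growth trajectories.

A trajectory is parameterised by an intercept at a baseline time and one
slope per period, where periods are delimited by interior knots.  The basis
component for period ``l`` measures how much time the subject has spent in
that period by time ``t``, so the mean trajectory is

    intercept + sum_l slope_l * basis_l(t)

which is continuous and piecewise linear with kinks exactly at the knots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SplineSpec", "evaluate_basis", "period_intervals", "round_to_week"]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout for one response variable.

    Parameters
    ----------
    response_name
        Label of the response this spline set belongs to.
    baseline
        Time origin; the intercept is the expected value here and all
        spline components are zero at this time.
    knots
        Strictly increasing interior knots, all inside ``(baseline, horizon)``.
        With ``m - 1`` knots there are ``m`` splines and ``m`` periods.
    horizon
        End of the observation window.  Only the period intervals depend on
        it; the last spline keeps accruing beyond it.
    """

    response_name: str
    baseline: float
    knots: tuple[float, ...]
    horizon: float

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        object.__setattr__(self, "knots", knots)
        bounds = (float(self.baseline),) + knots + (float(self.horizon),)
        if any(a >= b for a, b in zip(bounds, bounds[1:])):
            raise ValueError(
                f"{self.response_name!r}: require baseline < knots... < horizon, "
                f"got boundaries {bounds}"
            )

    @property
    def n_splines(self) -> int:
        return len(self.knots) + 1

    @property
    def boundaries(self) -> tuple[float, ...]:
        return (self.baseline,) + self.knots + (self.horizon,)

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "baseline": self.baseline,
            "knots": list(self.knots),
            "horizon": self.horizon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            response_name=d["response"],
            baseline=float(d["baseline"]),
            knots=tuple(d["knots"]),
            horizon=float(d["horizon"]),
        )


def evaluate_basis(spec: SplineSpec, t) -> np.ndarray:
    """Evaluate all spline components at time(s) ``t``.

    Component ``l`` (0-based) equals the length of overlap of ``[baseline, t]``
    with period ``l``: ``max(0, min(t, b_{l+1}) - b_l)`` for interior periods,
    with the last component unbounded above (the final period is open-ended).

    Returns an array of shape ``(m,)`` for scalar ``t`` or ``(len(t), m)``
    for vector ``t``.  Times before baseline are rejected; times beyond the
    horizon are allowed (the last spline keeps accruing) with a warning.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < spec.baseline):
        bad = t_arr[t_arr < spec.baseline]
        raise ValueError(
            f"time(s) {bad.tolist()} before baseline {spec.baseline} for "
            f"response {spec.response_name!r}: the model is undefined before baseline"
        )
    if np.any(t_arr > spec.horizon):
        warnings.warn(
            f"time(s) beyond horizon {spec.horizon} for response "
            f"{spec.response_name!r}; last spline keeps accruing",
            stacklevel=2,
        )
    lower = np.array((spec.baseline,) + spec.knots)  # period starts
    upper = np.array(spec.knots + (np.inf,))  # period ends (last open)
    out = np.clip(np.minimum(t_arr[:, None], upper[None, :]) - lower[None, :], 0.0, None)
    return out[0] if scalar else out


def period_intervals(spec: SplineSpec) -> list[tuple[float, float]]:
    """Closed time intervals of the periods, partitioning [baseline, horizon].

    Interval ``l`` is ``[b_l, b_{l+1}]``; consecutive intervals share their
    boundary point (periods meeting at a knot count as adjacent).
    """
    b = spec.boundaries
    return [(b[i], b[i + 1]) for i in range(spec.n_splines)]


def round_to_week(t):
    """Round times to the nearest whole week (half-up for positive times).

    Gestational-age data are often recorded at daily resolution; rounding to
    whole weeks reduces between-individual variation in measurement times and
    makes occasion matching across responses well defined.
    """
    return np.floor(np.asarray(t, dtype=float) + 0.5)
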