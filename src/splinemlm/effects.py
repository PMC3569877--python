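"""Indexing of individual-level random effects.

The multivariate model carries, per response, a random intercept and one
random slope per spline period.  Effects are ordered response by response,
intercept first then slopes in period order; this ordering fixes the rows
and columns of the individual-level covariance matrix G and of its
half-vectorisation used for sampling covariances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .spline_basis import SplineSpec

__all__ = [
    "RandomEffectIndex",
    "intercept",
    "slope",
    "effect_order",
    "effect_position",
    "vech_indices",
    "vech_position",
]


@dataclass(frozen=True, order=True)
class RandomEffectIndex:
    """One random effect: the intercept or a period slope of a response.

    ``period`` is 1-based (period 1 starts at baseline) and ``None`` for
    intercepts.
    """

    response: str
    kind: str  # "intercept" | "slope"
    period: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("intercept", "slope"):
            raise ValueError(f"kind must be 'intercept' or 'slope', got {self.kind!r}")
        if self.kind == "slope" and (self.period is None or self.period < 1):
            raise ValueError("slope effects need a 1-based period")
        if self.kind == "intercept" and self.period is not None:
            raise ValueError("intercept effects carry no period")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.kind == "intercept":
            return f"{self.response}:intercept"
        return f"{self.response}:slope{self.period}"


def intercept(response: str) -> RandomEffectIndex:
    return RandomEffectIndex(response, "intercept")


def slope(response: str, period: int) -> RandomEffectIndex:
    return RandomEffectIndex(response, "slope", period)


def effect_order(specs: Sequence[SplineSpec]) -> list[RandomEffectIndex]:
    """Canonical effect ordering: per response, intercept then slopes 1..m."""
    out: list[RandomEffectIndex] = []
    for spec in specs:
        out.append(intercept(spec.response_name))
        out.extend(slope(spec.response_name, l) for l in range(1, spec.n_splines + 1))
    return out


def effect_position(specs: Sequence[SplineSpec], effect: RandomEffectIndex) -> int:
    order = effect_order(specs)
    try:
        return order.index(effect)
    except ValueError:
        raise KeyError(f"unknown random effect {effect}") from None


def vech_indices(m: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle (i <= j) index pairs of an m x m symmetric matrix."""
    return [(i, j) for i in range(m) for j in range(i, m)]


def vech_position(m: int, i: int, j: int) -> int:
    """Position of entry (i, j) in the vech ordering of ``vech_indices``."""
    if i > j:
        i, j = j, i
    return i * m - i * (i - 1) // 2 + (j - i)
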