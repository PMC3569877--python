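"""Temporal hypotheses as zero-constraints on random-effect covariances.

Hypotheses about the timing of associations between two change processes
are expressed by fixing selected individual-level covariances to zero and
comparing the restricted fit to the unrestricted one by a likelihood-ratio
test.  The degrees of freedom of that test equal the number of constrained
covariances, so each generator here doubles as a df calculator.

Interval conventions: periods are CLOSED intervals; two periods are
"adjacent" when the closed intervals intersect (overlap or shared knot), and
period B is "subsequent" to period A when start(B) >= end(A) — i.e. the
immediately following, boundary-sharing period already counts as subsequent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .effects import RandomEffectIndex, effect_order, intercept, slope
from .spline_basis import SplineSpec, period_intervals

__all__ = [
    "ConstraintSet",
    "same_or_adjacent_only",
    "precedence",
    "block_effect_vs_response",
    "lag",
]

Pair = frozenset  # frozenset of two RandomEffectIndex


def _pair(a: RandomEffectIndex, b: RandomEffectIndex) -> Pair:
    if a == b:
        raise ValueError(f"cannot constrain the variance of {a}: only covariances")
    return frozenset((a, b))


@dataclass(frozen=True)
class ConstraintSet:
    """A set of random-effect pairs whose covariance is fixed at zero.

    ``len(cs)`` is the number of constrained covariances, which is also the
    degrees of freedom of the likelihood-ratio test of the restricted model
    against the unconstrained one.
    """

    pairs: frozenset = field(default_factory=frozenset)
    label: str = ""
    lag: int | None = None

    def __post_init__(self) -> None:
        pairs = frozenset(frozenset(p) for p in self.pairs)
        for p in pairs:
            if len(p) != 2:
                raise ValueError(f"constraint pair must have two distinct effects: {set(p)}")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.pairs

    def __or__(self, other: "ConstraintSet") -> "ConstraintSet":
        return ConstraintSet(self.pairs | other.pairs, label=f"{self.label}+{other.label}")

    def issubset(self, other: "ConstraintSet") -> bool:
        return self.pairs <= other.pairs

    def validate(self, specs: Sequence[SplineSpec]) -> None:
        """Check every referenced effect exists under ``specs``."""
        known = set(effect_order(specs))
        for p in self.pairs:
            for e in p:
                if e not in known:
                    raise KeyError(f"constraint references unknown effect {e}")

    def sorted_pairs(self, specs: Sequence[SplineSpec]) -> list[tuple[RandomEffectIndex, RandomEffectIndex]]:
        order = {e: i for i, e in enumerate(effect_order(specs))}
        out = []
        for p in self.pairs:
            a, b = sorted(p, key=order.__getitem__)
            out.append((a, b))
        return sorted(out, key=lambda ab: (order[ab[0]], order[ab[1]]))


def _slopes_with_intervals(spec: SplineSpec):
    return [
        (slope(spec.response_name, l + 1), iv)
        for l, iv in enumerate(period_intervals(spec))
    ]


def _check_horizon(specs: Sequence[SplineSpec]) -> None:
    for s in specs:
        if s.horizon is None:
            raise ValueError(f"response {s.response_name!r} has no horizon; adjacency undefined")


def same_or_adjacent_only(
    specs: Sequence[SplineSpec], include_within: bool = True
) -> ConstraintSet:
    """Changes are associated only in the same or adjacent time periods.

    Constrains cov(slope_a, slope_b) for every pair of slope effects whose
    closed period intervals are disjoint (no overlap, no shared endpoint).
    Intercepts are never constrained — baseline levels may correlate with
    change in any period.  With ``include_within`` (the default) nonadjacent
    within-response slope pairs are constrained as well as cross-response
    ones; pass ``False`` to restrict cross-response pairs only.
    """
    _check_horizon(specs)
    items = []
    for spec in specs:
        items.extend((spec.response_name, eff, iv) for eff, iv in _slopes_with_intervals(spec))
    pairs = set()
    for i, (resp_a, eff_a, (lo_a, hi_a)) in enumerate(items):
        for resp_b, eff_b, (lo_b, hi_b) in items[i + 1 :]:
            if not include_within and resp_a == resp_b:
                continue
            disjoint = hi_a < lo_b or hi_b < lo_a
            if disjoint:
                pairs.add(_pair(eff_a, eff_b))
    return ConstraintSet(frozenset(pairs), label="same_or_adjacent_only")


def _response_spec(specs: Sequence[SplineSpec], name: str) -> SplineSpec:
    for s in specs:
        if s.response_name == name:
            return s
    raise KeyError(f"unknown response {name!r}")


def precedence(
    specs: Sequence[SplineSpec], from_response: str, to_response: str
) -> ConstraintSet:
    """Change in ``from_response`` is not associated with subsequent change
    in ``to_response``.

    Constrains cov(slope of from in period A, slope of to in period B)
    whenever start(B) >= end(A).  Rejecting this restriction supports the
    reverse temporal ordering (``to`` change preceding ``from`` change is
    left free).
    """
    _check_horizon(specs)
    spec_from = _response_spec(specs, from_response)
    spec_to = _response_spec(specs, to_response)
    pairs = set()
    for eff_a, (_, hi_a) in _slopes_with_intervals(spec_from):
        for eff_b, (lo_b, _) in _slopes_with_intervals(spec_to):
            if eff_a == eff_b:
                continue
            if lo_b >= hi_a:
                pairs.add(_pair(eff_a, eff_b))
    return ConstraintSet(
        frozenset(pairs), label=f"precedence({from_response}->!{to_response})"
    )


def block_effect_vs_response(
    specs: Sequence[SplineSpec],
    effect: RandomEffectIndex,
    other_response: str,
    include_intercept: bool = True,
) -> ConstraintSet:
    """One random effect may not correlate with any effect of another response.

    Constrains cov(effect, e) for every slope e of ``other_response`` and,
    iff ``include_intercept``, its intercept too.
    """
    known = set(effect_order(specs))
    if effect not in known:
        raise KeyError(f"unknown random effect {effect}")
    spec_other = _response_spec(specs, other_response)
    if effect.response == other_response:
        raise ValueError("other_response must differ from the effect's response")
    pairs = set()
    if include_intercept:
        pairs.add(_pair(effect, intercept(other_response)))
    for l in range(1, spec_other.n_splines + 1):
        pairs.add(_pair(effect, slope(other_response, l)))
    return ConstraintSet(frozenset(pairs), label=f"block({effect} x {other_response})")


def lag(
    specs: Sequence[SplineSpec],
    from_response: str,
    to_response: str,
    delta_s: int,
) -> ConstraintSet:
    """A lag of ``delta_s`` periods between change in one variable and the other.

    Constrains the subsequent-period pairs (start(B) >= end(A)) whose
    period-index gap is at most ``delta_s``; pairs beyond the lag stay free.
    The gap is measured in period indices, which coincides with a time gap
    when both responses share one knot set.
    """
    if delta_s < 1:
        raise ValueError("delta_s must be >= 1")
    _check_horizon(specs)
    spec_from = _response_spec(specs, from_response)
    spec_to = _response_spec(specs, to_response)
    max_gap = max(spec_from.n_splines, spec_to.n_splines) - 1
    if delta_s > max_gap:
        warnings.warn(
            f"delta_s={delta_s} exceeds the largest period gap {max_gap}; "
            "the lag constraint saturates to full precedence",
            stacklevel=2,
        )
    pairs = set()
    for eff_a, (_, hi_a) in _slopes_with_intervals(spec_from):
        for eff_b, (lo_b, _) in _slopes_with_intervals(spec_to):
            if eff_a == eff_b:
                continue
            if lo_b >= hi_a and (eff_b.period - eff_a.period) <= delta_s:
                pairs.add(_pair(eff_a, eff_b))
    return ConstraintSet(
        frozenset(pairs),
        label=f"lag({from_response}->{to_response}, delta={delta_s})",
        lag=delta_s,
    )
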