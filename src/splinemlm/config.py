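"""YAML configuration for model specifications and hypothesis constraints.

A config file looks like::

    responses:
      - response: weight
        baseline: 8
        knots: [18, 29]
        horizon: 44
      - response: map
        baseline: 8
        knots: [18, 29, 36]
        horizon: 44
    covariates: [height_c]
    hypotheses:
      adjacency: {type: same_or_adjacent, include_within: true}
      weight_precedes: {type: precedence, from: map, to: weight}
      early_block:
        type: block
        effect: {response: map, kind: slope, period: 1}
        other_response: weight
        include_intercept: true
      one_period_lag: {type: lag, from: weight, to: map, delta: 1}
      custom:
        type: pairs
        pairs:
          - [{response: weight, kind: slope, period: 1},
             {response: map, kind: slope, period: 3}]
"""

from __future__ import annotations

from typing import Mapping

import yaml

from .effects import RandomEffectIndex
from .hypotheses import (
    ConstraintSet,
    block_effect_vs_response,
    lag,
    precedence,
    same_or_adjacent_only,
)
from .mlm_core import ModelSpec
from .spline_basis import SplineSpec

__all__ = ["load_config", "parse_config", "compile_hypothesis", "dump_config"]


def _effect_from_dict(d: Mapping) -> RandomEffectIndex:
    return RandomEffectIndex(d["response"], d["kind"], d.get("period"))


def compile_hypothesis(specs, block: Mapping) -> ConstraintSet:
    """Compile one named hypothesis block to a ConstraintSet."""
    kind = block["type"]
    if kind == "same_or_adjacent":
        return same_or_adjacent_only(specs, include_within=block.get("include_within", True))
    if kind == "precedence":
        return precedence(specs, from_response=block["from"], to_response=block["to"])
    if kind == "block":
        return block_effect_vs_response(
            specs,
            effect=_effect_from_dict(block["effect"]),
            other_response=block["other_response"],
            include_intercept=block.get("include_intercept", True),
        )
    if kind == "lag":
        return lag(specs, from_response=block["from"], to_response=block["to"], delta_s=block["delta"])
    if kind == "pairs":
        pairs = frozenset(
            frozenset(_effect_from_dict(e) for e in pair) for pair in block["pairs"]
        )
        return ConstraintSet(pairs, label="explicit")
    raise ValueError(f"unknown hypothesis type {kind!r}")


def parse_config(cfg: Mapping):
    """Parse a loaded config mapping.

    Returns ``(model_spec, hypotheses)`` where ``hypotheses`` maps each
    named hypothesis block to its ConstraintSet (df = its length).
    """
    specs = tuple(SplineSpec.from_dict(d) for d in cfg["responses"])
    covariates = tuple(cfg.get("covariates", ()))
    hyps = {
        name: compile_hypothesis(specs, blk)
        for name, blk in (cfg.get("hypotheses") or {}).items()
    }
    constraints = ConstraintSet()
    if "constraints" in cfg:  # name of a hypothesis block to bake into the model
        constraints = hyps[cfg["constraints"]]
    mspec = ModelSpec(responses=specs, covariates=covariates, constraints=constraints)
    return mspec, hyps


def load_config(path):
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return parse_config(cfg)


def dump_config(mspec: ModelSpec, path) -> None:
    cfg = {
        "responses": [s.to_dict() for s in mspec.responses],
        "covariates": list(mspec.covariates)
        if not isinstance(mspec.covariates, Mapping)
        else {k: list(v) for k, v in mspec.covariates.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
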