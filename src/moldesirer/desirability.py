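"""Derringer-Suich desirability transforms and their geometric aggregation.

Each raw property value ``x`` is mapped onto a desirability ``d`` in [0, 1]
(1 = fully satisfactory) by one of three piecewise shapes:

* ``larger_the_best``  — 0 below a lower limit ``l``, ramps to 1 at target ``t``
  with exponent ``r``: ``((x-l)/(t-l))**r`` on [l, t], 1 above.
* ``smaller_the_best`` — 1 below target ``t``, decays to 0 at upper limit ``u``:
  ``((u-x)/(u-t))**r`` on [t, u], 0 above.
* ``nominal_the_best`` — 0 outside [l, u], rises with exponent ``r1`` on
  [l, t], falls with exponent ``r2`` on (t, u], peak 1 exactly at ``t``.

Desirabilities are combined with a weighted geometric mean
``D = (prod d_i**w_i)**(1/sum w_i)``, so any fully unacceptable property
(d = 0 with positive weight) annihilates the aggregate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence


class DesirabilityParameterError(ValueError):
    """Limits/target ordering or weight constraints violated."""


@dataclass(frozen=True)
class DesirabilityParams:
    """Parameters of one desirability transform.

    shape selects the piecewise form; l/u/t are the lower limit, upper limit
    and target on the raw property axis; r (or r1/r2 for the nominal shape)
    controls the steepness of the ramp(s); w is the non-negative weight in
    the geometric-mean aggregation.
    """

    shape: str
    t: float
    l: Optional[float] = None
    u: Optional[float] = None
    r: float = 1.0
    r1: Optional[float] = None
    r2: Optional[float] = None
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("larger_the_best", "smaller_the_best", "nominal_the_best"):
            raise DesirabilityParameterError(f"unknown shape {self.shape!r}")
        if self.w < 0:
            raise DesirabilityParameterError(f"weight must be non-negative, got {self.w}")
        for name, val in (("r", self.r), ("r1", self.r1), ("r2", self.r2)):
            if val is not None and val <= 0:
                raise DesirabilityParameterError(f"{name} must be positive, got {val}")
        if self.shape == "larger_the_best":
            if self.l is None or self.l >= self.t:
                raise DesirabilityParameterError(
                    f"larger_the_best requires l < t, got l={self.l}, t={self.t}"
                )
        elif self.shape == "smaller_the_best":
            if self.u is None or self.t >= self.u:
                raise DesirabilityParameterError(
                    f"smaller_the_best requires t < u, got t={self.t}, u={self.u}"
                )
        else:
            if self.l is None or self.u is None or not (self.l < self.t < self.u):
                raise DesirabilityParameterError(
                    f"nominal_the_best requires l < t < u, got l={self.l}, t={self.t}, u={self.u}"
                )

    def __call__(self, x: float) -> float:
        return evaluate(x, self)


def larger_the_best(x: float, p: DesirabilityParams) -> float:
    """Maximization shape: 0 below l, ((x-l)/(t-l))**r on [l, t], 1 above t."""
    if p.shape != "larger_the_best":
        raise DesirabilityParameterError(f"params have shape {p.shape!r}")
    if x < p.l:
        return 0.0
    if x > p.t:
        return 1.0
    return ((x - p.l) / (p.t - p.l)) ** p.r


def smaller_the_best(x: float, p: DesirabilityParams) -> float:
    """Minimization shape: 1 below t, ((u-x)/(u-t))**r on [t, u], 0 above u."""
    if p.shape != "smaller_the_best":
        raise DesirabilityParameterError(f"params have shape {p.shape!r}")
    if x < p.t:
        return 1.0
    if x > p.u:
        return 0.0
    return ((p.u - x) / (p.u - p.t)) ** p.r


def nominal_the_best(x: float, p: DesirabilityParams) -> float:
    """Target shape: 0 outside [l, u]; exponent r1 rising, r2 falling; 1 at t."""
    if p.shape != "nominal_the_best":
        raise DesirabilityParameterError(f"params have shape {p.shape!r}")
    if x < p.l or x > p.u:
        return 0.0
    r1 = p.r1 if p.r1 is not None else p.r
    r2 = p.r2 if p.r2 is not None else p.r
    if x <= p.t:
        return ((x - p.l) / (p.t - p.l)) ** r1
    return ((p.u - x) / (p.u - p.t)) ** r2


_SHAPES = {
    "larger_the_best": larger_the_best,
    "smaller_the_best": smaller_the_best,
    "nominal_the_best": nominal_the_best,
}


def evaluate(x: float, p: DesirabilityParams) -> float:
    return _SHAPES[p.shape](x, p)


def weighted_geometric_mean(d: Sequence[float], w: Sequence[float]) -> float:
    """D = (prod d_i**w_i)**(1/sum w_i), all d_i in [0, 1], weights >= 0.

    A factor with zero weight is ignored entirely (treated as 1), so a
    zero-desirability property only annihilates the mean if its weight is
    positive.
    """
    if len(d) != len(w):
        raise DesirabilityParameterError(f"length mismatch: {len(d)} vs {len(w)}")
    if not d:
        raise DesirabilityParameterError("empty desirability list")
    wsum = 0.0
    log_acc = 0.0
    for di, wi in zip(d, w):
        if wi < 0:
            raise DesirabilityParameterError(f"negative weight {wi}")
        if not (0.0 <= di <= 1.0):
            raise DesirabilityParameterError(f"desirability {di} outside [0, 1]")
        if wi == 0.0:
            continue
        if di == 0.0:
            return 0.0
        wsum += wi
        log_acc += wi * math.log(di)
    if wsum == 0.0:
        raise DesirabilityParameterError("at least one weight must be positive")
    return math.exp(log_acc / wsum)


def default_cost_desirabilities() -> Mapping[str, DesirabilityParams]:
    """Default per-property desirabilities of the built-in composite fitness.

    score (docking-score axis, kcal/mol): smaller-the-best, fully desirable
    at -10 and unacceptable above -2.  qed: larger-the-best, target 0.75,
    lower limit 0.1.  sa_score: smaller-the-best, target 3, upper limit 7.
    All ramps linear (r = 1), all weights 1.
    """
    return {
        "score": DesirabilityParams(shape="smaller_the_best", t=-10.0, u=-2.0, r=1.0, w=1.0),
        "qed": DesirabilityParams(shape="larger_the_best", l=0.1, t=0.75, r=1.0, w=1.0),
        "sa_score": DesirabilityParams(shape="smaller_the_best", t=3.0, u=7.0, r=1.0, w=1.0),
    }


_YAML_SHAPE_NAMES = {
    "LargerTheBest": "larger_the_best",
    "SmallerTheBest": "smaller_the_best",
    "NominalTheBest": "nominal_the_best",
}
_YAML_SHAPE_NAMES_INV = {v: k for k, v in _YAML_SHAPE_NAMES.items()}


def params_from_dict(spec: Mapping) -> DesirabilityParams:
    """Build params from the YAML-config form.

    Keys mirror the configuration columns: ``Function``, ``LowerLimit``,
    ``UpperLimit``, ``Target``, ``r`` (or ``r1``/``r2``), ``w``.  Lowercase
    shape names are accepted too.
    """
    shape = spec.get("Function", spec.get("shape"))
    shape = _YAML_SHAPE_NAMES.get(shape, shape)
    kwargs = dict(
        shape=shape,
        t=spec.get("Target", spec.get("t")),
        l=spec.get("LowerLimit", spec.get("l")),
        u=spec.get("UpperLimit", spec.get("u")),
        r=spec.get("r", 1.0),
        r1=spec.get("r1"),
        r2=spec.get("r2"),
        w=spec.get("w", 1.0),
    )
    if kwargs["t"] is None:
        raise DesirabilityParameterError(f"desirability spec missing Target: {dict(spec)!r}")
    return DesirabilityParams(**kwargs)


def params_to_dict(p: DesirabilityParams) -> dict:
    out = {"Function": _YAML_SHAPE_NAMES_INV[p.shape], "Target": p.t, "r": p.r, "w": p.w}
    if p.l is not None:
        out["LowerLimit"] = p.l
    if p.u is not None:
        out["UpperLimit"] = p.u
    if p.r1 is not None:
        out["r1"] = p.r1
    if p.r2 is not None:
        out["r2"] = p.r2
    return out
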