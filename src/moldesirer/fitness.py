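"""Built-in fitness functions and the fitness-callable contract.

A fitness function takes an :class:`~moldesirer.molkit.Individual` as its
first argument, sets its ``cost`` attribute (lower = better) and returns the
same individual.  Because evaluation runs in worker processes and engine
states are checkpointed to disk, fitness callables must be serializable —
in practice, importable top-level functions.

Four built-ins are provided:

* ``cost`` — composite desirability fitness: docking-axis score, QED and
  synthetic accessibility each mapped through a desirability transform and
  combined by a weighted geometric mean D; the individual's cost is 1 - D.
* ``cost_only_score`` — the raw backend score alone.
* ``cost_multi_receptor`` / ``cost_multi_receptor_only_score`` — the same
  two, generalized to several receptors with per-receptor direction
  (on-target: minimize; anti-target: maximize).
"""

from __future__ import annotations

import inspect
import logging
import math
import pickle
from dataclasses import dataclass, field
from typing import Callable, List, Mapping, Optional

from .desirability import (
    DesirabilityParams,
    default_cost_desirabilities,
    evaluate,
    larger_the_best,
    smaller_the_best,
    weighted_geometric_mean,
)
from .molkit import Individual
from .properties import (
    ConfigurationError,
    EvaluationError,
    PropertyError,
    ReceptorSpec,
    compute_qed,
    compute_sa_score,
    scorer_backend,
)

logger = logging.getLogger(__name__)

BUILTIN_NAMES = (
    "cost",
    "cost_only_score",
    "cost_multi_receptor",
    "cost_multi_receptor_only_score",
)


@dataclass
class FitnessSpec:
    """Configuration of a fitness evaluation.

    desirabilities maps property names ("score", "qed", "sa_score") to their
    transforms; receptors lists the scorer backends to query (one for the
    single-receptor built-ins, two or more for the multi-receptor ones).
    constraint_type, when set, routes scoring through constrained conformer
    generation ("score_only" or "local_only") against constraint_ref /
    constraint_protein.
    """

    name: str = "cost"
    desirabilities: Mapping[str, DesirabilityParams] = field(
        default_factory=default_cost_desirabilities
    )
    receptors: List[ReceptorSpec] = field(default_factory=lambda: [ReceptorSpec()])
    constraint_type: Optional[str] = None
    constraint_ref: Optional[object] = None  # rdkit Mol with 3D coords, or SDF path
    constraint_protein: Optional[str] = None  # PDB path
    constraint_cutoff: float = 1.5
    constraint_n_conf: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BUILTIN_NAMES and self.name != "custom":
            raise ConfigurationError(f"unknown fitness function {self.name!r}")
        if self.name.startswith("cost_multi_receptor") and len(self.receptors) < 2:
            raise ConfigurationError(
                f"{self.name} requires >= 2 receptors, got {len(self.receptors)}"
            )
        if self.constraint_type not in (None, "score_only", "local_only"):
            raise ConfigurationError(f"unknown constraint_type {self.constraint_type!r}")


def _score_one(ind: Individual, spec: FitnessSpec, receptor: ReceptorSpec):
    """Score against one receptor, honoring the constrained-docking mode."""
    if spec.constraint_type is not None and spec.constraint_ref is not None:
        from .constraintconf import constrained_score

        return constrained_score(
            ind,
            spec.constraint_ref,
            spec.constraint_protein,
            mode=spec.constraint_type,
            receptor=receptor,
            cutoff=spec.constraint_cutoff,
            n_conf=spec.constraint_n_conf,
            seed=spec.seed,
        )
    return scorer_backend(ind, receptor)


def cost(ind: Individual, spec: Optional[FitnessSpec] = None) -> Individual:
    """Composite desirability fitness: cost = 1 - D.

    Computes the backend score, QED and synthetic accessibility, maps each
    through its desirability, aggregates with the weighted geometric mean and
    stores 1 - D on the individual.  Any failure poisons only this
    individual: its cost stays +inf and the error is logged with the SMILES.
    """
    spec = spec or FitnessSpec(name="cost")
    try:
        score, pose = _score_one(ind, spec, spec.receptors[0])
        qed = compute_qed(ind.mol)
        sa = compute_sa_score(ind.mol)
    except (EvaluationError, PropertyError, ConfigurationError) as exc:
        logger.warning("evaluation failed for %s: %s", ind.smiles, exc)
        ind.cost = float("inf")
        return ind
    ind.score, ind.qed, ind.sa_score = score, qed, sa
    ind.pdbqt = pose
    values = {"score": score, "qed": qed, "sa_score": sa}
    d = [evaluate(values[k], p) for k, p in spec.desirabilities.items()]
    w = [p.w for p in spec.desirabilities.values()]
    ind.cost = 1.0 - weighted_geometric_mean(d, w)
    return ind


def cost_only_score(ind: Individual, spec: Optional[FitnessSpec] = None) -> Individual:
    """Potency-only fitness: cost = raw backend score (no desirabilities)."""
    spec = spec or FitnessSpec(name="cost_only_score")
    try:
        score, pose = _score_one(ind, spec, spec.receptors[0])
    except (EvaluationError, PropertyError, ConfigurationError) as exc:
        logger.warning("evaluation failed for %s: %s", ind.smiles, exc)
        ind.cost = float("inf")
        return ind
    ind.score = score
    ind.pdbqt = pose
    ind.cost = score
    return ind


def _receptor_desirability(score: float, receptor: ReceptorSpec, spec: FitnessSpec) -> float:
    """Map one receptor's score to a desirability according to its direction.

    On-target ("minimize") uses the smaller-the-best transform of the
    "score" desirability; anti-target ("maximize") uses a larger-the-best
    ramp on the same axis, by default mirroring the score transform's knots.
    """
    base = spec.desirabilities.get("score")
    if receptor.direction == "minimize":
        p = base or DesirabilityParams(shape="smaller_the_best", t=-10.0, u=-2.0)
        if p.shape != "smaller_the_best":
            raise ConfigurationError("on-target score desirability must be smaller_the_best")
        return smaller_the_best(score, p)
    # Anti-target: high (weak) scores are desirable.  Mirror the on-target
    # knots unless the user supplied an explicit anti-target transform.
    anti = spec.desirabilities.get("anti_score")
    if anti is None:
        ref = base or DesirabilityParams(shape="smaller_the_best", t=-10.0, u=-2.0)
        anti = DesirabilityParams(shape="larger_the_best", l=ref.t, t=ref.u, r=ref.r, w=ref.w)
    return larger_the_best(score, anti)


def cost_multi_receptor(ind: Individual, spec: FitnessSpec) -> Individual:
    """Multi-receptor composite fitness.

    One score per receptor; each mapped by direction (minimize/maximize);
    those desirabilities join the QED and synthetic-accessibility ones in the
    weighted geometric mean.  cost = 1 - D.  Any receptor failing poisons the
    individual (cost +inf).
    """
    try:
        scores = []
        pose = ind.pdbqt
        for rec in spec.receptors:
            s, p = _score_one(ind, spec, rec)
            scores.append(s)
            pose = p
        qed = compute_qed(ind.mol)
        sa = compute_sa_score(ind.mol)
    except (EvaluationError, PropertyError, ConfigurationError) as exc:
        logger.warning("evaluation failed for %s: %s", ind.smiles, exc)
        ind.cost = float("inf")
        return ind
    ind.score = scores[0]
    ind.qed, ind.sa_score = qed, sa
    ind.pdbqt = pose
    d = [_receptor_desirability(s, rec, spec) for s, rec in zip(scores, spec.receptors)]
    w = [rec.weight for rec in spec.receptors]
    for key in ("qed", "sa_score"):
        p = spec.desirabilities[key]
        d.append(evaluate({"qed": qed, "sa_score": sa}[key], p))
        w.append(p.w)
    ind.cost = 1.0 - weighted_geometric_mean(d, w)
    return ind


def cost_multi_receptor_only_score(ind: Individual, spec: FitnessSpec) -> Individual:
    """Multi-receptor potency-only fitness: geometric aggregate of the score
    desirabilities alone, cost = 1 - D."""
    try:
        scores = []
        for rec in spec.receptors:
            s, _ = _score_one(ind, spec, rec)
            scores.append(s)
    except (EvaluationError, PropertyError, ConfigurationError) as exc:
        logger.warning("evaluation failed for %s: %s", ind.smiles, exc)
        ind.cost = float("inf")
        return ind
    ind.score = scores[0]
    d = [_receptor_desirability(s, rec, spec) for s, rec in zip(scores, spec.receptors)]
    w = [rec.weight for rec in spec.receptors]
    ind.cost = 1.0 - weighted_geometric_mean(d, w)
    return ind


BUILTINS: Mapping[str, Callable] = {
    "cost": cost,
    "cost_only_score": cost_only_score,
    "cost_multi_receptor": cost_multi_receptor,
    "cost_multi_receptor_only_score": cost_multi_receptor_only_score,
}


def resolve_fitness(name_or_fn) -> Callable:
    if callable(name_or_fn):
        return name_or_fn
    try:
        return BUILTINS[name_or_fn]
    except KeyError:
        raise ConfigurationError(f"unknown fitness function {name_or_fn!r}") from None


def validate_fitness_callable(fn: Callable) -> List[str]:
    """Check a user fitness callable against the engine's contract.

    Returns a list of human-readable violations (empty = contract satisfied):
    the callable must be serializable (it crosses process boundaries and is
    stored in checkpoints), must accept an Individual as its first parameter,
    and must return an Individual with the cost attribute set.
    """
    violations: List[str] = []
    if not callable(fn):
        return ["object is not callable"]
    try:
        pickle.loads(pickle.dumps(fn))
    except Exception as exc:
        violations.append(f"not serializable: {exc}")
    try:
        sig = inspect.signature(fn)
        if not sig.parameters:
            violations.append("takes no parameters; first must accept an Individual")
    except (TypeError, ValueError):
        pass
    try:
        from rdkit import Chem

        probe = Individual(Chem.MolFromSmiles("C"), idx=0)
        result = fn(probe)
        if not isinstance(result, Individual):
            violations.append("does not return an Individual")
        elif not isinstance(result.cost, float) or math.isnan(result.cost):
            violations.append("returned Individual has no finite-or-infinite cost set")
    except Exception as exc:
        violations.append(f"raised on a trial Individual: {exc}")
    return violations
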