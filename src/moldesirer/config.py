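"""YAML run configuration and multi-stage run plans.

A configuration file is a mapping of named runs executed in order.  The
first run must carry the full initialization (mandatory keys: ``seed_mol``,
``costfunc``, ``costfunc_kwargs``, ``fragment_table``); subsequent runs may
only override the mutable search attributes (``maxiter``, ``beta``, ``pc``,
``mutate_crem_kwargs``, ``costfunc_kwargs``).  Example::

    main:
      type: GA
      seed_mol: OCc1ccccc1
      costfunc: cost
      costfunc_kwargs: {}
      fragment_table: fragments.tsv
      popsize: 20
      pc: 0.5
      beta: 1.0
      maxiter: 10
      seed: 1
      deffnm: run1
    refine:
      type: GA
      maxiter: 5
      beta: 3.0
      mutate_crem_kwargs: {min_size: 0, max_size: 1, min_inc: -1, max_inc: 1}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .desirability import params_from_dict, params_to_dict, default_cost_desirabilities
from .fitness import BUILTIN_NAMES, FitnessSpec
from .mutation import MutationParams
from .properties import ConfigurationError, DockingBox, ReceptorSpec

MANDATORY_FIRST_RUN_KEYS = ("seed_mol", "costfunc", "costfunc_kwargs", "fragment_table")

_RUN_KEYS = {
    "type",
    "seed_mol",
    "costfunc",
    "costfunc_kwargs",
    "fragment_table",
    "crem_db_path",  # alias of fragment_table, mirroring the published key name
    "mutate_crem_kwargs",
    "grow_crem_kwargs",
    "popsize",
    "pc",
    "beta",
    "maxiter",
    "seed",
    "njobs",
    "deffnm",
    "pick",
    "protected_atom_indices",
}

_MUTATE_KEYS = {"radius", "min_size", "max_size", "min_inc", "max_inc"}

_OVERRIDE_KEYS = {
    "type",
    "maxiter",
    "beta",
    "pc",
    "mutate_crem_kwargs",
    "grow_crem_kwargs",
    "costfunc_kwargs",
    "deffnm",
    "njobs",
    "pick",
    "protected_atom_indices",
}


@dataclass
class RunSpec:
    """One named run in a plan."""

    name: str
    type: str = "GA"
    options: Dict = field(default_factory=dict)


@dataclass
class RunPlan:
    """Ordered list of runs; the first carries full initialization."""

    runs: List[RunSpec]

    def to_dict(self) -> Dict:
        return {run.name: {"type": run.type, **run.options} for run in self.runs}


def parse_config(yaml_text: str) -> RunPlan:
    """Parse and validate a YAML run plan.

    Unknown keys are rejected with their path; the first run must carry the
    mandatory initialization keys; later runs may only override mutable
    attributes.  Default desirability parameters are injected when the
    composite fitness is requested without an explicit table.
    """
    data = yaml.safe_load(yaml_text)
    if not isinstance(data, dict) or not data:
        raise ConfigurationError("configuration must be a non-empty mapping of named runs")
    runs: List[RunSpec] = []
    for i, (name, body) in enumerate(data.items()):
        if not isinstance(body, dict):
            raise ConfigurationError(f"run {name!r} must be a mapping")
        unknown = set(body) - _RUN_KEYS
        if unknown:
            raise ConfigurationError(
                f"unknown key(s) in run {name!r}: {', '.join(sorted(unknown))}"
            )
        body = dict(body)
        if "crem_db_path" in body:
            body["fragment_table"] = body.pop("crem_db_path")
        for mkey in ("mutate_crem_kwargs", "grow_crem_kwargs"):
            if mkey in body:
                extra = set(body[mkey]) - _MUTATE_KEYS - {"protected_atom_indices"}
                if extra:
                    raise ConfigurationError(
                        f"unknown key(s) in {name}.{mkey}: {', '.join(sorted(extra))}"
                    )
        run_type = body.pop("type", "GA")
        if run_type not in ("GA", "Local"):
            raise ConfigurationError(f"run {name!r}: type must be GA or Local, got {run_type!r}")
        if i == 0:
            missing = [k for k in MANDATORY_FIRST_RUN_KEYS if k not in body]
            if missing:
                raise ConfigurationError(
                    f"run {name!r} is missing mandatory key(s): {', '.join(missing)}"
                )
            if body["costfunc"] not in BUILTIN_NAMES and body["costfunc"] != "custom":
                raise ConfigurationError(f"unknown costfunc {body['costfunc']!r}")
        else:
            illegal = set(body) - _OVERRIDE_KEYS
            if illegal:
                raise ConfigurationError(
                    f"run {name!r} may only override mutable attributes; "
                    f"illegal key(s): {', '.join(sorted(illegal))}"
                )
        runs.append(RunSpec(name=name, type=run_type, options=body))
    return RunPlan(runs=runs)


def serialize_config(plan: RunPlan) -> str:
    return yaml.safe_dump(plan.to_dict(), sort_keys=False)


def fitness_spec_from_kwargs(costfunc: str, kwargs: Dict, seed: int = 0) -> FitnessSpec:
    """Build a FitnessSpec from the ``costfunc_kwargs`` mapping.

    Recognized keys: ``desirability`` (per-property mapping with the
    Function/LowerLimit/UpperLimit/Target/r/w columns), ``receptors`` (list
    of receptor mappings with backend/receptor_path/box/direction/weight),
    ``constraint_type``, ``constraint_ref``, ``constraint_protein``,
    ``constraint_cutoff``, ``constraint_n_conf``.
    """
    kwargs = dict(kwargs or {})
    desirabilities = default_cost_desirabilities()
    if "desirability" in kwargs:
        desirabilities = {
            prop: params_from_dict(spec) for prop, spec in kwargs.pop("desirability").items()
        }
    receptors = [ReceptorSpec()]
    if "receptors" in kwargs:
        receptors = []
        for rec in kwargs.pop("receptors"):
            rec = dict(rec)
            box = rec.pop("box", None)
            if box is not None:
                rec["box"] = DockingBox(
                    center=tuple(box.get("center", (0, 0, 0))),
                    dimensions=tuple(box.get("dimensions", (20, 20, 20))),
                    exhaustiveness=int(box.get("exhaustiveness", 9)),
                )
            receptors.append(ReceptorSpec(**rec))
    spec = FitnessSpec(
        name=costfunc if costfunc in BUILTIN_NAMES else "custom",
        desirabilities=desirabilities,
        receptors=receptors,
        constraint_type=kwargs.pop("constraint_type", None),
        constraint_ref=kwargs.pop("constraint_ref", None),
        constraint_protein=kwargs.pop("constraint_protein", None),
        constraint_cutoff=float(kwargs.pop("constraint_cutoff", 1.5)),
        constraint_n_conf=int(kwargs.pop("constraint_n_conf", 20)),
        seed=seed,
    )
    if kwargs:
        raise ConfigurationError(
            f"unknown costfunc_kwargs key(s): {', '.join(sorted(kwargs))}"
        )
    return spec


def mutation_params_from_kwargs(kwargs: Optional[Dict], protected=frozenset()) -> MutationParams:
    kwargs = dict(kwargs or {})
    protected = frozenset(kwargs.pop("protected_atom_indices", protected))
    return MutationParams(protected_atom_indices=protected, **kwargs)


def desirability_table_to_yaml(desirabilities) -> str:
    """Serialize a desirability table back to its YAML column form."""
    return yaml.safe_dump(
        {prop: params_to_dict(p) for prop, p in desirabilities.items()}, sort_keys=False
    )
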