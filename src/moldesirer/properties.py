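"""Molecular property calculators and scorer backends.

Drug-likeness (QED) and synthetic accessibility delegate to the published
RDKit implementations.  The "score" axis — a docking-like binding-affinity
estimate in kcal/mol — is served by a pluggable backend registry: the
built-in ``surrogate`` backend is a smooth, deterministic function of
heavy-atom count so the whole engine can be exercised without a docking
engine, and a ``vina`` adapter shells out to an external executable when one
is configured.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

from rdkit import Chem
from rdkit.Chem import QED, RDConfig

from .molkit import PLACEHOLDER_PDBQT, Individual, mol_from_input

# The synthetic-accessibility scorer ships in RDKit's Contrib tree.
sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402


class PropertyError(RuntimeError):
    """A descriptor computation failed; carries the offending SMILES."""


class ConfigurationError(ValueError):
    """Invalid or missing configuration (unknown backend, absent adapter...)."""


class EvaluationError(RuntimeError):
    """A scorer backend failed on a molecule; caller maps this to cost +inf."""


def compute_qed(mol: str | Chem.Mol) -> float:
    """Quantitative Estimate of Drug-likeness, strictly inside (0, 1).

    The standard weighted-desirability composite over the eight published
    physicochemical properties, with default weights.
    """
    if isinstance(mol, str):
        mol = mol_from_input(mol)
    try:
        return float(QED.qed(mol))
    except Exception as exc:
        raise PropertyError(f"qed failed for {Chem.MolToSmiles(mol)!r}: {exc}") from exc


def compute_sa_score(mol: str | Chem.Mol) -> float:
    """Synthetic accessibility score in [1, 10]; 1 = easy, 10 = hard.

    Fragment-contribution score with complexity penalties, per the published
    parameterization shipped with RDKit.
    """
    if isinstance(mol, str):
        mol = mol_from_input(mol)
    try:
        return float(sascorer.calculateScore(mol))
    except Exception as exc:
        raise PropertyError(f"sa_score failed for {Chem.MolToSmiles(mol)!r}: {exc}") from exc


def heavy_atom_count(mol: str | Chem.Mol) -> int:
    if isinstance(mol, str):
        mol = mol_from_input(mol)
    return mol.GetNumHeavyAtoms()


# Quadratic surrogate: minimum -6.125 at H = 35 heavy atoms, zero at H = 70.
# Magnitudes mimic a docking score that improves with ligand size and then
# saturates; purely a deterministic test device, not a physical model.
_SURROGATE_A = -0.35
_SURROGATE_B = 0.005


def surrogate_score(mol: str | Chem.Mol) -> float:
    """Deterministic docking-score stand-in: -0.35*H + 0.005*H^2 (H = heavy atoms)."""
    h = heavy_atom_count(mol)
    return _SURROGATE_A * h + _SURROGATE_B * h * h


@dataclass(frozen=True)
class DockingBox:
    """Search box for a docking engine: center and edge lengths in Angstrom."""

    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    dimensions: Tuple[float, float, float] = (20.0, 20.0, 20.0)
    exhaustiveness: int = 9

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dimensions):
            raise ConfigurationError(f"box dimensions must be positive: {self.dimensions}")
        if self.exhaustiveness < 1:
            raise ConfigurationError("exhaustiveness must be >= 1")


@dataclass
class ReceptorSpec:
    """One receptor for scoring: backend name, optional files, and direction.

    direction is "minimize" for an on-target receptor (more negative score is
    better) or "maximize" for an anti-target (binding is penalized).
    """

    backend: str = "surrogate"
    receptor_path: Optional[str] = None
    box: DockingBox = field(default_factory=DockingBox)
    direction: str = "minimize"
    weight: float = 1.0
    vina_executable: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")


BackendFn = Callable[[Individual, ReceptorSpec], Tuple[float, str]]

_BACKENDS: Dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    _BACKENDS[name] = fn


def get_backend(name: str) -> BackendFn:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scorer backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None


def scorer_backend(individual: Individual, receptor: ReceptorSpec) -> Tuple[float, str]:
    """Score one individual against one receptor spec.

    Returns ``(score, pose_payload)``.  Backend failures are re-raised as
    :class:`EvaluationError`; the caller maps them to cost ``+inf``.
    """
    fn = get_backend(receptor.backend)
    try:
        score, pose = fn(individual, receptor)
    except (ConfigurationError, EvaluationError):
        raise
    except Exception as exc:
        raise EvaluationError(f"backend {receptor.backend!r} failed on {individual.smiles}: {exc}") from exc
    if not isinstance(score, float) or score != score:
        raise EvaluationError(f"backend {receptor.backend!r} returned non-finite score")
    return score, pose


def _surrogate_backend(individual: Individual, receptor: ReceptorSpec) -> Tuple[float, str]:
    return surrogate_score(individual.mol), PLACEHOLDER_PDBQT


def _vina_backend(individual: Individual, receptor: ReceptorSpec) -> Tuple[float, str]:
    """Adapter to an external AutoDock-Vina executable (optional).

    The engine itself never parses docking files beyond the reported
    affinity; poses are carried as opaque text.
    """
    import re
    import subprocess
    import tempfile

    exe = receptor.vina_executable
    if not exe or not os.path.exists(exe):
        raise ConfigurationError(
            "no vina executable configured; set receptor.vina_executable or use the "
            "'surrogate' backend"
        )
    if not receptor.receptor_path:
        raise ConfigurationError("the vina backend requires a prepared receptor file")
    if individual.pdbqt == PLACEHOLDER_PDBQT:
        raise EvaluationError(
            f"no ligand pose payload available for {individual.smiles}; the vina "
            "backend scores externally prepared ligands only"
        )
    box = receptor.box
    with tempfile.NamedTemporaryFile("w", suffix=".pdbqt", delete=False) as fh:
        fh.write(individual.pdbqt)
        ligand = fh.name
    try:
        cmd = [
            exe, "--receptor", receptor.receptor_path, "--ligand", ligand,
            "--center_x", str(box.center[0]), "--center_y", str(box.center[1]),
            "--center_z", str(box.center[2]),
            "--size_x", str(box.dimensions[0]), "--size_y", str(box.dimensions[1]),
            "--size_z", str(box.dimensions[2]),
            "--exhaustiveness", str(box.exhaustiveness), "--score_only",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True, timeout=600)
        if proc.returncode != 0:
            raise EvaluationError(f"vina exited {proc.returncode}: {proc.stderr[:500]}")
        match = re.search(r"Affinity:\s*(-?\d+\.?\d*)", proc.stdout)
        if match is None:
            raise EvaluationError("could not parse an affinity from vina output")
        return float(match.group(1)), individual.pdbqt
    finally:
        os.unlink(ligand)


register_backend("surrogate", _surrogate_backend)
register_backend("vina", _vina_backend)
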