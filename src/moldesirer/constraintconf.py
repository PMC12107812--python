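"""Constrained conformer generation and protein-clash filtering.

For lead optimization it is often essential that a candidate keep not only
the chemical structure of a validated core but also its 3D binding
geometry.  This module maps a reference core into a candidate, embeds
conformers with the mapped atoms pinned to the reference coordinates
(falling back to rigid alignment of an unconstrained conformer when the
constrained embedding fails), and removes any conformer that collides with
the protein (any ligand heavy atom within a cutoff distance of any protein
heavy atom; hydrogens are ignored throughout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdFMCS
from scipy.spatial.distance import cdist

from .molkit import Individual, mol_from_input
from .properties import EvaluationError, ReceptorSpec, scorer_backend

logger = logging.getLogger(__name__)

#: Maximum core RMSD (Angstrom) for an embedded conformer to count as constrained.
TAU_CORE = 0.1
DEFAULT_CLASH_CUTOFF = 1.5  # Angstrom
DEFAULT_N_CONF = 20


class MappingError(RuntimeError):
    """Reference core could not be mapped into the candidate."""


class ConstraintError(RuntimeError):
    """No constrained conformer could be produced (or all clash)."""


@dataclass
class ConformerSet:
    """Conformers of one candidate with core bookkeeping.

    core_mapping maps candidate-atom index -> reference-atom index
    (injective); clash_flags / core_rmsd / fallback are per conformer.
    The surviving set is the conformers whose clash flag is False.
    """

    smiles: str
    mol: Chem.Mol  # carries the conformers
    core_mapping: Dict[int, int]
    core_rmsd: List[float] = field(default_factory=list)
    clash_flags: List[bool] = field(default_factory=list)
    fallback: List[bool] = field(default_factory=list)
    energies: List[float] = field(default_factory=list)

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    @property
    def surviving(self) -> List[int]:
        return [i for i in range(self.n_conformers) if not self.clash_flags[i]]


def map_core(candidate: Chem.Mol, reference: Chem.Mol) -> Dict[int, int]:
    """Map the reference's heavy-atom graph into the candidate.

    Substructure match first; among multiple matches the one with the
    smallest mapped-index sum wins (deterministic tie-break).  Falls back to
    a maximum-common-substructure match; an empty result raises.
    Returns {candidate_atom_idx: reference_atom_idx}.
    """
    ref = Chem.RemoveHs(reference)
    cand = Chem.RemoveHs(candidate)
    matches = cand.GetSubstructMatches(ref, uniquify=True, maxMatches=64)
    if matches:
        best = min(matches, key=lambda m: (sum(m), m))
        return {cand_idx: ref_idx for ref_idx, cand_idx in enumerate(best)}
    mcs = rdFMCS.FindMCS(
        [cand, ref], completeRingsOnly=True, timeout=10
    )
    # Fewer than 3 mapped atoms cannot define a rigid 3D frame for the core.
    if mcs.numAtoms < 3:
        raise MappingError("reference core does not map into the candidate")
    patt = Chem.MolFromSmarts(mcs.smartsString)
    cand_match = cand.GetSubstructMatch(patt)
    ref_match = ref.GetSubstructMatch(patt)
    if not cand_match or not ref_match:
        raise MappingError("reference core does not map into the candidate")
    return {c: r for c, r in zip(cand_match, ref_match)}


def constrained_embed(
    candidate: Chem.Mol,
    reference: Chem.Mol,
    mapping: Optional[Dict[int, int]] = None,
    seed: int = 0,
    n_conf: int = DEFAULT_N_CONF,
) -> ConformerSet:
    """Generate conformers with the mapped core pinned to reference coordinates.

    Each conformer is embedded with a coordinate map forcing the mapped
    candidate atoms onto the reference positions; conformers whose resulting
    core RMSD exceeds the tolerance (or whose embedding fails outright) are
    regenerated unconstrained and rigidly aligned on the mapped atoms
    instead, and flagged as fallbacks.  Raises if nothing can be produced.
    """
    if reference.GetNumConformers() == 0:
        raise ConstraintError("reference molecule has no 3D coordinates")
    if mapping is None:
        mapping = map_core(candidate, reference)
    if not mapping:
        raise ConstraintError("empty core mapping")
    values = list(mapping.values())
    if len(set(values)) != len(values):
        raise ConstraintError("core mapping is not injective")

    cand = Chem.Mol(Chem.RemoveHs(candidate))
    cand.RemoveAllConformers()
    ref_conf = Chem.RemoveHs(reference).GetConformer()
    coord_map = {
        cand_idx: ref_conf.GetAtomPosition(ref_idx) for cand_idx, ref_idx in mapping.items()
    }
    atom_map = [(c, r) for c, r in mapping.items()]  # (probe, ref) pairs for alignment

    out = ConformerSet(smiles=Chem.MolToSmiles(cand), mol=cand, core_mapping=dict(mapping))
    ref_pts = np.array([[*ref_conf.GetAtomPosition(r)] for _, r in atom_map])

    for i in range(n_conf):
        # Embed with explicit hydrogens for sane geometry; heavy-atom indices
        # are preserved (hydrogens are appended), so the coordinate map and
        # the mapping stay valid.  Hydrogens are stripped again afterwards.
        probe = Chem.AddHs(Chem.Mol(cand))
        probe.RemoveAllConformers()
        params_seed = seed * 1000 + i + 1
        cid = AllChem.EmbedMolecule(
            probe, coordMap=coord_map, randomSeed=params_seed, useRandomCoords=True
        )
        used_fallback = False
        if cid < 0:
            cid = AllChem.EmbedMolecule(probe, randomSeed=params_seed)
            if cid < 0:
                continue
            used_fallback = True
        probe = Chem.RemoveHs(probe)
        rmsd = _core_rmsd(probe, cid, atom_map, ref_pts)
        if not used_fallback and rmsd > TAU_CORE:
            # Constrained embedding drifted; realign rigidly instead.
            used_fallback = True
        if used_fallback:
            AllChem.AlignMol(
                probe, Chem.RemoveHs(reference), prbCid=cid, atomMap=atom_map
            )
            rmsd = _core_rmsd(probe, cid, atom_map, ref_pts)
        conf = probe.GetConformer(cid)
        new_id = out.mol.AddConformer(conf, assignId=True)
        try:
            ff = AllChem.UFFGetMoleculeForceField(out.mol, confId=new_id)
            energy = ff.CalcEnergy() if ff is not None else float("nan")
        except Exception:
            energy = float("nan")
        out.core_rmsd.append(rmsd)
        out.fallback.append(used_fallback)
        out.energies.append(energy)
        out.clash_flags.append(False)

    if out.n_conformers == 0:
        raise ConstraintError(f"no conformer could be generated for {out.smiles}")
    return out


def _core_rmsd(
    mol: Chem.Mol, conf_id: int, atom_map: List[Tuple[int, int]], ref_pts: np.ndarray
) -> float:
    conf = mol.GetConformer(conf_id)
    pts = np.array([[*conf.GetAtomPosition(c)] for c, _ in atom_map])
    return float(np.sqrt(np.mean(np.sum((pts - ref_pts) ** 2, axis=1))))


def read_protein_coords(path: str) -> np.ndarray:
    """Heavy-atom coordinates from a PDB file; waters (HOH) skipped."""
    coords = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            resname = line[17:20].strip()
            if resname == "HOH":
                continue
            element = line[76:78].strip() or line[12:16].strip()[:1]
            if element.upper().startswith("H"):
                continue
            coords.append(
                (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            )
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def clash_filter(
    confs: ConformerSet,
    protein_coords: np.ndarray,
    cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> ConformerSet:
    """Flag and drop conformers with any heavy atom within cutoff of the protein.

    A conformer clashes iff min over (ligand heavy atom, protein heavy atom)
    pairs of the Euclidean distance is < cutoff.  An empty protein list is a
    warned no-op.  Mutates and returns the same ConformerSet (flags updated;
    surviving set shrinks).
    """
    protein_coords = np.asarray(protein_coords, dtype=float).reshape(-1, 3)
    if protein_coords.size == 0:
        logger.warning("clash filter called with no protein atoms; keeping everything")
        return confs
    heavy_idx = [a.GetIdx() for a in confs.mol.GetAtoms() if a.GetAtomicNum() > 1]
    for i in range(confs.n_conformers):
        conf = confs.mol.GetConformer(i)
        pts = np.array([[*conf.GetAtomPosition(j)] for j in heavy_idx])
        min_dist = cdist(pts, protein_coords).min()
        if min_dist < cutoff:
            confs.clash_flags[i] = True
    return confs


def best_conformer(confs: ConformerSet) -> int:
    """Best surviving conformer: lowest core RMSD, then lowest embedding
    energy, then lowest conformer index."""
    survivors = confs.surviving
    if not survivors:
        raise ConstraintError("all conformers clash with the protein")
    def key(i):
        e = confs.energies[i]
        return (confs.core_rmsd[i], e if e == e else float("inf"), i)
    return min(survivors, key=key)


def constrained_score(
    candidate: Individual,
    reference,
    protein: Optional[str],
    mode: str = "score_only",
    receptor: Optional[ReceptorSpec] = None,
    cutoff: float = DEFAULT_CLASH_CUTOFF,
    n_conf: int = DEFAULT_N_CONF,
    seed: int = 0,
) -> Tuple[float, str]:
    """Score a candidate through the constrained-conformer pipeline.

    ``score_only`` scores the best surviving conformer as-is; ``local_only``
    asks the backend to relax the pose first, which only an external docking
    engine can do — under the built-in surrogate it degrades to score_only
    with a warning.  Constraint failures raise EvaluationError, which the
    fitness layer maps to cost +inf.
    """
    if mode not in ("score_only", "local_only"):
        raise ValueError(f"unknown constraint mode {mode!r}")
    receptor = receptor or ReceptorSpec()
    ref_mol = reference if isinstance(reference, Chem.Mol) else _load_reference(reference)
    try:
        confs = constrained_embed(candidate.mol, ref_mol, seed=seed, n_conf=n_conf)
    except (MappingError, ConstraintError) as exc:
        raise EvaluationError(f"constraint failure for {candidate.smiles}: {exc}") from exc
    if protein is not None:
        coords = protein if isinstance(protein, np.ndarray) else read_protein_coords(protein)
        clash_filter(confs, coords, cutoff=cutoff)
    try:
        best = best_conformer(confs)
    except ConstraintError as exc:
        raise EvaluationError(f"constraint failure for {candidate.smiles}: {exc}") from exc
    if mode == "local_only" and receptor.backend == "surrogate":
        logger.warning(
            "local_only constrained scoring requires an external docking engine; "
            "degrading to score_only under the surrogate backend"
        )
    posed = Individual(_with_single_conformer(confs.mol, best), idx=candidate.idx)
    score, pose = scorer_backend(posed, receptor)
    candidate.mol = posed.mol  # keep the constrained pose on the individual
    return score, pose


def _with_single_conformer(mol: Chem.Mol, conf_id: int) -> Chem.Mol:
    out = Chem.Mol(mol)
    out.RemoveAllConformers()
    out.AddConformer(Chem.Conformer(mol.GetConformer(conf_id)), assignId=True)
    return out


def _load_reference(path: str) -> Chem.Mol:
    if str(path).endswith(".sdf"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for mol in supplier:
            if mol is not None:
                return mol
        raise ConstraintError(f"no molecule in reference file {path}")
    return mol_from_input(open(path).read())
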