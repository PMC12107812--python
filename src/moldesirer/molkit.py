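"""Molecule wrapper and identity semantics shared by the whole engine.

The central type is :class:`Individual`: one candidate molecule carrying its
canonical SMILES identity, an opaque docked-pose payload, and a scalar cost
(lower is better, ``+inf`` = unevaluated or failed).  Equality and hashing are
defined on the canonical SMILES alone, so populations and "already seen"
bookkeeping behave like sets of chemical structures rather than of Python
objects.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, DataStructs

logger = logging.getLogger(__name__)

#: Placeholder pose payload written by the built-in surrogate scorer.
PLACEHOLDER_PDBQT = "REMARK surrogate pose placeholder\n"


class MoleculeParseError(ValueError):
    """Input string could not be parsed into a valid, sanitizable molecule."""


class Individual:
    """One candidate molecule in a population.

    Parameters
    ----------
    mol : rdkit.Chem.Mol
        Molecular graph, optionally carrying a 3D conformer.
    idx : int
        Integer identifier assigned by the engine.
    pdbqt : str, optional
        Opaque text payload for a docked pose; a placeholder comment block
        until a scorer backend provides one.
    cost : float, optional
        Scalar fitness, lower is better.  Defaults to ``+inf`` (unevaluated).

    Notes
    -----
    ``smiles`` is computed once at construction (canonical, hydrogens
    implicit, stereo preserved) and is immutable afterwards.  Two individuals
    compare equal iff their SMILES strings are identical; the hash is derived
    from the SMILES only.
    """

    __slots__ = ("mol", "idx", "_smiles", "pdbqt", "cost", "score", "qed", "sa_score")

    def __init__(
        self,
        mol: Chem.Mol,
        idx: int = 0,
        pdbqt: str = PLACEHOLDER_PDBQT,
        cost: float = float("inf"),
    ) -> None:
        if mol is None:
            raise MoleculeParseError("cannot build an Individual from None")
        self.mol = mol
        self.idx = int(idx)
        self._smiles = canonical_smiles(mol)
        self.pdbqt = pdbqt
        self.cost = float(cost)
        # Per-property values filled in by fitness functions (NaN = not computed).
        self.score = float("nan")
        self.qed = float("nan")
        self.sa_score = float("nan")

    @property
    def smiles(self) -> str:
        return self._smiles

    @property
    def evaluated(self) -> bool:
        return np.isfinite(self.cost)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Individual):
            return NotImplemented
        return self._smiles == other._smiles

    def __hash__(self) -> int:
        return hash(self._smiles)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Individual(idx={self.idx}, smiles={self._smiles!r}, cost={self.cost:g})"

    def copy(self) -> "Individual":
        new = Individual(Chem.Mol(self.mol), self.idx, self.pdbqt, self.cost)
        new.score, new.qed, new.sa_score = self.score, self.qed, self.sa_score
        return new

    def __getstate__(self):
        state = {s: getattr(self, s) for s in self.__slots__ if s != "mol"}
        state["mol"] = self.mol.ToBinary() if self.mol is not None else None
        return state

    def __setstate__(self, state):
        for s in self.__slots__:
            if s != "mol":
                object.__setattr__(self, s, state[s])
        self.mol = Chem.Mol(state["mol"]) if state["mol"] is not None else None


def mol_from_input(structure: str | Chem.Mol) -> Chem.Mol:
    """Parse a SMILES string or MOL block (or pass through an RDKit Mol).

    Raises
    ------
    MoleculeParseError
        If the string does not parse or the molecule fails sanitization;
        the message names the offending input.
    """
    if isinstance(structure, Chem.Mol):
        mol = Chem.Mol(structure)
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:
            raise MoleculeParseError(f"molecule failed sanitization: {exc}") from exc
        return mol
    text = str(structure)
    if not text.strip():
        raise MoleculeParseError("empty molecular input")
    if "\n" in text or text.strip().endswith("END"):
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    else:
        mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        raise MoleculeParseError(f"could not parse molecular input {text!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise MoleculeParseError(f"sanitization failed for {text!r}: {exc}") from exc
    return mol


def make_individual(structure: str | Chem.Mol, idx: int = 0) -> Individual:
    """Build an :class:`Individual` from a SMILES string or MOL block."""
    return Individual(mol_from_input(structure), idx=idx)


def canonical_smiles(mol: str | Chem.Mol) -> str:
    """Canonical SMILES without explicit hydrogens, stereo preserved.

    Accepts an RDKit Mol or a SMILES string.  Canonicalization is idempotent:
    re-parsing the output and canonicalizing again returns the same string.
    """
    if isinstance(mol, str):
        mol = mol_from_input(mol)
    return Chem.MolToSmiles(Chem.RemoveHs(mol))


class Fingerprint:
    """Fixed-length binary Morgan fingerprint.

    Thin wrapper keeping the bit vector together with the radius/length it
    was computed at, plus conversions to numpy for the analytics code.
    """

    __slots__ = ("bits", "radius", "nbits")

    def __init__(self, bits: DataStructs.ExplicitBitVect, radius: int, nbits: int):
        self.bits = bits
        self.radius = radius
        self.nbits = nbits

    def to_numpy(self) -> np.ndarray:
        arr = np.zeros(self.nbits, dtype=np.uint8)
        DataStructs.ConvertToNumpyArray(self.bits, arr)
        return arr

    def __len__(self) -> int:
        return self.nbits

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return self.nbits == other.nbits and list(self.bits.GetOnBits()) == list(
            other.bits.GetOnBits()
        )


def morgan_fingerprint(mol: str | Chem.Mol, radius: int = 2, nbits: int = 2048) -> Fingerprint:
    """Morgan (circular/ECFP-like) fingerprint, default radius 2 / 2048 bits."""
    if nbits <= 0:
        raise ValueError(f"nbits must be positive, got {nbits}")
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    if isinstance(mol, str):
        mol = mol_from_input(mol)
    gen = AllChem.GetMorganGenerator(radius=radius, fpSize=nbits)
    return Fingerprint(gen.GetFingerprint(mol), radius, nbits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| in [0, 1].

    Two all-zero fingerprints are defined as identical (similarity 1.0):
    both molecules are "featureless" at the chosen radius.
    """
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    if a.bits.GetNumOnBits() == 0 and b.bits.GetNumOnBits() == 0:
        return 1.0
    return DataStructs.TanimotoSimilarity(a.bits, b.bits)


def write_sdf(individuals: Sequence[Individual], path: str) -> int:
    """Write individuals with 3D coordinates to an SDF (V2000) file.

    Each record carries ``idx``, ``smiles`` and ``cost`` as SDF data fields.
    Individuals without a conformer are skipped with a logged warning.
    Returns the number of records written.
    """
    written = 0
    writer = Chem.SDWriter(str(path))
    try:
        for ind in individuals:
            mol = ind.mol
            if mol is None or mol.GetNumConformers() == 0:
                logger.warning("skipping %s in SDF export: no 3D conformer", ind.smiles)
                continue
            mol = Chem.Mol(mol)
            mol.SetProp("idx", str(ind.idx))
            mol.SetProp("smiles", ind.smiles)
            mol.SetProp("cost", repr(ind.cost))
            writer.write(mol)
            written += 1
    finally:
        writer.close()
    return written


def read_sdf(path: str) -> List[Individual]:
    """Read an SDF written by :func:`write_sdf` back into individuals."""
    out: List[Individual] = []
    import os

    if os.path.getsize(str(path)) == 0:
        return out
    for mol in Chem.SDMolSupplier(str(path), removeHs=False):
        if mol is None:
            continue
        idx = int(mol.GetProp("idx")) if mol.HasProp("idx") else 0
        cost = float(mol.GetProp("cost")) if mol.HasProp("cost") else float("inf")
        out.append(Individual(mol, idx=idx, cost=cost))
    return out
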