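"""Fragment-based structure generation: the mutate/grow operators.

The built-in mutator replaces one terminal fragment of the parent (a
connected set of heavy atoms attached to the rest of the molecule by exactly
one bond — size 0 meaning a hydrogen position) with a fragment drawn from a
fragment table, subject to a heavy-atom increment window.  This supplies the
mutate/grow semantics the evolutionary engine needs; an adapter to an
external interchangeable-fragment library (CReM) forwards the same parameter
set verbatim when that library is installed.

Parameter contract (mirroring the staged-campaign controls):

* ``radius`` — context-sphere size of the external library; accepted and
  ignored by the built-in mutator (context tables require the external
  fragment database).
* ``min_size``/``max_size`` — heavy atoms of the replaced fragment
  (0 = hydrogen positions).
* ``min_inc``/``max_inc`` — allowed change in total heavy-atom count,
  may be negative (deletions).
* ``protected_atom_indices`` — heavy atoms never removed or replaced.
  Hydrogen (grow) sites anchored on protected atoms remain legal, so a
  protected scaffold can still sprout substituents while its own atoms and
  bonds stay intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from rdkit import Chem

from .molkit import canonical_smiles, mol_from_input
from .properties import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fragment:
    """One attachable fragment: SMILES with a single dummy-atom attachment
    point ([*]) and its heavy-atom count (dummy excluded)."""

    smiles: str
    heavy_atoms: int
    max_sa: float = float("inf")


class FragmentTable:
    """Table of interchangeable fragments for the built-in mutator.

    Serialized as TSV: ``fragment_smiles<TAB>heavy_atoms``.  Every fragment
    must parse, carry exactly one terminal attachment point, and declare the
    heavy-atom count of its parsed structure.
    """

    def __init__(self, fragments: Sequence[Fragment]):
        self.fragments: List[Fragment] = []
        for frag in fragments:
            mol = Chem.MolFromSmiles(frag.smiles)
            if mol is None:
                raise ValueError(f"fragment {frag.smiles!r} does not parse")
            dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
            if len(dummies) != 1:
                raise ValueError(
                    f"fragment {frag.smiles!r} must carry exactly one attachment point"
                )
            if dummies[0].GetDegree() != 1:
                raise ValueError(f"attachment point of {frag.smiles!r} is not terminal")
            heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
            if heavy != frag.heavy_atoms:
                raise ValueError(
                    f"fragment {frag.smiles!r} declares {frag.heavy_atoms} heavy atoms "
                    f"but parses to {heavy}"
                )
            self.fragments.append(frag)
        if not self.fragments:
            raise ValueError("fragment table is empty")

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fragment_smiles\theavy_atoms\n")
            for frag in self.fragments:
                fh.write(f"{frag.smiles}\t{frag.heavy_atoms}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FragmentTable":
        fragments = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if i == 0 and parts[0] == "fragment_smiles":
                    continue
                if len(parts) < 2:
                    raise ValueError(f"{path}: malformed line {i + 1}: {line!r}")
                fragments.append(Fragment(parts[0], int(parts[1])))
        return cls(fragments)


@dataclass
class MutationParams:
    """Controls for one stage of structure generation (see module docstring)."""

    radius: int = 3
    min_size: int = 0
    max_size: int = 8
    min_inc: int = -5
    max_inc: int = 3
    protected_atom_indices: FrozenSet[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.min_size > self.max_size:
            raise ValueError(f"min_size {self.min_size} > max_size {self.max_size}")
        if self.min_inc > self.max_inc:
            raise ValueError(f"min_inc {self.min_inc} > max_inc {self.max_inc}")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")
        self.protected_atom_indices = frozenset(self.protected_atom_indices)


Site = Tuple[Tuple[int, ...], int]  # (heavy-atom indices of the site, site size)


def enumerate_replaceable_sites(mol: Chem.Mol, p: MutationParams) -> List[Site]:
    """All replaceable sites of a molecule under the given parameters.

    A size-0 site is one hydrogen position (an atom with k hydrogens yields k
    sites, so equivalent positions keep their multiplicity for sampling).  A
    size-s >= 1 site is a connected set of s heavy atoms attached to the rest
    of the molecule by exactly one bond (so its removal leaves the remainder
    connected), containing no protected atom.  Removing the entire molecule
    is not a site.
    """
    sites: List[Site] = []
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    n_heavy = len(heavy)

    if p.min_size == 0:
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() <= 1:
                continue
            for _ in range(atom.GetTotalNumHs()):
                sites.append(((atom.GetIdx(),), 0))

    lo, hi = max(1, p.min_size), p.max_size
    if hi >= 1 and n_heavy > 1:
        adjacency = {
            i: {n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors() if n.GetAtomicNum() > 1}
            for i in heavy
        }
        seen: Set[FrozenSet[int]] = set()
        # Grow connected subsets from each heavy atom, bounded by hi.
        def extend(subset: FrozenSet[int], frontier: Set[int]) -> None:
            if len(subset) >= lo:
                crossing = {
                    (i, j)
                    for i in subset
                    for j in adjacency[i]
                    if j not in subset
                }
                if len(crossing) == 1 and len(subset) < n_heavy:
                    if not (subset & p.protected_atom_indices):
                        key = subset
                        if key not in seen:
                            seen.add(key)
                            sites.append((tuple(sorted(subset)), len(subset)))
            if len(subset) >= hi:
                return
            for j in sorted(frontier):
                new_frontier = (frontier | adjacency[j]) - subset - {j}
                # only extend with atoms >= j among new candidates to avoid
                # revisiting permutations of the same subset
                extend(subset | {j}, {k for k in new_frontier})

        for start in heavy:
            extend(frozenset([start]), set(adjacency[start]))

    return sites


def _deduplicate_subsets(sites: List[Site]) -> List[Site]:
    seen = set()
    out = []
    for atoms, size in sites:
        key = (atoms, size)
        if key not in seen:
            seen.add(key)
            out.append((atoms, size))
    return out


def _attach_fragment(mol: Chem.Mol, anchor_idx: int, frag_mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Bond a fragment's attachment neighbor to the anchor atom (single bond)."""
    combined = Chem.RWMol(Chem.CombineMols(mol, frag_mol))
    offset = mol.GetNumAtoms()
    dummy = next(
        a.GetIdx() for a in combined.GetAtoms() if a.GetIdx() >= offset and a.GetAtomicNum() == 0
    )
    neighbor = combined.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
    combined.AddBond(anchor_idx, neighbor, Chem.BondType.SINGLE)
    combined.RemoveAtom(dummy)
    try:
        out = combined.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


def _cap_with_hydrogen(mol: Chem.Mol, anchor_idx: int) -> Optional[Chem.Mol]:
    try:
        out = Chem.Mol(mol)
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


def _replace_site(
    mol: Chem.Mol, site_atoms: Tuple[int, ...], frag: Fragment
) -> Optional[Chem.Mol]:
    """Remove the site atoms and attach the fragment at the freed valence."""
    frag_mol = Chem.MolFromSmiles(frag.smiles)
    # Find the single crossing bond and its anchor on the
    # remainder side, delete the site, then attach (or cap with H).
    site = set(site_atoms)
    anchor = None
    for idx in site_atoms:
        for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
            if nbr.GetAtomicNum() > 1 and nbr.GetIdx() not in site:
                if anchor is not None and anchor != nbr.GetIdx():
                    return None  # more than one crossing bond
                anchor = nbr.GetIdx()
    if anchor is None:
        return None
    rw = Chem.RWMol(mol)
    for idx in sorted(site, reverse=True):
        rw.RemoveAtom(idx)
    # account for index shifts caused by removals before the anchor
    shift = sum(1 for idx in site if idx < anchor)
    new_anchor = anchor - shift
    base = rw.GetMol()
    try:
        Chem.SanitizeMol(base)
    except Exception:
        return None
    if frag.heavy_atoms == 0:
        return _cap_with_hydrogen(base, new_anchor)
    return _attach_fragment(base, new_anchor, frag_mol)


def mutate(
    mol: Chem.Mol,
    p: MutationParams,
    table: FragmentTable,
    rng: np.random.Generator,
    max_children: int = 50,
) -> List[Chem.Mol]:
    """All feasible single-site fragment replacements, capped by sampling.

    Every child differs from the parent by replacing one enumerated site
    with one table fragment such that the heavy-atom increment lies in
    ``[min_inc, max_inc]``.  Children are sanitized, deduplicated by
    canonical SMILES, and capped at ``max_children`` by seeded sampling.
    Protected atoms are guaranteed present and unmodified in every child.
    """
    parent_smiles = canonical_smiles(mol)
    children: dict[str, Chem.Mol] = {}
    sites = enumerate_replaceable_sites(mol, p)
    # Collapse duplicate hydrogen sites per anchor for generation purposes.
    gen_sites: List[Site] = _deduplicate_subsets(sites)
    for site_atoms, size in gen_sites:
        for frag in table:
            inc = frag.heavy_atoms - size
            if not (p.min_inc <= inc <= p.max_inc):
                continue
            if size == 0:
                if frag.heavy_atoms == 0:
                    continue
                anchor = site_atoms[0]
                if mol.GetAtomWithIdx(anchor).GetTotalNumHs() < 1:
                    continue
                child = _attach_fragment(mol, anchor, Chem.MolFromSmiles(frag.smiles))
            else:
                child = _replace_site(mol, site_atoms, frag)
            if child is None:
                continue
            smi = canonical_smiles(child)
            if smi == parent_smiles or smi in children:
                continue
            if p.protected_atom_indices and not _protected_intact(mol, child, p):
                continue
            children[smi] = child
    ordered = [children[s] for s in sorted(children)]
    if len(ordered) > max_children:
        keep = sorted(rng.choice(len(ordered), size=max_children, replace=False))
        ordered = [ordered[i] for i in keep]
    return ordered


def _protected_intact(parent: Chem.Mol, child: Chem.Mol, p: MutationParams) -> bool:
    """Check the protected substructure of the parent maps into the child."""
    idxs = sorted(p.protected_atom_indices)
    if not idxs:
        return True
    sub = Chem.PathToSubmol(
        parent,
        [
            b.GetIdx()
            for b in parent.GetBonds()
            if b.GetBeginAtomIdx() in p.protected_atom_indices
            and b.GetEndAtomIdx() in p.protected_atom_indices
        ],
    )
    if sub.GetNumAtoms() == 0:
        # isolated protected atoms: check element presence via single-atom query
        for idx in idxs:
            sym = parent.GetAtomWithIdx(idx).GetSymbol()
            if not child.HasSubstructMatch(Chem.MolFromSmarts(f"[{sym}]")):
                return False
        return True
    return child.HasSubstructMatch(sub)


def grow(
    mol: Chem.Mol,
    p: MutationParams,
    table: FragmentTable,
    rng: np.random.Generator,
    max_children: int = 50,
) -> List[Chem.Mol]:
    """Growth-only mutation: hydrogen sites, positive heavy-atom increments."""
    grow_params = MutationParams(
        radius=p.radius,
        min_size=0,
        max_size=0,
        min_inc=max(1, p.min_inc),
        max_inc=max(1, p.max_inc),
        protected_atom_indices=p.protected_atom_indices,
    )
    return mutate(mol, grow_params, table, rng, max_children)


def external_generator_adapter(
    mol: Chem.Mol, raw_params: dict, db_path: Optional[str] = None
) -> List[str]:
    """Forward the parameter set verbatim to the CReM ``mutate_mol`` function.

    Requires the optional external fragment-replacement library and its
    database.  Output is normalized to a deduplicated canonical-SMILES list.
    """
    try:
        from crem.crem import mutate_mol  # type: ignore
    except ImportError:
        raise ConfigurationError(
            "the external fragment-replacement library (crem) is not installed; "
            "use the built-in fragment-table mutator instead"
        ) from None
    if not db_path:
        raise ConfigurationError("external generator requires a fragment database path")
    out = mutate_mol(mol, db_name=db_path, return_mol=False, **raw_params)
    seen: List[str] = []
    for smi in out:
        can = canonical_smiles(smi)
        if can not in seen:
            seen.append(can)
    return seen
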