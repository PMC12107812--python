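"""Fragment-table mutation: site enumeration, replacement, grow, invariants."""

import numpy as np
import pytest
from rdkit import Chem

from moldesirer.molkit import canonical_smiles
from moldesirer.mutation import (
    Fragment,
    FragmentTable,
    MutationParams,
    enumerate_replaceable_sites,
    external_generator_adapter,
    grow,
    mutate,
)
from moldesirer.properties import ConfigurationError


class TestFragmentTable:
    def test_validation_rejects_bad_fragments(self):
        with pytest.raises(ValueError, match="does not parse"):
            FragmentTable([Fragment("xx", 1)])
        with pytest.raises(ValueError, match="attachment point"):
            FragmentTable([Fragment("CC", 2)])  # no dummy atom
        with pytest.raises(ValueError, match="parses to"):
            FragmentTable([Fragment("[*]CC", 5)])  # wrong declared count

    def test_tsv_round_trip(self, tmp_path, toy_table):
        path = tmp_path / "frags.tsv"
        toy_table.to_tsv(path)
        back = FragmentTable.from_tsv(path)
        assert [(f.smiles, f.heavy_atoms) for f in back] == [
            (f.smiles, f.heavy_atoms) for f in toy_table
        ]

    def test_param_validation(self):
        with pytest.raises(ValueError):
            MutationParams(min_size=3, max_size=1)
        with pytest.raises(ValueError):
            MutationParams(min_inc=2, max_inc=-2)


class TestSiteEnumeration:
    def test_methane_hydrogen_sites(self):
        sites = enumerate_replaceable_sites(
            Chem.MolFromSmiles("C"), MutationParams(min_size=0, max_size=0, min_inc=1, max_inc=6)
        )
        assert len(sites) == 4
        assert all(size == 0 for _, size in sites)

    def test_ethane_single_carbon_sites(self):
        sites = enumerate_replaceable_sites(
            Chem.MolFromSmiles("CC"),
            MutationParams(min_size=1, max_size=1, min_inc=-1, max_inc=1),
        )
        heavy = [s for s in sites if s[1] == 1]
        assert sorted(atoms for atoms, _ in heavy) == [(0,), (1,)]

    def test_protection_empties_heavy_sites(self):
        sites = enumerate_replaceable_sites(
            Chem.MolFromSmiles("c1ccccc1"),
            MutationParams(
                min_size=1, max_size=3, min_inc=-2, max_inc=2,
                protected_atom_indices=frozenset(range(6)),
            ),
        )
        assert sites == []

    def test_terminal_fragments_only(self):
        # In toluene with sizes 1..1, only the methyl carbon is a terminal
        # single-atom fragment; ring atoms have two crossing bonds.
        mol = Chem.MolFromSmiles("Cc1ccccc1")
        sites = enumerate_replaceable_sites(
            mol, MutationParams(min_size=1, max_size=1, min_inc=-1, max_inc=1)
        )
        heavy = [atoms for atoms, size in sites if size == 1]
        assert heavy == [(0,)]


class TestMutate:
    def test_methane_grow_enumeration(self, grow_table, rng):
        # Four equivalent H sites x {methyl, ethyl} deduplicate to exactly
        # ethane and propane.
        children = mutate(
            Chem.MolFromSmiles("C"),
            MutationParams(min_size=0, max_size=0, min_inc=1, max_inc=6),
            grow_table,
            rng,
        )
        assert sorted(canonical_smiles(c) for c in children) == ["CC", "CCC"]

    def test_increment_bound_excludes_all(self, grow_table, rng):
        children = mutate(
            Chem.MolFromSmiles("C"),
            MutationParams(min_size=0, max_size=0, min_inc=3, max_inc=6),
            grow_table,
            rng,
        )
        assert children == []

    def test_fully_protected_scaffold_mutate_only(self, toy_table, rng):
        mol = Chem.MolFromSmiles("c1ccccc1")
        children = mutate(
            mol,
            MutationParams(
                min_size=1, max_size=3, min_inc=-2, max_inc=2,
                protected_atom_indices=frozenset(range(6)),
            ),
            toy_table,
            rng,
        )
        assert children == []

    def test_increment_window_respected(self, full_table):
        rng = np.random.default_rng(0)
        parents = ["CCO", "Cc1ccccc1", "CC(C)CC(=O)O", "c1ccncc1"]
        for smiles in parents:
            parent = Chem.MolFromSmiles(smiles)
            h_parent = parent.GetNumHeavyAtoms()
            params = MutationParams(min_size=0, max_size=2, min_inc=-2, max_inc=4)
            for child in mutate(parent, params, full_table, rng, max_children=100):
                inc = child.GetNumHeavyAtoms() - h_parent
                assert params.min_inc <= inc <= params.max_inc

    def test_children_sanitize_and_deduplicate(self, full_table):
        rng = np.random.default_rng(1)
        children = mutate(
            Chem.MolFromSmiles("CCO"),
            MutationParams(min_size=0, max_size=2, min_inc=-2, max_inc=4),
            full_table,
            rng,
            max_children=200,
        )
        smiles = [canonical_smiles(c) for c in children]
        assert len(smiles) == len(set(smiles))
        for c in children:
            Chem.SanitizeMol(c)  # raises on valence problems

    def test_protected_substructure_intact(self, full_table):
        rng = np.random.default_rng(2)
        parent = Chem.MolFromSmiles("OCc1ccccc1")
        protected = frozenset(range(parent.GetNumHeavyAtoms()))
        params = MutationParams(
            min_size=0, max_size=0, min_inc=1, max_inc=6, protected_atom_indices=protected
        )
        children = mutate(parent, params, full_table, rng, max_children=50)
        assert children  # growth on a fully protected scaffold is allowed
        core = Chem.MolFromSmiles("OCc1ccccc1")
        for child in children:
            assert child.HasSubstructMatch(core)

    def test_deterministic_under_fixed_seed(self, full_table):
        parent = Chem.MolFromSmiles("CC(=O)Nc1ccccc1")
        params = MutationParams(min_size=0, max_size=2, min_inc=-2, max_inc=4)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            runs.append(
                [canonical_smiles(c) for c in mutate(parent, params, full_table, rng, 30)]
            )
        assert runs[0] == runs[1]

    def test_max_children_cap(self, full_table):
        rng = np.random.default_rng(3)
        children = mutate(
            Chem.MolFromSmiles("CCCCO"),
            MutationParams(min_size=0, max_size=2, min_inc=-2, max_inc=4),
            full_table,
            rng,
            max_children=5,
        )
        assert len(children) == 5

    def test_deletion_via_hydrogen_cap(self, full_table):
        rng = np.random.default_rng(4)
        children = mutate(
            Chem.MolFromSmiles("CCO"),
            MutationParams(min_size=1, max_size=1, min_inc=-1, max_inc=-1),
            full_table,
            rng,
        )
        smiles = {canonical_smiles(c) for c in children}
        assert "CC" in smiles or "CO" in smiles  # terminal atom deleted


class TestGrow:
    def test_methane_methyl_gives_ethane(self, grow_table, rng):
        children = grow(
            Chem.MolFromSmiles("C"),
            MutationParams(min_size=0, max_size=0, min_inc=1, max_inc=6),
            grow_table,
            rng,
        )
        assert "CC" in {canonical_smiles(c) for c in children}

    def test_no_hydrogen_no_growth(self, grow_table, rng):
        # Neopentane's central carbon has no hydrogens; protecting the methyl
        # carbons leaves H sites only on protected atoms - still allowed -
        # but a molecule with every valence saturated and all atoms
        # H-free cannot grow at all.
        mol = Chem.MolFromSmiles("FC(F)(F)F")
        children = grow(
            mol,
            MutationParams(min_size=0, max_size=0, min_inc=1, max_inc=6),
            grow_table,
            rng,
        )
        assert children == []

    def test_grow_subset_of_mutate(self, full_table):
        parent = Chem.MolFromSmiles("CCO")
        params = MutationParams(min_size=0, max_size=0, min_inc=1, max_inc=6)
        g = {
            canonical_smiles(c)
            for c in grow(parent, params, full_table, np.random.default_rng(0), 500)
        }
        m = {
            canonical_smiles(c)
            for c in mutate(parent, params, full_table, np.random.default_rng(0), 500)
        }
        assert g <= m


class TestExternalAdapter:
    def test_absent_library_raises_configuration_error(self):
        with pytest.raises(ConfigurationError, match="crem"):
            external_generator_adapter(
                Chem.MolFromSmiles("C"),
                {"radius": 3, "min_size": 0, "max_size": 0, "min_inc": 1, "max_inc": 6},
                db_path="missing.db",
            )
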