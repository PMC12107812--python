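"""Campaign analytics: similarity samples, summaries, projection, free energy."""

import numpy as np
import pytest

from moldesirer.analysis import (
    FreeEnergyRecord,
    evolution_summary,
    inter_similarity,
    intra_similarity,
    pca_scores,
    project_chemical_space,
    rbfe_to_abfe,
    similarity_histogram,
)
from moldesirer.molkit import morgan_fingerprint, tanimoto

RANDOM_SMILES = [
    "CCO", "c1ccccc1", "CC(=O)O", "c1ccncc1", "CCN", "CC(C)O",
    "c1ccc2ccccc2c1", "CC(=O)Nc1ccccc1", "OCC(O)CO", "ClCCCl",
]


class TestSimilaritySamples:
    def test_identical_molecules_all_ones(self):
        values = intra_similarity(["CCO"] * 5)
        assert values == pytest.approx(np.ones(10))

    def test_pair_count(self):
        assert len(intra_similarity(RANDOM_SMILES[:3])) == 3
        assert len(intra_similarity(RANDOM_SMILES)) == 45

    def test_matches_brute_force_double_loop(self):
        fps = [morgan_fingerprint(s) for s in RANDOM_SMILES]
        expected = []
        for i in range(len(fps)):
            for j in range(i + 1, len(fps)):
                expected.append(tanimoto(fps[i], fps[j]))
        assert intra_similarity(RANDOM_SMILES) == pytest.approx(np.array(expected))

    def test_too_few_molecules(self):
        with pytest.raises(ValueError):
            intra_similarity(["C"])

    def test_inter_singleton_identity(self):
        assert inter_similarity(["CCO"], ["CCO"]) == pytest.approx([1.0])

    def test_inter_cross_pair_count(self):
        assert len(inter_similarity(RANDOM_SMILES[:2], RANDOM_SMILES[2:5])) == 6

    def test_inter_symmetric_as_multiset(self):
        a, b = RANDOM_SMILES[:3], RANDOM_SMILES[3:7]
        ab = sorted(inter_similarity(a, b))
        ba = sorted(inter_similarity(b, a))
        assert ab == pytest.approx(ba)

    def test_inter_empty_rejected(self):
        with pytest.raises(ValueError):
            inter_similarity([], RANDOM_SMILES)

    def test_histogram_bins_and_density(self):
        values = intra_similarity(RANDOM_SMILES)
        hist = similarity_histogram(values)
        assert len(hist) == 300
        assert hist["count"].sum() == len(values)
        assert np.isfinite(hist["density"]).all()


class TestEvolutionSummary:
    def _history(self, toy_table):
        from moldesirer.ga import GA

        ga = GA("C", fragment_table=toy_table, popsize=8, seed=13)
        ga.run(5)
        return ga.history_frame()

    def test_one_row_per_generation(self, toy_table):
        history = self._history(toy_table)
        summary = evolution_summary(history)
        assert list(summary["generation"]) == sorted(history["generation"].unique())

    def test_min_cost_non_increasing(self, toy_table):
        summary = evolution_summary(self._history(toy_table))
        mins = summary["cost_min"].to_numpy()
        assert (np.diff(mins) <= 1e-12).all()

    def test_recompute_matches(self, toy_table):
        history = self._history(toy_table)
        summary = evolution_summary(history)
        with_accepted = summary[summary["n_accepted"] > 0]
        gen = int(with_accepted["generation"].iloc[-1])
        pool = history[(history["generation"] == gen) & history["accepted"]]
        row = summary[summary["generation"] == gen].iloc[0]
        assert row["cost_min"] == pytest.approx(pool["cost"].min())
        assert row["cost_median"] == pytest.approx(pool["cost"].median())
        assert row["acceptance_rate"] == pytest.approx(
            pool.shape[0] / history[history["generation"] == gen].shape[0]
        )

    def test_empty_history_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            evolution_summary(pd.DataFrame())


class TestProjection:
    def test_pca_matches_eigendecomposition(self):
        rng = np.random.default_rng(21)
        X = rng.integers(0, 2, size=(20, 64)).astype(float)
        scores, frac = pca_scores(X, n_components=5)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:5]
        expected = Xc @ evecs[:, order]
        for k in range(5):  # eigenvector sign is arbitrary
            col, exp = scores[:, k], expected[:, k]
            assert min(np.abs(col - exp).max(), np.abs(col + exp).max()) < 1e-8
        assert frac == pytest.approx(evals[order].sum() / evals.sum())

    def test_duplicated_rows_identical_scores(self):
        rng = np.random.default_rng(22)
        X = rng.integers(0, 2, size=(10, 32)).astype(float)
        X2 = np.vstack([X, X[0]])
        scores, _ = pca_scores(X2, n_components=3)
        assert scores[-1] == pytest.approx(scores[0])

    def test_projection_shape_seeded(self):
        rng = np.random.default_rng(23)
        X = rng.integers(0, 2, size=(30, 64)).astype(float)
        coords, frac = project_chemical_space(X, n_components=5, seed=0)
        assert coords.shape == (30, 2)
        assert 0.0 < frac <= 1.0
        coords2, _ = project_chemical_space(X, n_components=5, seed=0)
        assert coords2 == pytest.approx(coords)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            project_chemical_space(np.zeros((5, 16)), n_components=5)


class TestFreeEnergy:
    def test_identity_returns_representative_exactly(self):
        rec = FreeEnergyRecord(ddg_i=-1.3, dg_r=-6.22, ddg_r=-1.3)
        dg, _ = rbfe_to_abfe(rec)
        assert dg == -6.22

    def test_hand_arithmetic_with_reference_absolute_value(self):
        # representative absolute value -6.22 kcal/mol; molecule i is 1 kcal/mol
        # better than the representative in relative terms
        dg, _ = rbfe_to_abfe(FreeEnergyRecord(ddg_i=-2.0, dg_r=-6.22, ddg_r=-1.0))
        assert dg == pytest.approx(-7.22)

    def test_quadrature_error_3_4_5(self):
        _, err = rbfe_to_abfe(
            FreeEnergyRecord(0.0, 0.0, 0.0, err_ddg_i=0.3, err_dg_r=0.4, err_ddg_r=0.0)
        )
        assert err == pytest.approx(0.5)

    def test_negative_error_rejected(self):
        with pytest.raises(ValueError):
            FreeEnergyRecord(0.0, 0.0, 0.0, err_ddg_i=-0.1)

    def test_linearity_against_independent_recomputation(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            ddg_i, dg_r, ddg_r = rng.normal(0, 5, size=3)
            errs = np.abs(rng.normal(0, 1, size=3))
            dg, err = rbfe_to_abfe(
                FreeEnergyRecord(ddg_i, dg_r, ddg_r, *errs)
            )
            assert dg == pytest.approx(ddg_i + dg_r - ddg_r)
            assert err == pytest.approx(float(np.sqrt((errs**2).sum())))

    def test_error_invariant_to_input_sign_flips(self):
        base = FreeEnergyRecord(-2.0, -6.0, -1.0, 0.2, 0.3, 0.4)
        flipped = FreeEnergyRecord(2.0, 6.0, 1.0, 0.2, 0.3, 0.4)
        assert rbfe_to_abfe(base)[1] == rbfe_to_abfe(flipped)[1]
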