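"""Evolutionary engine: selection, elitism, statefulness, checkpointing."""

import math

import numpy as np
import pytest
from scipy import stats

from moldesirer.ga import (
    GA,
    SelectionError,
    merge_and_truncate,
    select_parents,
    selection_probabilities,
)
from moldesirer.molkit import Individual, make_individual
from moldesirer.properties import ConfigurationError


class TestSelectionProbabilities:
    def test_beta_zero_uniform(self):
        p = selection_probabilities([0.1, 0.9, 0.4], beta=0.0)
        assert p == pytest.approx([1 / 3] * 3)

    def test_equal_costs_uniform(self):
        p = selection_probabilities([0.7, 0.7, 0.7, 0.7], beta=5.0)
        assert p == pytest.approx([0.25] * 4)

    def test_hand_computed_boltzmann(self):
        p = selection_probabilities([0.0, math.log(2)], beta=1.0)
        assert p == pytest.approx([2 / 3, 1 / 3])

    def test_shift_invariance_machine_precision(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            costs = rng.uniform(0, 1, size=10)
            base = selection_probabilities(costs, beta=2.5)
            for c in (-100.0, -1.0, 3.7, 250.0):
                shifted = selection_probabilities(costs + c, beta=2.5)
                assert shifted == pytest.approx(base, abs=1e-12)

    def test_infinite_costs_excluded(self):
        p = selection_probabilities([0.2, float("inf"), 0.4], beta=1.0)
        assert p[1] == 0.0
        assert p.sum() == pytest.approx(1.0)

    def test_all_infinite_raises(self):
        with pytest.raises(SelectionError):
            selection_probabilities([float("inf")] * 3, beta=1.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            selection_probabilities([0.1], beta=-1.0)


def _population(costs):
    pop = []
    for i, c in enumerate(costs):
        ind = make_individual("C" * (i + 1), idx=i)
        ind.cost = c
        pop.append(ind)
    return pop


class TestSelectParents:
    def test_empirical_matches_boltzmann(self):
        rng = np.random.default_rng(7)
        costs = [0.1, 0.35, 0.6, 0.9]
        pop = _population(costs)
        draws = select_parents(pop, 100_000, beta=2.0, rng=rng)
        observed = np.bincount([d.idx for d in draws], minlength=4)
        expected = selection_probabilities(costs, 2.0) * len(draws)
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_high_beta_is_greedy(self):
        rng = np.random.default_rng(8)
        pop = _population([0.0, 1.0])
        draws = select_parents(pop, 10_000, beta=1e3, rng=rng)
        frac_best = sum(1 for d in draws if d.idx == 0) / len(draws)
        assert frac_best >= 0.999

    def test_zero_draws(self, rng):
        assert select_parents(_population([0.1]), 0, 1.0, rng) == []


class TestMergeAndTruncate:
    def test_empty_offspring_keeps_population(self):
        pop = _population([0.2, 0.4])
        assert merge_and_truncate(pop, [], 2) == pop

    def test_better_offspring_replaces_everything(self):
        pop = _population([0.8, 0.9])
        off = _population([0.1, 0.2])
        assert merge_and_truncate(pop, off, 2) == off

    def test_brute_force_sort(self):
        pop = _population([0.2, 0.4, 0.9])
        off = []
        for i, c in enumerate([0.3, 0.95]):
            ind = make_individual("N" * 1 + "C" * (i + 1), idx=10 + i)
            ind.cost = c
            off.append(ind)
        kept = merge_and_truncate(pop, off, 3)
        assert [k.cost for k in kept] == pytest.approx([0.2, 0.3, 0.4])

    def test_ties_prefer_incumbents(self):
        pop = _population([0.5])
        challenger = make_individual("CC", idx=99)
        challenger.cost = 0.5
        kept = merge_and_truncate(pop, [challenger], 1)
        assert kept[0].idx == 0


class TestEngine:
    def test_configuration_validation(self, toy_table):
        with pytest.raises(ConfigurationError):
            GA("C", fragment_table=None)
        with pytest.raises(ConfigurationError):
            GA("C", fragment_table=toy_table, pc=0.0)
        with pytest.raises(ConfigurationError):
            GA("C", fragment_table=toy_table, beta=-1)

    def test_popsize_one_single_seed(self, toy_table):
        ga = GA("C", fragment_table=toy_table, popsize=1, seed=0)
        ga.initialize_population()
        assert [i.smiles for i in ga.population] == ["C"]
        assert ga.population[0].evaluated

    def test_initial_population_unique_and_full(self, toy_table):
        ga = GA("C", fragment_table=toy_table, popsize=5, seed=0)
        ga.initialize_population()
        smiles = [i.smiles for i in ga.population]
        assert len(smiles) == 5
        assert len(set(smiles)) == 5
        assert "C" in smiles

    def test_duplicate_seeds_deduplicated(self, toy_table):
        ga = GA(["C", "C", "CC"], fragment_table=toy_table, popsize=4, seed=0)
        assert len(ga.seed_individuals) == 2

    def test_zero_generations_no_op(self, toy_table):
        ga = GA("C", fragment_table=toy_table, popsize=5, seed=0)
        ga.initialize_population()
        before = [(i.smiles, i.cost) for i in ga.population]
        ga.run(0)
        assert [(i.smiles, i.cost) for i in ga.population] == before

    def test_children_count_formula(self, toy_table):
        ga = GA("C", fragment_table=toy_table, popsize=30, pc=0.5, seed=0)
        ga.initialize_population()
        rng = ga._rng_for_generation(1)
        offspring, n_generated = ga.produce_offspring(rng)
        assert n_generated >= len(offspring)
        assert len(offspring) <= 15  # pc * popsize parents, one child each

    def test_elitist_dominance_every_generation(self, toy_table):
        ga = GA("C", fragment_table=toy_table, popsize=10, pc=0.5, beta=1.0, seed=3)
        ga.initialize_population()
        prev = sorted(i.cost for i in ga.population)
        for _ in range(8):
            ga.step()
            cur = sorted(i.cost for i in ga.population)
            assert all(c <= p + 1e-12 for c, p in zip(cur, prev))
            prev = cur

    def test_population_always_unique(self, toy_table):
        ga = GA("C", fragment_table=toy_table, popsize=10, seed=4)
        ga.run(6)
        for rec in ga.history:
            pass  # history intact
        smiles = [i.smiles for i in ga.population]
        assert len(smiles) == len(set(smiles))

    def test_multi_call_statefulness(self, toy_table):
        ga = GA("C", fragment_table=toy_table, popsize=8, maxiter=3, seed=5)
        ga.run()
        assert ga.generation == 3
        best_before = ga.best.cost
        ga.beta = 3.0  # attribute change between calls, then resume
        ga.run(2)
        assert ga.generation == 5
        assert ga.best.cost <= best_before

    def test_run_determinism(self, toy_table):
        def final(seed):
            ga = GA("C", fragment_table=toy_table, popsize=8, seed=seed)
            ga.run(5)
            return sorted((i.smiles, i.cost) for i in ga.population)

        assert final(11) == final(11)
        assert final(11) != final(12)  # different seeds explore differently

    def test_acceptance_rate_recorded(self, toy_table):
        ga = GA("C", fragment_table=toy_table, popsize=8, seed=6)
        ga.run(4)
        for rec in ga.history[1:]:
            assert 0.0 <= rec.acceptance_rate <= 1.0 or math.isnan(rec.acceptance_rate)

    def test_history_frame_columns(self, toy_table):
        ga = GA("C", fragment_table=toy_table, popsize=6, seed=7)
        ga.run(2)
        frame = ga.history_frame()
        assert list(frame.columns) == [
            "generation", "idx", "smiles", "cost", "score", "qed", "sa_score", "accepted",
        ]
        assert frame["generation"].max() == 2


class TestCheckpointing:
    def test_save_load_round_trip(self, toy_table, tmp_path):
        ga = GA("C", fragment_table=toy_table, popsize=6, seed=8)
        ga.run(3)
        path = tmp_path / "state.pbz2"
        ga.checkpoint(path)
        loaded = GA.resume(path)
        assert sorted((i.smiles, i.cost) for i in loaded.population) == sorted(
            (i.smiles, i.cost) for i in ga.population
        )
        assert loaded.generation == ga.generation

    def test_split_run_equals_straight_run(self, toy_table, tmp_path):
        straight = GA("C", fragment_table=toy_table, popsize=8, seed=9)
        straight.run(10)

        first = GA("C", fragment_table=toy_table, popsize=8, seed=9)
        first.run(5)
        path = tmp_path / "mid.pbz2"
        first.checkpoint(path)
        resumed = GA.resume(path)
        resumed.run(5)

        assert sorted((i.smiles, i.cost) for i in resumed.population) == sorted(
            (i.smiles, i.cost) for i in straight.population
        )

    def test_truncated_file_raises(self, toy_table, tmp_path):
        ga = GA("C", fragment_table=toy_table, popsize=4, seed=10)
        ga.initialize_population()
        path = tmp_path / "full.pbz2"
        ga.checkpoint(path)
        data = path.read_bytes()
        bad = tmp_path / "broken.pbz2"
        bad.write_bytes(data[: len(data) // 2])
        with pytest.raises(IOError):
            GA.resume(bad)

    def test_output_files(self, toy_table, tmp_path):
        ga = GA("C", fragment_table=toy_table, popsize=5, seed=11, deffnm="toy")
        ga.run(2)
        paths = ga.write_outputs(tmp_path)
        assert (tmp_path / "toy.pbz2").exists()
        assert (tmp_path / "toy_history.tsv").exists()
        import pandas as pd

        hist = pd.read_csv(paths["history"], sep="\t")
        assert {"generation", "smiles", "cost"} <= set(hist.columns)
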