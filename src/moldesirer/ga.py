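"""The crossover-free genetic algorithm.

Evolution loop per generation: Boltzmann roulette selection of parents,
single-site fragment mutation, evaluation of the new candidates, elitist
merge-and-truncate back to the fixed population size.  Selection draws
parent ``i`` with probability

    P_i = exp(-beta * cost_i) / sum_j exp(-beta * cost_j)

so ``beta = 0`` is uniform (pure exploration) and large ``beta`` is greedy.
There is no crossover operator: the fragment table acts as an external
recombination source.

The engine object is stateful and serializable: it can be called repeatedly
(each call continues from the stored population), its attributes may be
changed between calls to switch search strategy, and it checkpoints to a
bz2-compressed pickle (``.pbz2``) from which a resumed run is bit-identical
to an uninterrupted one under the same master seed.
"""

from __future__ import annotations

import bz2
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .fitness import FitnessSpec, resolve_fitness
from .molkit import Individual, canonical_smiles, make_individual, write_sdf
from .mutation import FragmentTable, MutationParams, mutate
from .properties import ConfigurationError

logger = logging.getLogger(__name__)


class SelectionError(RuntimeError):
    """No finite-cost individuals available for selection."""


def selection_probabilities(costs: Sequence[float], beta: float) -> np.ndarray:
    """Boltzmann selection distribution over a cost vector.

    Infinite-cost entries get probability 0.  The minimum finite cost is
    subtracted before exponentiation; the distribution is mathematically
    invariant under this shift, which only guards against overflow.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    costs_arr = np.asarray(costs, dtype=float)
    finite = np.isfinite(costs_arr)
    if not finite.any():
        raise SelectionError("all costs are infinite; nothing to select")
    shifted = np.where(finite, costs_arr - costs_arr[finite].min(), np.inf)
    weights = np.where(finite, np.exp(-beta * shifted), 0.0)
    return weights / weights.sum()


def select_parents(
    population: Sequence[Individual], n: int, beta: float, rng: np.random.Generator
) -> List[Individual]:
    """Draw n parents with replacement from the Boltzmann roulette."""
    if n == 0:
        return []
    probs = selection_probabilities([ind.cost for ind in population], beta)
    picks = rng.choice(len(population), size=n, replace=True, p=probs)
    return [population[i] for i in picks]


def merge_and_truncate(
    population: Sequence[Individual], offspring: Sequence[Individual], popsize: int
) -> List[Individual]:
    """Elitist survivor selection: keep the popsize lowest-cost individuals.

    Ties break toward the incumbent population (stability), then toward the
    lower idx.  The union is assumed duplicate-free by SMILES (the engine
    enforces this upstream).
    """
    tagged = [(ind.cost, 0, ind.idx, ind) for ind in population] + [
        (ind.cost, 1, ind.idx, ind) for ind in offspring
    ]
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))
    return [t[3] for t in tagged[:popsize]]


@dataclass
class GenerationRecord:
    """History entry for one generation (initialization = generation 0)."""

    generation: int
    candidates: List[Dict]  # idx, smiles, cost, score, qed, sa_score, accepted
    n_generated: int
    n_accepted: int

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_generated if self.n_generated else float("nan")


class GA:
    """Stateful evolutionary optimizer of molecules.

    Parameters
    ----------
    seed_mol : str, Mol, Individual, or a list of them
        Starting structure(s); SMILES strings and MOL blocks accepted.
    fitness : callable or built-in name
        Fitness function; must follow the Individual-in/Individual-out
        contract and be serializable.
    fitness_spec : FitnessSpec
        Configuration passed as the second argument to the fitness function.
    fragment_table : FragmentTable
        Fragment source for the mutation operator.
    mutation_params : MutationParams
        Stage controls (replaced-site size window, increment window,
        protected atoms).
    popsize, pc, beta, maxiter
        Population size, proportion of children per generation, selection
        pressure, and generations per call.
    seed : int
        Master RNG seed; per-generation streams are derived from it so
        results are independent of the parallelism width.
    njobs : int
        Worker processes for evaluation (1 = serial).
    deffnm : str
        Output prefix for checkpoint / SDF / history files.
    """

    def __init__(
        self,
        seed_mol,
        fitness: Callable | str = "cost",
        fitness_spec: Optional[FitnessSpec] = None,
        fragment_table: Optional[FragmentTable] = None,
        mutation_params: Optional[MutationParams] = None,
        popsize: int = 20,
        pc: float = 0.5,
        beta: float = 1.0,
        maxiter: int = 10,
        seed: int = 0,
        njobs: int = 1,
        deffnm: str = "moldesirer",
        max_children_per_parent: int = 50,
        max_retry: int = 5,
    ) -> None:
        if fragment_table is None:
            raise ConfigurationError("a fragment table is required for mutation")
        if not (0 < pc <= 1):
            raise ConfigurationError(f"pc must be in (0, 1], got {pc}")
        if beta < 0:
            raise ConfigurationError(f"beta must be >= 0, got {beta}")
        if popsize < 1:
            raise ConfigurationError("popsize must be >= 1")

        seeds = seed_mol if isinstance(seed_mol, (list, tuple)) else [seed_mol]
        self.seed_individuals: List[Individual] = []
        seen = set()
        for i, s in enumerate(seeds):
            ind = s if isinstance(s, Individual) else make_individual(s, idx=i)
            if ind.smiles not in seen:
                seen.add(ind.smiles)
                self.seed_individuals.append(ind)
        if not self.seed_individuals:
            raise ConfigurationError("no valid seed molecules provided")

        self.fitness = resolve_fitness(fitness)
        self.fitness_spec = fitness_spec or FitnessSpec()
        self.fragment_table = fragment_table
        self.mutation_params = mutation_params or MutationParams()
        self.popsize = popsize
        self.pc = pc
        self.beta = beta
        self.maxiter = maxiter
        self.master_seed = seed
        self.njobs = njobs
        self.deffnm = deffnm
        self.max_children_per_parent = max_children_per_parent
        self.max_retry = max_retry

        self.population: List[Individual] = []
        self.generation = 0
        self.next_idx = len(self.seed_individuals)
        self.seen_smiles: set = {ind.smiles for ind in self.seed_individuals}
        self.history: List[GenerationRecord] = []
        self._initialized = False

    # -- RNG ---------------------------------------------------------------
    def _rng_for_generation(self, generation: int) -> np.random.Generator:
        # One independent stream per generation, derived from the master
        # seed, so njobs and call boundaries cannot perturb the trajectory.
        return np.random.default_rng(np.random.SeedSequence([self.master_seed, generation]))

    # -- evaluation --------------------------------------------------------
    def _evaluate(self, individuals: List[Individual]) -> List[Individual]:
        todo = [ind for ind in individuals if not ind.evaluated]
        if not todo:
            return individuals
        if self.njobs > 1:
            import multiprocessing as mp

            with mp.Pool(self.njobs) as pool:
                results = pool.starmap(
                    self.fitness, [(ind, self.fitness_spec) for ind in todo]
                )
            for ind, res in zip(todo, results):
                ind.cost, ind.pdbqt = res.cost, res.pdbqt
                ind.score, ind.qed, ind.sa_score = res.score, res.qed, res.sa_score
        else:
            for ind in todo:
                self.fitness(ind, self.fitness_spec)
        return individuals

    # -- initialization ----------------------------------------------------
    def initialize_population(self) -> None:
        """Population = seeds plus mutated seed variants up to popsize unique
        SMILES; may start smaller (with a warning) if the mutator is
        exhausted.  Everything is evaluated."""
        rng = self._rng_for_generation(0)
        population = list(self.seed_individuals[: self.popsize])
        frontier = list(population)
        attempts = 0
        while len(population) < self.popsize and attempts < self.max_retry:
            new_frontier: List[Individual] = []
            for parent in frontier:
                if len(population) >= self.popsize:
                    break
                children = mutate(
                    parent.mol,
                    self.mutation_params,
                    self.fragment_table,
                    rng,
                    self.max_children_per_parent,
                )
                for child in children:
                    smi = canonical_smiles(child)
                    if smi in self.seen_smiles:
                        continue
                    self.seen_smiles.add(smi)
                    ind = Individual(child, idx=self.next_idx)
                    self.next_idx += 1
                    population.append(ind)
                    new_frontier.append(ind)
                    if len(population) >= self.popsize:
                        break
            if not new_frontier:
                break
            frontier = new_frontier
            attempts += 1
        if len(population) < self.popsize:
            logger.warning(
                "initial population has %d < popsize %d unique structures",
                len(population),
                self.popsize,
            )
        self._evaluate(population)
        self.population = merge_and_truncate(population, [], self.popsize)
        self.generation = 0
        self.history.append(
            GenerationRecord(
                generation=0,
                candidates=[self._candidate_row(i, True) for i in self.population],
                n_generated=len(population),
                n_accepted=len(self.population),
            )
        )
        self._initialized = True

    def _candidate_row(self, ind: Individual, accepted: bool) -> Dict:
        return {
            "idx": ind.idx,
            "smiles": ind.smiles,
            "cost": ind.cost,
            "score": ind.score,
            "qed": ind.qed,
            "sa_score": ind.sa_score,
            "accepted": bool(accepted),
        }

    # -- one generation ----------------------------------------------------
    def produce_offspring(self, rng: np.random.Generator) -> tuple[List[Individual], int]:
        """Children for one generation.

        max(1, round(pc * popsize)) parents are drawn by roulette; each
        yields one mutated child not seen before in the whole run (bounded
        retries).  Returns (accepted-for-evaluation children, number of
        structures generated including rejected duplicates).
        """
        n_children = max(1, round(self.pc * self.popsize))
        offspring: List[Individual] = []
        n_generated = 0
        parents = select_parents(self.population, n_children, self.beta, rng)
        current = {ind.smiles for ind in self.population}
        for parent in parents:
            child_ind = None
            for _ in range(self.max_retry):
                children = mutate(
                    parent.mol,
                    self.mutation_params,
                    self.fragment_table,
                    rng,
                    self.max_children_per_parent,
                )
                if not children:
                    break
                pick = children[rng.integers(len(children))]
                smi = canonical_smiles(pick)
                n_generated += 1
                fresh = smi not in self.seen_smiles and smi not in current
                self.seen_smiles.add(smi)
                if fresh:
                    child_ind = Individual(pick, idx=self.next_idx)
                    self.next_idx += 1
                    break
            if child_ind is not None:
                offspring.append(child_ind)
                current.add(child_ind.smiles)
        return offspring, n_generated

    def step(self) -> GenerationRecord:
        """Run one generation: select, mutate, evaluate, merge."""
        if not self._initialized:
            self.initialize_population()
        gen = self.generation + 1
        rng = self._rng_for_generation(gen)
        offspring, n_generated = self.produce_offspring(rng)
        if not offspring:
            logger.warning("generation %d produced no offspring", gen)
        self._evaluate(offspring)
        new_population = merge_and_truncate(self.population, offspring, self.popsize)
        survivors = {id(ind) for ind in new_population}
        record = GenerationRecord(
            generation=gen,
            candidates=[self._candidate_row(i, id(i) in survivors) for i in offspring],
            n_generated=n_generated,
            n_accepted=sum(1 for i in offspring if id(i) in survivors),
        )
        self.population = new_population
        self.generation = gen
        self.history.append(record)
        logger.info(
            "generation %d: best=%.4f mean=%.4f acceptance=%.2f",
            gen,
            self.best.cost,
            float(np.mean([i.cost for i in self.population if i.evaluated])),
            record.acceptance_rate,
        )
        return record

    def run(self, generations: Optional[int] = None) -> "GA":
        """Run ``generations`` (default: maxiter) generations and return self."""
        if not self._initialized:
            self.initialize_population()
        n = self.maxiter if generations is None else generations
        for _ in range(n):
            self.step()
        return self

    __call__ = run

    # -- accessors ---------------------------------------------------------
    @property
    def best(self) -> Individual:
        return min(self.population, key=lambda i: i.cost)

    def history_frame(self) -> pd.DataFrame:
        """All candidate records across generations as a tidy DataFrame."""
        rows = []
        for rec in self.history:
            for cand in rec.candidates:
                rows.append({"generation": rec.generation, **cand})
        return pd.DataFrame(
            rows,
            columns=["generation", "idx", "smiles", "cost", "score", "qed", "sa_score", "accepted"],
        )

    # -- persistence -------------------------------------------------------
    def checkpoint(self, path: str | Path) -> None:
        """Serialize the full engine state to a bz2-compressed pickle."""
        with bz2.open(str(path), "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def resume(path: str | Path) -> "GA":
        """Load a checkpointed engine; continued runs match uninterrupted ones."""
        try:
            with bz2.open(str(path), "rb") as fh:
                obj = pickle.load(fh)
        except Exception as exc:
            raise IOError(f"could not load checkpoint {path}: {exc}") from exc
        if not isinstance(obj, GA):
            raise IOError(f"checkpoint {path} does not contain an engine state")
        return obj

    def write_outputs(self, directory: str | Path = ".") -> Dict[str, str]:
        """Write <deffnm>.pbz2, <deffnm>_pop.sdf and <deffnm>_history.tsv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "checkpoint": str(directory / f"{self.deffnm}.pbz2"),
            "population": str(directory / f"{self.deffnm}_pop.sdf"),
            "history": str(directory / f"{self.deffnm}_history.tsv"),
        }
        self.checkpoint(paths["checkpoint"])
        write_sdf(self.population, paths["population"])
        self.history_frame().to_csv(paths["history"], sep="\t", index=False)
        return paths
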