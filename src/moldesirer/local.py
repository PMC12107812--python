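"""Single-shot local exploration around a seed molecule.

Not an iterative optimizer: one grow step (hydrogen sites, positive
heavy-atom increments) around the seed, a seeded random pick of at most
``pick`` children, evaluation of seed plus picked children, results sorted
by cost.  Useful in lead optimization, where the scaffold and pose context
are fixed and only decorations are explored.
"""

from __future__ import annotations

import bz2
import pickle
from pathlib import Path
from typing import Callable, List, Optional

import numpy as np
import pandas as pd

from .fitness import FitnessSpec, resolve_fitness
from .ga import GA
from .molkit import Individual, make_individual
from .mutation import FragmentTable, MutationParams, grow


class Local:
    """Grow-pick-evaluate around a fixed seed.

    Parameters mirror the evolutionary engine where they overlap; ``pick``
    bounds how many grown children are evaluated (a uniform random subset
    without replacement when the grow set is larger).
    """

    def __init__(
        self,
        seed_mol,
        fitness: Callable | str = "cost",
        fitness_spec: Optional[FitnessSpec] = None,
        fragment_table: Optional[FragmentTable] = None,
        grow_params: Optional[MutationParams] = None,
        seed: int = 0,
        njobs: int = 1,
        deffnm: str = "local",
    ) -> None:
        self.seed_individual = (
            seed_mol if isinstance(seed_mol, Individual) else make_individual(seed_mol, idx=0)
        )
        self.fitness = resolve_fitness(fitness)
        self.fitness_spec = fitness_spec or FitnessSpec()
        self.fragment_table = fragment_table
        self.grow_params = grow_params or MutationParams(min_size=0, max_size=0, min_inc=1, max_inc=6)
        self.master_seed = seed
        self.njobs = njobs
        self.deffnm = deffnm
        self.results: List[Individual] = []

    def run(self, pick: int = 50, max_children: int = 200) -> List[Individual]:
        """Grow, pick, evaluate; returns individuals sorted by ascending cost.

        The seed is always evaluated and always present in the output.
        ``pick = 0`` returns just the evaluated seed.
        """
        if pick < 0:
            raise ValueError(f"pick must be >= 0, got {pick}")
        rng = np.random.default_rng(np.random.SeedSequence([self.master_seed, 0]))
        children = []
        if self.fragment_table is not None and pick > 0:
            mols = grow(
                self.seed_individual.mol, self.grow_params, self.fragment_table, rng, max_children
            )
            if pick < len(mols):
                keep = sorted(rng.choice(len(mols), size=pick, replace=False))
                mols = [mols[i] for i in keep]
            children = [Individual(m, idx=i + 1) for i, m in enumerate(mols)]
        pool = [self.seed_individual] + children
        if self.njobs > 1:
            import multiprocessing as mp

            with mp.Pool(self.njobs) as mpool:
                results = mpool.starmap(self.fitness, [(i, self.fitness_spec) for i in pool])
            for ind, res in zip(pool, results):
                ind.cost, ind.pdbqt = res.cost, res.pdbqt
                ind.score, ind.qed, ind.sa_score = res.score, res.qed, res.sa_score
        else:
            for ind in pool:
                self.fitness(ind, self.fitness_spec)
        self.results = sorted(pool, key=lambda i: (i.cost, i.idx))
        return self.results

    __call__ = run

    def to_dataframe(self) -> pd.DataFrame:
        return to_table(self.results)

    def checkpoint(self, path: str | Path) -> None:
        with bz2.open(str(path), "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def resume(path: str | Path) -> "Local":
        with bz2.open(str(path), "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, Local):
            raise IOError(f"checkpoint {path} does not contain a local-search state")
        return obj


def local_run(
    seed,
    grow_params: MutationParams,
    table: FragmentTable,
    pick: int,
    fitness_spec: Optional[FitnessSpec] = None,
    fitness: Callable | str = "cost",
    seed_int: int = 0,
    njobs: int = 1,
) -> List[Individual]:
    """Functional wrapper over :class:`Local`."""
    engine = Local(
        seed,
        fitness=fitness,
        fitness_spec=fitness_spec,
        fragment_table=table,
        grow_params=grow_params,
        seed=seed_int,
        njobs=njobs,
    )
    return engine.run(pick=pick)


def to_table(results: List[Individual]) -> pd.DataFrame:
    """One row per individual: idx, smiles, cost, score, qed, sa_score."""
    rows = [
        {
            "idx": i.idx,
            "smiles": i.smiles,
            "cost": i.cost,
            "score": i.score,
            "qed": i.qed,
            "sa_score": i.sa_score,
        }
        for i in results
    ]
    return pd.DataFrame(rows, columns=["idx", "smiles", "cost", "score", "qed", "sa_score"])
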