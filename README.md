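# moldesirer

Multi-property evolutionary design of small molecules.

`moldesirer` is for medicinal and computational chemists who want to evolve a
seed fragment into candidate ligands that are simultaneously potent,
drug-like and synthesizable — without committing to a single scalar
objective up front. It implements a crossover-free genetic algorithm over
molecular graphs: candidate structures are mutated by replacing terminal
fragments drawn from a fragment table, evaluated under a composite
desirability fitness, and selected by Boltzmann roulette with elitist
survivor truncation.

## The method

Each property *x* (a docking-style binding score in kcal/mol, the QED
drug-likeness estimate, the synthetic-accessibility score) is mapped onto a
desirability *d* ∈ [0, 1] by a Derringer–Suich transform:

* larger-the-best: d = 0 for x < l, ((x−l)/(t−l))^r on [l, t], 1 above t
* smaller-the-best: d = 1 for x < t, ((u−x)/(u−t))^r on [t, u], 0 above u
* nominal-the-best: rises to 1 at the target t inside [l, u], 0 outside

The transforms are aggregated by a weighted geometric mean

D = (∏ dᵢ^{wᵢ})^{1/Σwᵢ}

and an individual's cost is 1 − D (0 is perfect; any fully unacceptable
property annihilates the aggregate). The default table is: score
smaller-the-best with target −10 and upper limit −2 kcal/mol; QED
larger-the-best with lower limit 0.1 and target 0.75; synthetic
accessibility smaller-the-best with target 3 and upper limit 7; all ramps
linear, all weights 1.

Parents are drawn with replacement from the Boltzmann distribution

Pᵢ = e^{−β·costᵢ} / Σⱼ e^{−β·costⱼ}

where β is the selection pressure (β = 0 uniform, large β greedy). Each
parent yields one mutated child; parent and child pools are merged and
truncated to the fixed population size, so the sorted cost vector is
pointwise non-increasing across generations. There is no crossover
operator — the fragment table acts as an external recombination source.

A surrogate scorer (a smooth quadratic in heavy-atom count with its minimum
at 35 atoms) serves the binding-score axis so the whole engine runs in
seconds on a laptop; an adapter can shell out to AutoDock-Vina when an
executable and a prepared receptor are configured. For lead optimization,
the constrained-conformer module pins a reference core's 3D coordinates
during embedding and discards conformers that clash with the protein, and
the `Local` engine explores single-step growths around a fixed seed.

## Worked example

Evolve the benzyl-alcohol fragment for 15 generations under the surrogate
scorer and the default desirability table:

```python
from moldesirer import GA, MutationParams
from moldesirer.fixtures import build_toy_fragment_table

ga = GA(
    "OCc1ccccc1",
    fragment_table=build_toy_fragment_table(),
    mutation_params=MutationParams(min_size=0, max_size=2, min_inc=-2, max_inc=6),
    popsize=20, pc=0.5, beta=1.0, maxiter=15, seed=1,
)
ga.run()
best = ga.best
print(f"best molecule : {best.smiles}")
print(f"cost          : {best.cost:.3f}")
print(f"score         : {best.score:.2f}")
print(f"qed           : {best.qed:.2f}")
print(f"sa_score      : {best.sa_score:.2f}")
```

prints

```
best molecule : CCc1cc(C#N)c(-c2ccncc2-c2ccncc2)c(CO)c1C#N
cost          : 0.225
score         : -5.72
qed           : 0.78
sa_score      : 2.88
```

The engine grew the 8-heavy-atom seed into a 25-heavy-atom candidate: the
surrogate score improved from the fully-undesirable region (weaker than the
−2 kcal/mol limit, cost 1) to −5.72, QED sits above the 0.75 target and the
synthetic-accessibility score is below its target of 3, giving a composite
cost of 0.225. Under a real docking backend the score axis is served by the
docking engine instead; nothing else changes.

The same run is available from the shell via a YAML plan
(`moldesirer config.yml`), including multi-stage plans that switch mutation
windows and selection pressure between calls, `--continue` resumption from
the `.pbz2` checkpoint, and `local` / `constraintconf` / `analyze`
subcommands.

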