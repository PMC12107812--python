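# Methods

## Model

`moldesirer` treats molecular design as the minimization of a scalar cost
over chemical space. The cost of a molecule is 1 − D, where D is the
weighted geometric mean of per-property desirabilities (Derringer–Suich
transforms). Three properties enter the built-in composite fitness:

| property  | meaning                                   | transform         | knots (default)        | units    |
|-----------|-------------------------------------------|-------------------|------------------------|----------|
| score     | docking-style binding-affinity estimate   | smaller-the-best  | t = −10, u = −2        | kcal/mol |
| qed       | quantitative estimate of drug-likeness    | larger-the-best   | l = 0.1, t = 0.75      | —        |
| sa_score  | synthetic-accessibility score (1 easy…10) | smaller-the-best  | t = 3, u = 7           | —        |

All ramps are linear (r = 1) and all weights 1 by default. The geometric
mean makes the objective conjunctive: a molecule that fails any one
property outright (d = 0 with positive weight) has cost 1 regardless of the
others. The knot defaults are deliberately asymmetric — ambitious targets,
permissive limits — so early populations retain diversity while the
gradient still points toward simultaneously good molecules.

Piecewise evaluation at the knots uses the closed-interval branch as
written (d(l) = 0 and d(t) = 1 for larger-the-best, etc.); a factor with
zero weight is ignored entirely rather than treated as 0^0.

## Search

The engine is a generational GA without crossover:

1. **Initialization.** The population is the seed structure(s) plus mutated
   variants until `popsize` unique canonical SMILES are collected. If the
   mutator is exhausted first, the population starts smaller with a
   warning; it is never padded with duplicates.
2. **Selection.** Parents are drawn with replacement from the Boltzmann
   distribution Pᵢ ∝ e^{−β·costᵢ}. β ≥ 0 is the selection pressure; the
   minimum cost is subtracted before exponentiation, which is
   mathematically a no-op (shift invariance) and numerically prevents
   overflow. Individuals with infinite cost get probability 0.
3. **Mutation.** Each of max(1, round(pc·popsize)) parents yields one child
   drawn from its single-site replacement set (below). Children whose
   SMILES were ever generated before in the run are rejected with bounded
   retries; every generated SMILES enters a global `seen` set whether
   accepted or not, which makes "molecules generated" and the per-
   generation acceptance rate (accepted / generated) well defined.
4. **Evaluation.** Only new individuals are evaluated. A failed evaluation
   (parse, descriptor, backend, or constraint failure) poisons only that
   individual: its cost stays +∞ and it loses every truncation contest.
5. **Survivor selection.** Parent and child pools merge; the `popsize`
   lowest-cost individuals survive. Ties break toward the incumbent
   population, then toward the lower creation index, making the trajectory
   stable under permutations. Elitism follows: the sorted cost vector is
   pointwise non-increasing generation over generation.

The engine object is stateful and serializable. Repeated calls continue
from the stored population; attributes (β, pc, mutation windows, output
prefix) may be changed between calls to implement staged strategies.
Checkpoints are bz2-compressed pickles; a resumed run is identical to an
uninterrupted one because every generation derives its own RNG stream from
(master seed, generation index) — parallelism width and call boundaries
cannot perturb the trajectory.

## Structure generation

The built-in mutator replaces one *terminal fragment* of the parent: a
connected set of `min_size`…`max_size` heavy atoms attached to the rest of
the molecule by exactly one bond, with size 0 meaning one hydrogen
position. The replacement is drawn from a fragment table (TSV of fragment
SMILES with a single dummy-atom attachment point, plus heavy-atom count);
a zero-heavy-atom "hydrogen cap" fragment implements pure deletion. The
child's heavy-atom increment must lie in [`min_inc`, `max_inc`]. New bonds
are single bonds at the freed valence; children failing sanitization are
dropped, never emitted; the output is deduplicated by canonical SMILES and
capped by seeded sampling (default 50 per parent).

Protected atoms are never removed or replaced, but hydrogen (grow) sites on
protected atoms remain legal: a protected scaffold keeps its atoms and
internal bonds intact (verified per child by substructure match) while
still sprouting substituents. This is what a constrained campaign needs —
the reference core untouched for the entire run, growth still possible.

The `radius` parameter (context-sphere size of external fragment-
replacement libraries) is accepted for interface compatibility and ignored
by the built-in mutator: context-conditioned replacement statistics require
the external fragment database, to which an optional adapter forwards the
full parameter set verbatim when that library is installed.

The staged schedule shipped in `fixtures` mirrors a
lead-generation-to-lead-optimization progression: grow-only
(sizes 0/0, increments 1..6), allow-grow (0/2, −2..4), pure-mutate
(1/8, −5..3), then point mutation (0/1, −1..1).

## Scoring backends

The score axis is served by a registry of backends returning
(score, pose payload). The built-in `surrogate` backend is the quadratic
−0.35·H + 0.005·H² of the heavy-atom count H: smooth, deterministic,
minimum −6.125 at H = 35, crossing 0 at H = 70. Its coefficients were
chosen so magnitudes resemble docking scores in the [−10, −2] kcal/mol
band and so the optimum size sits inside drug-like space; it gives the GA a
growth gradient and makes every engine test deterministic. It is a test
device, not a physical model — in particular it is conformation-
independent, so it cannot reward pose quality. The `vina` adapter shells
out to an AutoDock-Vina executable (score-only) when one is configured,
with the docking box (center, edge lengths in Å, exhaustiveness, default 9)
carried in the receptor spec. Pose payloads are opaque text end to end; the
package never parses docking file dialects.

Multi-receptor fitness maps each receptor's score through a direction-
dependent transform: on-target ("minimize") uses the smaller-the-best score
transform; anti-target ("maximize") uses a larger-the-best ramp mirroring
the on-target knots unless the user supplies an explicit `anti_score`
transform. All receptor desirabilities join QED and synthetic accessibility
in the same geometric mean with their own weights (default 1, not
renormalized — adding a receptor therefore changes the aggregate exponent,
which is the straightforward reading of the weighted-mean formula).

## Constrained conformers

`map_core` matches the reference's heavy-atom graph into the candidate
(substructure match; deterministic tie-break by smallest mapped-index sum;
maximum-common-substructure fallback requiring at least 3 mapped atoms,
since fewer cannot fix a rigid frame). `constrained_embed` embeds each
conformer with the mapped atoms pinned to the reference coordinates
(hydrogens added for embedding, stripped after); a conformer whose core
RMSD exceeds τ = 0.1 Å, or whose constrained embedding fails, is replaced
by an unconstrained conformer rigidly aligned on the mapped atoms and
flagged as a fallback. The clash filter removes any conformer with a
ligand heavy atom within the cutoff (default 1.5 Å) of any protein heavy
atom; waters are skipped by residue name, hydrogens are ignored throughout.
The scored conformer is the survivor with the lowest core RMSD, then the
lowest embedding-force-field energy, then the lowest index. `score_only`
scores that conformer as-is; `local_only` (engine-side relaxation) requires
an external docking engine and degrades to `score_only` under the
surrogate, with a warning.

## Analytics

Similarity analyses use Morgan fingerprints of radius 2 and 2048 bits with
Tanimoto similarity; intra-set samples are all n(n−1)/2 unordered pairs,
inter-set samples all |A|·|B| cross pairs. Histograms use 300 bins on
[0, 1] with a Gaussian KDE (rule-of-thumb bandwidth) as the smoothed
density. Chemical-space projection is PCA to 50 components (cumulative
explained-variance fraction reported) followed by seeded t-SNE to 2D,
default perplexity 30 (reduced automatically for small samples); the
embedding is qualitative by nature and only the variance fraction is
treated as quantitative. Two all-zero fingerprints are defined as
maximally similar (both featureless at the chosen radius).

Relative binding free energies are converted to absolute ones through a
representative molecule r: ΔG_i = ΔΔG_i + ΔG_r − ΔΔG_r, with the three
input uncertainties added in quadrature. The choice of representative is
the caller's; the conversion is exact for the representative itself.

## Desk-scale study conditions

The test suite and the acceptance script run everything on synthetic
inputs: a fragment table of ~25 common substituents (heavy atoms 1–6), toy
receptor geometries (a 12 Å spherical shell with an empty pocket; a plane
of atoms at x = 0 for exact clash-boundary checks), and campaigns of
popsize 20, pc 0.5, β 1, 15 generations under the surrogate scorer — sizes
chosen so a full campaign takes seconds while still exercising every code
path over hundreds of generated molecules. What passing these tests shows:
the algebra (desirability, selection, merge, free-energy conversion) is
exact; the engine's invariants (elitism, uniqueness, determinism,
checkpoint equivalence) hold; constrained embedding preserves cores to
0.1 Å and the clash filter is exact at its boundary. What they do not
show: anything about real binding affinity, docking-pose quality, or the
chemistry of a production fragment database — the surrogate score is a
monotone-in-size stand-in, and the toy fragment table is far smaller and
more benign than an interchangeable-fragment database derived from a
compound corpus. Campaign-level magnitudes measured under a real docking
engine (thousands of molecules, ~10 % acceptance) are therefore outside
what desk-scale runs can or should reproduce.

## Known limitations

* The built-in mutator only replaces terminal fragments (one attachment
  bond), so ring-internal substitutions and linker rewiring require the
  external-library adapter.
* Fragments carrying ring-closure attachment points are rejected;
  attachment chemistry is always a single bond.
* The surrogate score is conformation-independent; constrained-conformer
  scoring under the surrogate validates the pipeline, not pose energetics.
* QED and synthetic accessibility delegate to the published descriptor
  implementations; small version-to-version drift of those toolkits moves
  third-decimal values.
* Stereochemistry participates in SMILES identity (it is preserved by
  canonicalization); the mutator itself neither creates nor enumerates
  stereocenters.
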