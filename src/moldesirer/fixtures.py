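"""Deterministic generators for desk-scale runs and tests.

Everything a toy campaign needs without any download: a fragment table of
common medicinal-chemistry substituents, toy protein geometries for clash
tests, and the four-stage run plan shape used for staged optimization
(grow -> allow-grow -> pure-mutate -> point-mutation).  All generators are
pure functions of their seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Tuple

import numpy as np

from .mutation import Fragment, FragmentTable, MutationParams

# Common substituents, heavy-atom counts 1..6; the attachment point is the
# dummy atom.  Stands in for a downloadable interchangeable-fragment
# database at desk scale.
_FRAGMENT_POOL: List[Tuple[str, int]] = [
    ("[*]C", 1),          # methyl
    ("[*]O", 1),          # hydroxyl
    ("[*]N", 1),          # amino
    ("[*]F", 1),          # fluoro
    ("[*]Cl", 1),         # chloro
    ("[*]CC", 2),         # ethyl
    ("[*]OC", 2),         # methoxy
    ("[*]C=O", 2),        # formyl
    ("[*]C#N", 2),        # nitrile
    ("[*]CCC", 3),        # propyl
    ("[*]C(C)C", 3),      # isopropyl
    ("[*]C(=O)O", 3),     # carboxyl
    ("[*]C(=O)N", 3),     # amide
    ("[*]S(C)=O", 3),     # methylsulfinyl
    ("[*]CCCC", 4),       # butyl
    ("[*]C(C)(C)C", 4),   # tert-butyl
    ("[*]C1CC1", 3),      # cyclopropyl
    ("[*]C1CCC1", 4),     # cyclobutyl
    ("[*]C1CCCC1", 5),    # cyclopentyl
    ("[*]c1ccoc1", 5),    # furanyl
    ("[*]c1ccsc1", 5),    # thiophenyl
    ("[*]c1ccncc1", 6),   # pyridyl
    ("[*]c1ccccc1", 6),   # phenyl
    ("[*]C1CCCCC1", 6),   # cyclohexyl
    ("[*][H]", 0),        # hydrogen cap (pure deletion of a replaced site)
]


def build_toy_fragment_table(
    seed: int = 0, n_fragments: int = 12, max_heavy: int = 6
) -> FragmentTable:
    """Deterministic fragment table of simple substituents.

    Samples ``n_fragments`` fragments (without replacement, seeded) from the
    built-in pool, restricted to ``heavy_atoms <= max_heavy``; always
    includes methyl so growth is never impossible.  Heavy-atom counts of 1
    through ``max_heavy`` support a grow stage with increments 1..6.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    pool = [f for f in _FRAGMENT_POOL if 1 <= f[1] <= max_heavy]
    rng = np.random.default_rng(seed)
    n = min(n_fragments, len(pool))
    idx = sorted(rng.choice(len(pool), size=n, replace=False))
    chosen = [pool[i] for i in idx]
    if not any(s == "[*]C" for s, _ in chosen):
        chosen[0] = ("[*]C", 1)
    return FragmentTable([Fragment(s, h) for s, h in sorted(set(chosen), key=lambda f: (f[1], f[0]))])


def full_fragment_table() -> FragmentTable:
    """The complete built-in substituent pool, hydrogen cap included."""
    return FragmentTable([Fragment(s, h) for s, h in _FRAGMENT_POOL])


def build_toy_receptor(kind: str = "cavity", seed: int = 0) -> str:
    """Toy protein heavy-atom geometry as PDB text.

    "cavity": a spherical shell of carbon pseudo-atoms of radius 12 A
    centered at the origin, leaving an empty pocket more than 8 A wide — a
    ligand centered in the pocket never clashes.  "wall": a 21x21 plane of
    atoms at x = 0 with 1 A spacing — any conformer atom within the cutoff
    of the plane is removed.
    """
    coords: List[Tuple[float, float, float]] = []
    if kind == "cavity":
        n = 400
        # deterministic quasi-uniform points on the sphere (Fibonacci lattice)
        golden = (1 + 5**0.5) / 2
        for i in range(n):
            theta = 2 * np.pi * i / golden
            z = 1 - (2 * i + 1) / n
            r = np.sqrt(max(0.0, 1 - z * z))
            coords.append((12.0 * r * np.cos(theta), 12.0 * r * np.sin(theta), 12.0 * z))
    elif kind == "wall":
        for y in range(-10, 11):
            for z in range(-10, 11):
                coords.append((0.0, float(y), float(z)))
    else:
        raise ValueError(f"unknown toy receptor kind {kind!r}")
    lines = []
    for i, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {i:5d}  C   ALA A{(i - 1) % 9999 + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_toy_receptor(path: str | Path, kind: str = "cavity", seed: int = 0) -> Path:
    path = Path(path)
    path.write_text(build_toy_receptor(kind, seed))
    return path


#: The four-stage schedule shape used by staged campaigns:
#: (name, radius, min_size, max_size, min_inc, max_inc)
STAGE_SCHEDULE = [
    ("01_grow", 3, 0, 0, 1, 6),
    ("02_allow_grow", 3, 0, 2, -2, 4),
    ("03_pure_mutate", 3, 1, 8, -5, 3),
    ("04_local", 3, 0, 1, -1, 1),
]


def staged_mutation_params(protected=frozenset()) -> List[Tuple[str, MutationParams]]:
    """MutationParams for the four staged-campaign steps, in order."""
    return [
        (
            name,
            MutationParams(
                radius=radius,
                min_size=mn,
                max_size=mx,
                min_inc=lo,
                max_inc=hi,
                protected_atom_indices=protected,
            ),
        )
        for name, radius, mn, mx, lo, hi in STAGE_SCHEDULE
    ]


def staged_campaign_config(
    popsize: int = 20,
    generations_per_stage: Tuple[int, int, int, int] = (4, 5, 8, 3),
    seed: int = 0,
    seed_mol: str = "C",
    deffnm: str = "staged",
) -> dict:
    """Four-run plan dictionary mirroring the staged schedule.

    The relative stage lengths default to the 20/25/40/15 proportions of a
    100-generation campaign scaled to 20 generations; parameter tuples per
    stage are exactly the schedule's.  The result parses with
    :func:`moldesirer.config.parse_config`.
    """
    if popsize < 1 or any(g < 1 for g in generations_per_stage):
        raise ValueError("popsize and all stage lengths must be positive")
    plan = {}
    for i, ((name, radius, mn, mx, lo, hi), gens) in enumerate(
        zip(STAGE_SCHEDULE, generations_per_stage)
    ):
        run: dict = {
            "type": "GA",
            "maxiter": gens,
            "mutate_crem_kwargs": {
                "radius": radius,
                "min_size": mn,
                "max_size": mx,
                "min_inc": lo,
                "max_inc": hi,
            },
        }
        if i == 0:
            run.update(
                {
                    "seed_mol": seed_mol,
                    "costfunc": "cost",
                    "costfunc_kwargs": {},
                    "fragment_table": "builtin",
                    "popsize": popsize,
                    "pc": 0.5,
                    "beta": 1.0,
                    "seed": seed,
                    "deffnm": deffnm,
                    "njobs": 1,
                }
            )
        plan[name] = run
    return plan
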