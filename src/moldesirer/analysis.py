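"""Post-hoc campaign analytics.

Similarity structure (pairwise Tanimoto within and between campaigns),
population-evolution summaries from engine histories, a PCA + t-SNE
projection of fingerprint space, and the arithmetic converting relative
binding free energies to absolute ones via a representative molecule:

    dG_i     = ddG_i + dG_r - ddG_r
    err(dG_i) = sqrt(err(ddG_i)^2 + err(dG_r)^2 + err(ddG_r)^2)

where ddG denotes a relative and dG an absolute binding free energy
(kcal/mol), and subscript r the representative for which an absolute
calculation was run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .molkit import Fingerprint, morgan_fingerprint, tanimoto


def intra_similarity(mols: Sequence) -> np.ndarray:
    """All n(n-1)/2 unordered-pair Tanimoto similarities within one set.

    Accepts molecules, SMILES, or precomputed fingerprints (Morgan radius 2,
    2048 bits by default).
    """
    fps = _as_fingerprints(mols)
    n = len(fps)
    if n < 2:
        raise ValueError(f"need at least 2 molecules, got {n}")
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[k] = tanimoto(fps[i], fps[j])
            k += 1
    return out


def inter_similarity(a: Sequence, b: Sequence) -> np.ndarray:
    """All |A| x |B| cross-pair Tanimoto similarities between two sets."""
    fa, fb = _as_fingerprints(a), _as_fingerprints(b)
    if not fa or not fb:
        raise ValueError("both molecule sets must be non-empty")
    out = np.empty(len(fa) * len(fb))
    k = 0
    for x in fa:
        for y in fb:
            out[k] = tanimoto(x, y)
            k += 1
    return out


def _as_fingerprints(mols: Sequence) -> List[Fingerprint]:
    fps = []
    for m in mols:
        fps.append(m if isinstance(m, Fingerprint) else morgan_fingerprint(m))
    return fps


def similarity_histogram(values: np.ndarray, bins: int = 300) -> pd.DataFrame:
    """Histogram (default 300 bins over [0, 1]) with a Gaussian-KDE smooth.

    The KDE uses the rule-of-thumb (Scott) bandwidth.  Returns a frame with
    bin centers, counts, and the smoothed density evaluated at the centers.
    """
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = np.full_like(centers, np.nan)
    if len(np.unique(values)) > 1:
        density = gaussian_kde(values)(centers)
    return pd.DataFrame({"similarity": centers, "count": counts, "density": density})


def evolution_summary(history: pd.DataFrame) -> pd.DataFrame:
    """Per-generation population statistics from an engine history frame.

    Expects the tidy candidate table (columns generation, cost, score, qed,
    sa_score, accepted); summarizes accepted members only — min/median/max of
    each property plus the generation's acceptance rate.
    """
    if history is None or len(history) == 0:
        raise ValueError("empty history")
    rows = []
    for gen, group in history.groupby("generation"):
        accepted = group[group["accepted"]]
        pool = accepted if len(accepted) else group
        row = {"generation": int(gen), "n_candidates": len(group), "n_accepted": len(accepted)}
        row["acceptance_rate"] = len(accepted) / len(group) if len(group) else float("nan")
        for prop in ("cost", "score", "qed", "sa_score"):
            vals = pool[prop].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"{prop}_min"] = vals.min() if vals.size else float("nan")
            row[f"{prop}_median"] = float(np.median(vals)) if vals.size else float("nan")
            row[f"{prop}_max"] = vals.max() if vals.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).sort_values("generation").reset_index(drop=True)


def project_chemical_space(
    fingerprints: Sequence,
    n_components: int = 50,
    seed: int = 0,
    perplexity: float = 30.0,
) -> Tuple[np.ndarray, float]:
    """PCA to ``n_components`` then a 2D t-SNE embedding of the PC scores.

    Returns (coords[n, 2], cumulative explained-variance fraction of the
    retained components).  The embedding is seeded; it is a qualitative
    visualization device, so only the variance fraction is quantitative.
    """
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    X = np.asarray(
        [fp.to_numpy() if isinstance(fp, Fingerprint) else np.asarray(fp) for fp in fingerprints],
        dtype=float,
    )
    if X.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} fingerprints for {n_components} components, "
            f"got {X.shape[0]}"
        )
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(X)
    variance_fraction = float(pca.explained_variance_ratio_.sum())
    perplexity = min(perplexity, (X.shape[0] - 1) / 3)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    coords = tsne.fit_transform(scores)
    return coords, variance_fraction


def pca_scores(fingerprints: Sequence, n_components: int) -> Tuple[np.ndarray, float]:
    """PCA scores alone (no t-SNE), for quantitative checks."""
    from sklearn.decomposition import PCA

    X = np.asarray(
        [fp.to_numpy() if isinstance(fp, Fingerprint) else np.asarray(fp) for fp in fingerprints],
        dtype=float,
    )
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, float(pca.explained_variance_ratio_.sum())


@dataclass(frozen=True)
class FreeEnergyRecord:
    """Free-energy bookkeeping for one molecule against a representative.

    ddg_i / ddg_r: relative binding free energies of molecule i and of the
    representative (kcal/mol); dg_r: absolute binding free energy of the
    representative; err_*: associated non-negative uncertainties.
    """

    ddg_i: float
    dg_r: float
    ddg_r: float
    err_ddg_i: float = 0.0
    err_dg_r: float = 0.0
    err_ddg_r: float = 0.0

    def __post_init__(self) -> None:
        for name in ("err_ddg_i", "err_dg_r", "err_ddg_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def rbfe_to_abfe(rec: FreeEnergyRecord) -> Tuple[float, float]:
    """Absolute binding free energy of molecule i and its propagated error.

    dG_i = ddG_i + dG_r - ddG_r; the error adds the three input errors in
    quadrature.  Exact identity: when i is the representative itself
    (ddG_i = ddG_r), dG_i = dG_r.
    """
    dg = rec.ddg_i + rec.dg_r - rec.ddg_r
    err = math.sqrt(rec.err_ddg_i**2 + rec.err_dg_r**2 + rec.err_ddg_r**2)
    return dg, err
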