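"""Bray-Curtis dissimilarity and non-metric multidimensional scaling.

NMDS seeks a low-dimensional configuration whose inter-point distances
are monotonically related to the observed community dissimilarities;
goodness of fit is Kruskal stress-1. The optimizer is SMACOF with
isotonic regression (scikit-learn's nonmetric MDS), run from multiple
random starts with the best configuration kept, centered and rotated to
its principal axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .community import CountMatrix


@dataclass(frozen=True)
class DissimilarityMatrix:
    sample_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.sample_ids),) * 2:
            raise ValueError("dissimilarity matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("dissimilarity diagonal must be zero")
        if m.min() < 0 or m.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis dissimilarities must lie in [0, 1]")
        object.__setattr__(self, "matrix", m)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.sample_ids)
        return pd.DataFrame(self.matrix, index=ids, columns=ids)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame    # samples x k
    stress: float
    n_starts: int
    converged: bool
    seed: int


def bray_curtis(cm: CountMatrix) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity, sum|x-y| / sum(x+y), on samples."""
    totals = cm.sample_totals()
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"zero-total sample(s): {empty}")
    d = squareform(pdist(cm.counts.T.astype(float), metric="braycurtis"))
    return DissimilarityMatrix(tuple(cm.sample_ids), d)


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Nonmetric MDS of a dissimilarity matrix; returns stress-1 in [0, 1].

    The best of ``n_starts`` random initializations is retained; the
    configuration is centered and rotated onto its principal axes so the
    output is unique up to axis signs.
    """
    n = len(d.sample_ids)
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than n_samples = {n}")
    import inspect

    kwargs = dict(
        n_components=k,
        dissimilarity="precomputed",
        n_init=n_starts,
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
    )
    if "metric_mds" in inspect.signature(MDS.__init__).parameters:
        kwargs["metric_mds"] = False
    else:  # pragma: no cover - older scikit-learn
        kwargs["metric"] = False
    model = MDS(**kwargs)
    coords = model.fit_transform(d.matrix)
    coords = coords - coords.mean(axis=0)
    # principal-axis rotation, with deterministic sign convention
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    signs = np.sign(coords[np.abs(coords).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    coords = coords * signs
    frame = pd.DataFrame(
        coords,
        index=list(d.sample_ids),
        columns=[f"axis{i+1}" for i in range(k)],
    )
    return OrdinationResult(
        coordinates=frame,
        stress=float(model.stress_),
        n_starts=n_starts,
        converged=bool(model.n_iter_ < max_iter),
        seed=seed,
    )
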