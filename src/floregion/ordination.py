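"""Non-metric multidimensional scaling with multi-start stress minimization.

NMDS embeds a dissimilarity matrix in a low-dimensional space so that the
rank order of configuration distances matches the rank order of the input
dissimilarities as closely as possible. Fit is measured by Kruskal stress-1,

    stress = sqrt( sum (dhat_ij - d_ij)^2 / sum d_ij^2 ),

where d are the configuration distances and dhat the disparities from a
monotone (isotonic) regression of d on the input ranks (primary treatment of
ties). Because the SMACOF descent can stall in local minima, many starts are
run (100 by default, matching common practice) and the lowest-stress
solution is kept; the first start is the metric (principal-coordinates)
configuration — the usual warm start in ordination software, and one whose
axes nest across dimensionalities — the rest are random. Coordinates are centered and rotated to
their principal axes, with a deterministic sign convention, so repeated runs
with one seed are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .core import DistanceMatrix, FloregionError


@dataclass
class NMDSResult:
    coordinates: np.ndarray  # (n_sites, n_dimensions), centered, PCA-rotated
    stress: float  # Kruskal stress-1 of the retained solution
    site_ids: tuple
    n_dimensions: int
    n_starts: int
    best_start_index: int
    seed: int
    converged: bool
    stress_per_start: np.ndarray


def stress1(dissimilarities: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against condensed dissimilarities."""
    d = pdist(coords)
    # primary treatment of ties: within tied dissimilarities the configuration
    # distances are free, so sort tied blocks by d before the isotonic fit
    order = np.lexsort((d, dissimilarities))
    iso = IsotonicRegression()
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(np.arange(d.size), d[order])
    denom = float(np.dot(d, d))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def nmds(
    dist: DistanceMatrix,
    n_dimensions: int = 2,
    n_starts: int = 100,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> NMDSResult:
    """Multi-start non-metric MDS of ``dist``; keeps the lowest-stress start."""
    n = dist.n
    if n < n_dimensions + 2:
        raise FloregionError(
            f"NMDS in {n_dimensions} dimensions needs at least {n_dimensions + 2} sites"
        )
    y = dist.condensed()
    if not np.isfinite(y).all():
        raise FloregionError("distance matrix contains non-finite values")
    if np.allclose(y, y[0]):
        warnings.warn(
            "all dissimilarities equal; NMDS configuration is arbitrary",
            stacklevel=2,
        )
    sq = squareform(y)
    rng = np.random.default_rng(seed)
    best = None
    stresses = np.empty(n_starts)
    for s in range(n_starts):
        if s == 0:
            init = _pcoa_init(sq, n_dimensions, rng)
        else:
            init = rng.standard_normal((n, n_dimensions))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn chatters about n_init
            coords, _, n_iter = smacof(
                sq,
                metric=False,
                n_components=n_dimensions,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=tol,
                normalized_stress=True,
                return_n_iter=True,
            )
        st = stress1(y, coords)
        stresses[s] = st
        if best is None or st < best[0]:
            best = (st, coords, s, n_iter < max_iter)
    st, coords, best_idx, converged = best
    coords = _orient(coords)
    return NMDSResult(
        coordinates=coords,
        stress=float(st),
        site_ids=dist.site_ids,
        n_dimensions=n_dimensions,
        n_starts=n_starts,
        best_start_index=int(best_idx),
        seed=seed,
        converged=bool(converged),
        stress_per_start=stresses,
    )


def _pcoa_init(sq: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Principal-coordinates (classical MDS) configuration as a warm start.

    Axes with non-positive eigenvalues (possible for non-Euclidean
    dissimilarities) are filled with small random jitter.
    """
    n = sq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (sq**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    coords = np.zeros((n, k))
    for col, idx in enumerate(order):
        if w[idx] > 0:
            coords[:, col] = v[:, idx] * np.sqrt(w[idx])
        else:
            coords[:, col] = 1e-6 * rng.standard_normal(n)
    return coords


def _orient(coords: np.ndarray) -> np.ndarray:
    """Center, rotate to principal axes and fix axis signs (stress-invariant)."""
    x = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(x.shape[1]):
        k = int(np.argmax(np.abs(x[:, j])))
        if x[k, j] < 0:
            x[:, j] = -x[:, j]
    return x
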