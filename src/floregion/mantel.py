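"""Mantel correlation between dissimilarity matrices.

The statistic is the Pearson correlation of the strictly-lower-triangle
entries of two matrices over the same sites. Significance comes from a
permutation null: a random relabelling of sites is applied to the second
matrix (simultaneous row/column permutation) and the correlation recomputed;
the one-sided p-value for positive association is
``(1 + #{null r >= observed r}) / (1 + n_permutations)``.

Pairs where either matrix is NaN (e.g. SES pairs with a degenerate null) are
excluded from every correlation, observed and permuted alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DistanceMatrix, FloregionError

VALID_ALTERNATIVES = ("greater", "two-sided")


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int
    correlation_kind: str  # "pearson"
    alternative: str
    n_sites: int


def _nan_pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise FloregionError("too few finite pairs for a Mantel correlation")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise FloregionError("zero variance in a distance triangle; r undefined")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test between two distance matrices over identical sites."""
    if alternative not in VALID_ALTERNATIVES:
        raise FloregionError(f"alternative must be one of {VALID_ALTERNATIVES}")
    if d1.site_ids != d2.site_ids:
        raise FloregionError("matrices must share site ids and ordering")
    n = d1.n
    if n < 4:
        raise FloregionError("Mantel test needs at least 4 sites")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    y = d2.values[iu]
    r_obs = _nan_pearson(x, y)

    rng = np.random.default_rng(seed)
    v2 = d2.values
    null_r = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        yp = v2[np.ix_(perm, perm)][iu]
        null_r[b] = _nan_pearson(x, yp)
    if alternative == "greater":
        p = (1.0 + np.sum(null_r >= r_obs)) / (1.0 + n_permutations)
    else:
        p = (1.0 + np.sum(np.abs(null_r) >= abs(r_obs))) / (1.0 + n_permutations)
    return MantelResult(
        r=r_obs,
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
        correlation_kind="pearson",
        alternative=alternative,
        n_sites=n,
    )
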