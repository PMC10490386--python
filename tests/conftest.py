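import numpy as np
import pytest

from floregion import (
    DistanceMatrix,
    OccurrenceMatrix,
    Phylogeny,
    SyntheticScenario,
)

import pandas as pd


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree() -> Phylogeny:
    """Star phylogeny, four unit-length terminal branches."""
    return Phylogeny.from_newick("(t1:1,t2:1,t3:1,t4:1);")


@pytest.fixture
def small_matrix() -> OccurrenceMatrix:
    table = pd.DataFrame(
        [[1, 1, 0], [0, 1, 1], [1, 0, 1]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
    )
    return OccurrenceMatrix(table)


@pytest.fixture
def strong_scenario() -> SyntheticScenario:
    """Strongly separated planted structure for recovery checks."""
    return SyntheticScenario(
        n_tips=400, p_focal=0.95, p_background=0.02, noise_flip=0.0, seed=7
    )


def euclidean_dm(points: np.ndarray, prefix: str = "s") -> DistanceMatrix:
    from scipy.spatial.distance import pdist, squareform

    n = points.shape[0]
    ids = tuple(f"{prefix}{i}" for i in range(n))
    return DistanceMatrix(ids, squareform(pdist(points)), "euclidean")


@pytest.fixture
def random_ultrametric():
    """Factory: distances read off a random ultrametric dendrogram.

    Built by agglomerating singletons at strictly increasing heights, so
    UPGMA must reproduce the generating merges exactly (its fixed point).
    """

    def make(n: int, seed: int) -> DistanceMatrix:
        rng = np.random.default_rng(seed)
        clusters = [[i] for i in range(n)]
        vals = np.zeros((n, n))
        height = 0.0
        while len(clusters) > 1:
            height += rng.uniform(0.2, 1.0)
            i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
            for a in clusters[i]:
                for b in clusters[j]:
                    vals[a, b] = vals[b, a] = height
            clusters[i] = clusters[i] + clusters.pop(j)
        ids = tuple(f"u{i}" for i in range(n))
        return DistanceMatrix(ids, vals, "ultrametric")

    return make
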