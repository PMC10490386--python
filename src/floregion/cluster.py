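"""Agglomerative clustering, dendrogram validation and region delineation.

Eight Lance–Williams linkage variants are fitted to a dissimilarity matrix
and scored by how faithfully their dendrogram reproduces the input: the
cophenetic correlation coefficient (CCC; Pearson correlation between
original and cophenetic distances, higher is better) and Gower's distance
(GD; sum of squared discrepancies, lower is better). The method with the
highest CCC (ties: lowest GD, then a fixed name order) is selected. The
number of regions is chosen by maximizing the mean silhouette width over
dendrogram cuts, and sites are assigned to regions by the k-cut and to
realms by the 2-cut of the same dendrogram, so regions nest inside realms
by construction. Geographic contiguity is reported as a diagnostic against
an optional adjacency list, never enforced.

Naming follows the R ``hclust`` conventions: ward.D applies the Ward update
to raw dissimilarities, ward.D2 to squared dissimilarities (with heights on
the original scale); UPGMC/WPGMC heights are on the distance (not squared)
scale, and those centroid methods may produce inversions, which are flagged
but not repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .core import DistanceMatrix, FloregionError, SiteAdjacency

# fixed lexicographic (ASCII) order; doubles as the deterministic tie-break
# in select_method, so UPGMA precedes the other exact fits on ultrametric
# input (every graph-based linkage reproduces an ultrametric matrix exactly)
METHOD_ORDER = (
    "UPGMA",
    "UPGMC",
    "WPGMA",
    "WPGMC",
    "complete",
    "single",
    "ward.D",
    "ward.D2",
)

_SCIPY_NAME = {
    "single": "single",
    "complete": "complete",
    "UPGMA": "average",
    "WPGMA": "weighted",
    "UPGMC": "centroid",
    "WPGMC": "median",
    "ward.D2": "ward",
}


@dataclass
class LinkageResult:
    """One linkage fit: merge tree, cophenetic matrix and fit scores."""

    method: str
    site_ids: tuple
    merge_sequence: np.ndarray  # scipy-format (n-1, 4) linkage matrix
    cophenetic: DistanceMatrix
    ccc: float
    gd: float
    has_inversions: bool

    @property
    def n(self) -> int:
        return len(self.site_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merge_sequence[:, 2]


@dataclass
class RegionAssignment:
    """Site -> region (k-cut) and site -> realm (2-cut) labels."""

    site_ids: tuple
    regions: dict
    realms: dict
    k: int
    realm_of_region: dict
    mean_silhouette: float
    silhouette_widths: dict
    criteria_report: dict = field(default_factory=dict)


def linkage(dist: DistanceMatrix, method: str) -> LinkageResult:
    """Agglomerate ``dist`` under the named linkage variant."""
    if method not in METHOD_ORDER:
        raise FloregionError(f"unknown linkage method {method!r}; choose from {METHOD_ORDER}")
    if dist.n < 3:
        raise FloregionError("clustering needs at least 3 sites")
    y = dist.condensed()
    if not np.isfinite(y).all():
        raise FloregionError("distance matrix contains non-finite values")
    if method == "ward.D":
        # scipy's 'ward' runs the Lance-Williams Ward update on the squares
        # of its input and reports square-rooted heights; feeding sqrt(d) and
        # squaring the heights therefore yields Ward on raw dissimilarities.
        z = sch.linkage(np.sqrt(y), method="ward")
        z = z.copy()
        z[:, 2] **= 2
    else:
        z = sch.linkage(y, method=_SCIPY_NAME[method])
    coph = squareform(sch.cophenet(z))
    coph_dm = DistanceMatrix(dist.site_ids, coph, metric=f"cophenetic[{method}]")
    try:
        fit_ccc = ccc(dist, coph_dm)
    except FloregionError:
        fit_ccc = float("nan")  # zero-variance input; GD still meaningful
    return LinkageResult(
        method=method,
        site_ids=dist.site_ids,
        merge_sequence=z,
        cophenetic=coph_dm,
        ccc=fit_ccc,
        gd=gower_distance(dist, coph_dm),
        has_inversions=bool(np.any(np.diff(z[:, 2]) < -1e-12)),
    )


def cophenetic_matrix(result: LinkageResult) -> DistanceMatrix:
    """Entry (i, j): height of the first merge uniting sites i and j."""
    return result.cophenetic


def ccc(dist: DistanceMatrix, coph: DistanceMatrix) -> float:
    """Cophenetic correlation: Pearson r over strictly-lower triangles."""
    x, y = dist.condensed(), coph.condensed()
    if x.std() == 0 or y.std() == 0:
        raise FloregionError("zero variance; cophenetic correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def gower_distance(dist: DistanceMatrix, coph: DistanceMatrix) -> float:
    """Sum of squared discrepancies between original and cophenetic distances."""
    d = dist.condensed() - coph.condensed()
    return float(np.dot(d, d))


def select_method(
    dist: DistanceMatrix, methods: tuple = METHOD_ORDER
) -> tuple[str, pd.DataFrame, dict]:
    """Fit every linkage, score CCC/GD, and pick the best method.

    Best = maximal CCC; ties broken by minimal GD, then by position in the
    fixed method order. Returns (best_method, score table, fitted results).
    """
    results = {m: linkage(dist, m) for m in methods}
    table = pd.DataFrame(
        {
            "CCC": [results[m].ccc for m in methods],
            "GD": [results[m].gd for m in methods],
        },
        index=list(methods),
    )
    def rank(m):
        # round scores so floating-point dust cannot decide a genuine tie
        c = results[m].ccc
        c = round(c, 10) if np.isfinite(c) else -np.inf
        return (-c, round(results[m].gd, 10), methods.index(m))

    best = min(methods, key=rank)
    return best, table, results


def cut_dendrogram(result: LinkageResult, k: int) -> np.ndarray:
    """Partition sites into exactly k clusters by undoing the last k-1 merges.

    Cutting by merge order (not height) is deterministic under tied heights:
    the merge index itself breaks ties, and cuts at k1 < k2 always nest.
    Labels are integers 0..k-1 ordered by each cluster's smallest site index.
    """
    n = result.n
    if not (1 <= k <= n):
        raise FloregionError(f"k={k} out of range for {n} sites")
    z = result.merge_sequence
    members: dict[int, list] = {i: [i] for i in range(n)}
    for row in range(n - k):
        a, b = int(z[row, 0]), int(z[row, 1])
        members[n + row] = members.pop(a) + members.pop(b)
    labels = np.empty(n, dtype=int)
    for lab, mem in enumerate(sorted(members.values(), key=min)):
        labels[np.asarray(mem)] = lab
    return labels


def silhouette(dist: DistanceMatrix, labels) -> tuple[np.ndarray, float]:
    """Silhouette widths s(i) = (b - a) / max(a, b) from a distance matrix.

    a(i): mean distance to own cluster (self excluded); b(i): smallest mean
    distance to another cluster. Singleton clusters score 0.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise FloregionError("silhouette needs at least 2 clusters")
    v = dist.values
    widths = np.zeros(dist.n)
    masks = {c: labels == c for c in uniq}
    for i in range(dist.n):
        own = masks[labels[i]].copy()
        own[i] = False
        if not own.any():  # singleton
            widths[i] = 0.0
            continue
        a = v[i, own].mean()
        b = min(v[i, masks[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return widths, float(widths.mean())


def select_k(
    result: LinkageResult,
    dist: DistanceMatrix,
    k_min: int = 2,
    k_max: int | None = None,
) -> tuple[int, dict]:
    """Choose the cut level maximizing mean silhouette width.

    Ties go to the smaller k. Returns (k_best, {k: mean silhouette}).
    """
    n = result.n
    if k_max is None:
        k_max = min(15, n - 1)
    if not (2 <= k_min <= k_max <= n - 1):
        raise FloregionError(f"invalid k range [{k_min}, {k_max}] for {n} sites")
    curve: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        _, mean_s = silhouette(dist, cut_dendrogram(result, k))
        curve[k] = mean_s
    k_best = min(curve, key=lambda k: (-curve[k], k))
    return k_best, curve


def assign_regions(
    result: LinkageResult,
    dist: DistanceMatrix,
    k: int,
    adjacency: SiteAdjacency | None = None,
) -> RegionAssignment:
    """Label sites with regions (k-cut) and realms (2-cut of the same tree).

    Each region is a complete dendrogram subtree by construction of the cut,
    and nests inside exactly one realm because cuts of one tree are
    hierarchical. Contiguity against ``adjacency`` is reported, not enforced.
    """
    region_labels = cut_dendrogram(result, k)
    realm_labels = cut_dendrogram(result, min(2, k))
    sites = result.site_ids
    region_names = {c: f"region_{c + 1}" for c in np.unique(region_labels)}
    realm_names = {c: f"realm_{c + 1}" for c in np.unique(realm_labels)}
    regions = {s: region_names[c] for s, c in zip(sites, region_labels)}
    realms = {s: realm_names[c] for s, c in zip(sites, realm_labels)}

    realm_of_region: dict = {}
    for s in sites:
        r = regions[s]
        if r in realm_of_region and realm_of_region[r] != realms[s]:
            raise AssertionError("region split across realms; cuts failed to nest")
        realm_of_region[r] = realms[s]

    widths, mean_s = silhouette(dist, region_labels)
    report: dict = {"monophyletic_regions": True}
    if adjacency is not None:
        nb = adjacency.neighbors()
        bad = []
        for rname in region_names.values():
            mem = {s for s in sites if regions[s] == rname}
            if _n_components(mem, nb) > 1:
                bad.append(rname)
        report["noncontiguous_regions"] = sorted(bad)
        report["n_noncontiguous_regions"] = len(bad)
    return RegionAssignment(
        site_ids=sites,
        regions=regions,
        realms=realms,
        k=k,
        realm_of_region=realm_of_region,
        mean_silhouette=mean_s,
        silhouette_widths={s: float(w) for s, w in zip(sites, widths)},
        criteria_report=report,
    )


def _n_components(members: set, neighbors) -> int:
    todo = set(members)
    n = 0
    while todo:
        n += 1
        stack = [todo.pop()]
        while stack:
            x = stack.pop()
            for y in neighbors.get(x, ()):  # type: ignore[union-attr]
                if y in todo:
                    todo.remove(y)
                    stack.append(y)
    return n


def dendrogram_newick(result: LinkageResult) -> str:
    """Dendrogram as Newick with branch lengths from merge-height gaps."""
    root, _ = sch.to_tree(result.merge_sequence, rd=True)
    sites = result.site_ids

    def rec(node, parent_height):
        if node.is_leaf():
            return f"{sites[node.id]}:{parent_height:.12g}"
        h = node.dist
        left = rec(node.left, h)
        right = rec(node.right, h)
        return f"({left},{right}):{max(parent_height - h, 0.0):.12g}"

    h = root.dist
    return f"({rec(root.left, h)},{rec(root.right, h)});"
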