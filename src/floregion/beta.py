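"""Taxonomic and phylogenetic pairwise turnover.

Two families of dissimilarity are computed between site pairs, both from the
same a/b/c decomposition — a the shared amount, b and c the amounts unique to
each site:

* the Simpson turnover component of Sorensen dissimilarity,
  ``beta_sim = min(b, c) / (a + min(b, c))``, which isolates taxon
  replacement from richness differences, and
* the turnover component of Jaccard dissimilarity,
  ``beta_jtu = 2 min(b, c) / (a + 2 min(b, c))``, used as a sensitivity
  variant (it is a monotone transform of beta_sim, so the two always rank
  site pairs identically).

For the taxonomic versions a, b, c count genera; for the phylogenetic
versions (pbeta_sim, pbeta_jtu) they are branch-length amounts from rooted
phylogenetic diversity (PD): with ``P_i``, ``P_j`` and ``P_u`` the PD of each
site and of their union, ``a = P_i + P_j - P_u``, ``b = P_u - P_j``,
``c = P_u - P_i``, which conserves ``a + b + c = P_u`` exactly. PD is
root-anchored by default (every tip's path runs to the root of the dated
tree); an MRCA-anchored variant is available via ``anchor="mrca"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DistanceMatrix, FloregionError, OccurrenceMatrix, Phylogeny

TAXON_METRICS = ("beta_sim", "beta_jtu")
PHYLO_METRICS = ("pbeta_sim", "pbeta_jtu")
METRICS = TAXON_METRICS + PHYLO_METRICS


@dataclass(frozen=True)
class BetaComponents:
    """Shared (a) and unique (b, c) amounts for one site pair.

    ``basis`` records whether amounts are taxon counts or branch lengths.
    """

    a: float
    b: float
    c: float
    basis: str  # "taxon-count" | "branch-length"

    def __post_init__(self):
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise FloregionError("negative turnover component")

    def swapped(self) -> "BetaComponents":
        return BetaComponents(self.a, self.c, self.b, self.basis)


def taxon_components(x_i: frozenset | set, x_j: frozenset | set) -> BetaComponents:
    """a = |intersection|, b = |i only|, c = |j only|."""
    x_i, x_j = set(x_i), set(x_j)
    return BetaComponents(
        a=len(x_i & x_j), b=len(x_i - x_j), c=len(x_j - x_i), basis="taxon-count"
    )


def _check_defined(comp: BetaComponents) -> None:
    if comp.a == 0 and min(comp.b, comp.c) == 0:
        raise FloregionError(
            "turnover undefined: one side empty or both communities empty"
        )


def beta_sim(comp: BetaComponents) -> float:
    """Simpson turnover: min(b, c) / (a + min(b, c)); 0 identical, 1 disjoint."""
    _check_defined(comp)
    m = min(comp.b, comp.c)
    return m / (comp.a + m)


def beta_jtu(comp: BetaComponents) -> float:
    """Jaccard turnover: 2 min(b, c) / (a + 2 min(b, c))."""
    _check_defined(comp)
    m = min(comp.b, comp.c)
    return 2.0 * m / (comp.a + 2.0 * m)


def rooted_pd(taxa, tree: Phylogeny, anchor: str = "root") -> float:
    """Phylogenetic diversity of a tip set.

    anchor="root": sum of branch lengths on the union of root-to-tip paths.
    anchor="mrca": sum over the minimal spanning subtree below the set's
    most recent common ancestor (the stem above the MRCA excluded).
    """
    taxa = {str(t).strip() for t in taxa}
    if not taxa:
        raise FloregionError("empty taxon set has no phylogenetic diversity")
    unknown = taxa - set(tree.tip_labels)
    if unknown:
        raise FloregionError(f"taxa not in tree: {sorted(unknown)}")
    arr = tree.arrays()
    mask = np.isin(np.asarray(arr.tip_labels), sorted(taxa))
    counts = arr.edge_tips.astype(np.int64) @ mask.astype(np.int64)
    if anchor == "root":
        keep = counts > 0
    elif anchor == "mrca":
        keep = (counts > 0) & (counts < mask.sum())
    else:
        raise FloregionError(f"unknown PD anchor: {anchor!r}")
    return float(arr.edge_lengths[keep].sum())


def phylo_components(
    x_i, x_j, tree: Phylogeny, anchor: str = "root"
) -> BetaComponents:
    """Branch-length a/b/c from PD of each site and of their union."""
    x_i, x_j = set(x_i), set(x_j)
    if not x_i or not x_j:
        raise FloregionError("phylogenetic components need two nonempty sets")
    p_i = rooted_pd(x_i, tree, anchor=anchor)
    p_j = rooted_pd(x_j, tree, anchor=anchor)
    p_u = rooted_pd(x_i | x_j, tree, anchor=anchor)
    a = p_i + p_j - p_u
    b = p_u - p_j
    c = p_u - p_i
    # guard tiny negative values from floating summation order
    eps = 1e-12 * max(p_u, 1.0)
    return BetaComponents(
        a=max(a, 0.0) if a > -eps else a,
        b=max(b, 0.0) if b > -eps else b,
        c=max(c, 0.0) if c > -eps else c,
        basis="branch-length",
    )


def _taxon_abc_matrices(pres: np.ndarray):
    """Vectorized a / min(b, c) over all site pairs from a presence array."""
    v = pres.astype(float)
    a = v @ v.T
    n = v.sum(axis=1)
    b = n[:, None] - a
    c = n[None, :] - a
    return a, np.minimum(b, c)


def _phylo_abc_matrices(pres: np.ndarray, tree: Phylogeny):
    arr = tree.arrays()
    edge_f = arr.edge_tips.astype(float)  # (E, T)
    m = (pres.astype(float) @ edge_f.T) > 0  # (S, E) edge on some rooted path
    mw = m * arr.edge_lengths  # length-weighted incidence
    a = mw @ m.T  # branch length present in both sites' rooted paths
    p = m @ arr.edge_lengths
    b = p[:, None] - a
    c = p[None, :] - a
    return a, np.minimum(b, c)


def _phylo_abc_matrices_mrca(pres: np.ndarray, tree: Phylogeny):
    """Per-pair MRCA-anchored decomposition (slower; pairwise loop)."""
    arr = tree.arrays()
    counts = pres.astype(float) @ arr.edge_tips.T.astype(float)  # (S, E)
    sizes = pres.sum(axis=1)
    L = arr.edge_lengths
    s = pres.shape[0]
    a = np.zeros((s, s))
    bmin = np.zeros((s, s))
    for i in range(s):
        inc_i = (counts[i] > 0) & (counts[i] < sizes[i])
        p_i = float(L[inc_i].sum())
        for j in range(i + 1, s):
            u = pres[i] | pres[j]
            cu = arr.edge_tips.astype(np.int64) @ u.astype(np.int64)
            inc_j = (counts[j] > 0) & (counts[j] < sizes[j])
            inc_u = (cu > 0) & (cu < u.sum())
            p_j = float(L[inc_j].sum())
            p_u = float(L[inc_u].sum())
            aij = p_i + p_j - p_u
            a[i, j] = a[j, i] = aij
            bmin[i, j] = bmin[j, i] = min(p_u - p_j, p_u - p_i)
    return a, bmin


def pairwise(
    mat: OccurrenceMatrix,
    metric: str,
    tree: Phylogeny | None = None,
    anchor: str = "root",
) -> DistanceMatrix:
    """Symmetric site x site matrix of the named turnover metric.

    ``tree`` is required for the phylogenetic metrics and must already be
    harmonized with the matrix (identical taxon label sets).
    """
    if metric not in METRICS:
        raise FloregionError(f"unknown metric {metric!r}; choose from {METRICS}")
    pres = mat.presence()
    if (pres.sum(axis=1) == 0).any():
        raise FloregionError("matrix contains empty sites; drop them first")
    if metric in PHYLO_METRICS:
        if tree is None:
            raise FloregionError(f"{metric} requires a phylogeny")
        if set(tree.tip_labels) != set(mat.taxon_ids):
            raise FloregionError(
                "tree tips and matrix taxa differ; run harmonize() first"
            )
        # align presence columns to the tree's canonical tip order
        order = {t: k for k, t in enumerate(mat.taxon_ids)}
        pres = pres[:, [order[t] for t in tree.arrays().tip_labels]]
        if anchor == "root":
            a, bmin = _phylo_abc_matrices(pres, tree)
        else:
            a, bmin = _phylo_abc_matrices_mrca(pres, tree)
    else:
        a, bmin = _taxon_abc_matrices(pres)
    with np.errstate(invalid="ignore"):  # self-pairs divide 0/0, fixed below
        if metric.endswith("jtu"):
            vals = 2.0 * bmin / (a + 2.0 * bmin)
        else:
            vals = bmin / (a + bmin)
    np.fill_diagonal(vals, 0.0)
    vals = np.clip(vals, 0.0, 1.0)
    vals = 0.5 * (vals + vals.T)  # enforce exact symmetry against fp noise
    return DistanceMatrix(mat.site_ids, vals, metric)


def site_mean(dist: DistanceMatrix) -> "np.ndarray":
    """Per-site mean dissimilarity to all other sites (NaN pairs excluded).

    Returned as a pandas-free array aligned with ``dist.site_ids``.
    """
    if dist.n < 2:
        raise FloregionError("site means need at least 2 sites")
    v = dist.values.copy()
    np.fill_diagonal(v, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(v, axis=1)
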