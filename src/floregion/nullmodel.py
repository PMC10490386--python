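"""Tip-shuffling null model and standardized effect sizes for pbeta_sim.

The null randomly permutes the tip labels of the phylogeny, preserving tree
shape, branch lengths and every site's taxon list — and therefore preserving
taxonomic turnover exactly — while destroying the phylogenetic identity of
taxa. Repeating the permutation many times (999 by default) yields, for each
site pair, a null distribution of pbeta_sim from which the standardized
effect size

    SES = (observed - mean(null)) / sd(null)

is computed with the sample (n-1) standard deviation. Positive SES means
more phylogenetic turnover than expected given the taxonomic turnover;
|SES| > 1.96 is flagged as significant at the ~5% two-sided level. Per-site
summaries average each site's SES against all others, matching per-county
map reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .beta import _phylo_abc_matrices, pairwise
from .core import DistanceMatrix, FloregionError, OccurrenceMatrix, Phylogeny

log = logging.getLogger("floregion")

SES_SIGNIFICANCE = 1.96


@dataclass
class SESResult:
    """Observed, null-ensemble and standardized pbeta_sim matrices."""

    observed: DistanceMatrix
    null_mean: DistanceMatrix
    null_sd: DistanceMatrix
    ses: DistanceMatrix  # NaN where null_sd == 0 (SES undefined)
    n_permutations: int
    seed: int
    site_mean_ses: np.ndarray
    n_sites_positive: int
    n_sites_negative: int
    n_sites_significant: int
    n_undefined_pairs: int

    @property
    def site_ids(self):
        return self.observed.site_ids


def shuffle_tips(tree: Phylogeny, rng: np.random.Generator) -> Phylogeny:
    """Return a tree with identical shape and branch lengths but tip labels
    permuted uniformly at random over all tips."""
    t2 = Phylogeny.from_newick(tree.to_newick())
    leaves = list(t2.dendropy_tree.leaf_node_iter())
    labels = [str(lv.taxon.label).strip() for lv in leaves]
    perm = rng.permutation(len(labels))
    tns = dendropy.TaxonNamespace()
    for lv, k in zip(leaves, perm):
        lv.taxon = tns.new_taxon(label=labels[k])
    t2.dendropy_tree.taxon_namespace = tns
    return Phylogeny(t2.dendropy_tree)


def ses_pbeta(
    mat: OccurrenceMatrix,
    tree: Phylogeny,
    n_permutations: int = 999,
    seed: int = 0,
    check_taxonomic_invariance: bool = False,
    anchor: str = "root",
) -> SESResult:
    """Tip-shuffle SES of phylogenetic turnover.

    ``check_taxonomic_invariance`` verifies (once) that taxonomic turnover is
    unchanged under a tip shuffle — true by construction, since a shuffle
    only relabels which tip is which on the tree.

    Pairs whose null distribution is degenerate (sd = 0, e.g. on a star tree
    with equal branch lengths where every labelling gives the same turnover)
    get SES = NaN; they are excluded from site means and counted.
    """
    if n_permutations < 2:
        raise FloregionError("need at least 2 permutations for a null sd")
    if set(tree.tip_labels) != set(mat.taxon_ids):
        raise FloregionError("tree tips and matrix taxa differ; run harmonize() first")
    if anchor != "root":
        raise FloregionError("tip-shuffle SES is defined on root-anchored turnover")
    rng = np.random.default_rng(seed)
    observed = pairwise(mat, "pbeta_sim", tree)
    n = observed.n

    # permuting tip labels on the tree == permuting taxon columns of the
    # incidence matrix; work on arrays for speed.
    tips = tree.arrays().tip_labels
    order = {t: k for k, t in enumerate(mat.taxon_ids)}
    pres = mat.presence()[:, [order[t] for t in tips]]

    if check_taxonomic_invariance:
        from .beta import _taxon_abc_matrices

        a0, m0 = _taxon_abc_matrices(pres)
        p0 = pres[:, rng.permutation(pres.shape[1])]
        a1, m1 = _taxon_abc_matrices(p0)
        # shuffling relabels tips; site taxon counts and overlaps persist
        if not (np.allclose(a0, a1) and np.allclose(m0, m1)):  # pragma: no cover
            raise AssertionError("taxonomic turnover changed under tip shuffle")

    iu = np.triu_indices(n, k=1)
    null_vals = np.empty((n_permutations, iu[0].size))
    for b in range(n_permutations):
        perm = rng.permutation(pres.shape[1])
        a, bmin = _phylo_abc_matrices(pres[:, perm], tree)
        vals = bmin / (a + bmin)
        null_vals[b] = vals[iu]
    mean_c = null_vals.mean(axis=0)
    sd_c = null_vals.std(axis=0, ddof=1)

    obs_c = observed.values[iu]
    ses_c = np.full_like(obs_c, np.nan)
    ok = sd_c > 0
    ses_c[ok] = (obs_c[ok] - mean_c[ok]) / sd_c[ok]
    n_undef = int((~ok).sum())
    if n_undef:
        log.info("ses_pbeta: %d pair(s) with degenerate null (sd = 0)", n_undef)

    def square(cond, fill_diag=0.0):
        m = np.zeros((n, n))
        m[iu] = cond
        m = m + m.T
        np.fill_diagonal(m, fill_diag)
        return m

    ses_mat = DistanceMatrix(observed.site_ids, square(ses_c), "ses_pbeta_sim")
    result = SESResult(
        observed=observed,
        null_mean=DistanceMatrix(observed.site_ids, square(mean_c), "null_mean"),
        null_sd=DistanceMatrix(observed.site_ids, square(sd_c), "null_sd"),
        ses=ses_mat,
        n_permutations=n_permutations,
        seed=seed,
        site_mean_ses=_site_mean_allow_all_nan(ses_mat),
        n_sites_positive=0,
        n_sites_negative=0,
        n_sites_significant=0,
        n_undefined_pairs=n_undef,
    )
    sm = result.site_mean_ses
    result.n_sites_positive = int(np.sum(sm > 0))
    result.n_sites_negative = int(np.sum(sm < 0))
    result.n_sites_significant = int(np.sum(np.abs(sm) > SES_SIGNIFICANCE))
    return result


def _site_mean_allow_all_nan(dist: DistanceMatrix) -> np.ndarray:
    v = dist.values.copy()
    np.fill_diagonal(v, np.nan)
    with np.errstate(invalid="ignore"):
        out = np.full(dist.n, np.nan)
        counts = np.sum(np.isfinite(v), axis=1)
        has = counts > 0
        out[has] = np.nansum(v[has], axis=1) / counts[has]
    return out
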