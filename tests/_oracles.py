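"""Independent slow oracles used to verify the package's fast paths.

These deliberately avoid the implementation's edge-incidence machinery:
branch-length components are derived by walking the dendropy tree and
classifying every edge by the membership of its descendant tips.
"""

from __future__ import annotations

import numpy as np


def edge_classification_components(x_i, x_j, tree):
    """a/b/c branch-length components by per-edge classification.

    Every edge (root edge excluded) is classified by whether any descendant
    tip lies in x_i and/or x_j: shared (both), unique-i, unique-j, or absent.
    """
    x_i, x_j = set(x_i), set(x_j)
    dt = tree.dendropy_tree
    a = b = c = 0.0
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            continue
        tips = {str(lf.taxon.label).strip() for lf in node.leaf_iter()}
        in_i = bool(tips & x_i)
        in_j = bool(tips & x_j)
        if in_i and in_j:
            a += node.edge.length
        elif in_i:
            b += node.edge.length
        elif in_j:
            c += node.edge.length
    return a, b, c


def brute_force_taxon_components(x_i, x_j, universe):
    """Element-by-element a/b/c counts over an explicit taxon universe."""
    a = b = c = 0
    for t in universe:
        if t in x_i and t in x_j:
            a += 1
        elif t in x_i:
            b += 1
        elif t in x_j:
            c += 1
    return a, b, c


def upgma_by_hand(vals: np.ndarray):
    """Naive UPGMA agglomeration: returns merge heights and a cophenetic
    matrix, tracking all pairwise means explicitly."""
    n = vals.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                i, j = keys[ai], keys[bi]
                d = np.mean([vals[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = d
        clusters[i] = clusters[i] + clusters.pop(j)
    return np.array(heights), coph
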