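"""Core in-memory containers shared across the package.

Three containers carry the pipeline's state: :class:`Phylogeny` (a rooted,
branch-lengthed tree over taxon labels, wrapping a dendropy tree plus cached
edge/tip index arrays), :class:`OccurrenceMatrix` (a binary site x taxon
incidence table backed by a pandas DataFrame) and :class:`DistanceMatrix`
(a labelled symmetric dissimilarity matrix). :class:`SiteAdjacency` records
which sites are geographically adjacent, used only for contiguity reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd


class FloregionError(ValueError):
    """Base class for input-validation and contract errors."""


@dataclass(frozen=True)
class TreeArrays:
    """Edge-indexed view of a rooted tree.

    ``edge_tips[e, t]`` is True when tip ``t`` descends from edge ``e`` (the
    edge above a node, the root's own edge excluded). Rooted phylogenetic
    diversity of any tip set is then a masked sum over ``edge_lengths``.
    """

    tip_labels: tuple[str, ...]
    edge_lengths: np.ndarray  # (E,) float
    edge_tips: np.ndarray     # (E, T) bool

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())


class Phylogeny:
    """A rooted tree with finite, nonnegative branch lengths and unique tips.

    Parameters
    ----------
    tree
        A dendropy tree. The seed-node (root) edge length, if present, is
        ignored: it lies above the root and would add a constant to every
        rooted path. All other edges must carry finite lengths >= 0 unless
        ``default_edge_length`` supplies one.
    default_edge_length
        Optional length assigned to edges whose length is missing. By default
        missing lengths are an error because branch-length-based turnover is
        undefined without them.
    """

    def __init__(self, tree: dendropy.Tree, default_edge_length: float | None = None):
        self._tree = tree
        labels: list[str] = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise FloregionError("tree contains an unlabeled tip")
            labels.append(str(leaf.taxon.label).strip())
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise FloregionError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise FloregionError("tree must have at least 2 tips")
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            if node.edge.length is None:
                if default_edge_length is None:
                    raise FloregionError(
                        "tree has edges without branch lengths; pass a default "
                        "edge length to accept it"
                    )
                node.edge.length = float(default_edge_length)
            if not np.isfinite(node.edge.length) or node.edge.length < 0:
                raise FloregionError(f"invalid branch length: {node.edge.length}")
        self._tip_labels = tuple(sorted(labels))
        self._arrays: TreeArrays | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, default_edge_length: float | None = None) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree, default_edge_length=default_edge_length)

    # -- basic properties ---------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in sorted order (the canonical tip ordering)."""
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def total_branch_length(self) -> float:
        return self.arrays().total_length

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        depths: dict[str, float] = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node is not self._tree.seed_node:
                d += node.edge.length
                node = node.parent_node
            depths[str(leaf.taxon.label).strip()] = d
        return depths

    # -- array view ---------------------------------------------------------

    def arrays(self) -> TreeArrays:
        """Edge-indexed arrays (cached); edges exclude the root's own edge."""
        if self._arrays is None:
            idx = {lab: i for i, lab in enumerate(self._tip_labels)}
            lengths: list[float] = []
            rows: list[np.ndarray] = []
            # postorder so each node's tip mask is built from its children
            masks: dict[int, np.ndarray] = {}
            for node in self._tree.postorder_node_iter():
                if node.is_leaf():
                    m = np.zeros(len(idx), dtype=bool)
                    m[idx[str(node.taxon.label).strip()]] = True
                else:
                    m = np.zeros(len(idx), dtype=bool)
                    for ch in node.child_nodes():
                        m |= masks[id(ch)]
                masks[id(node)] = m
                if node is not self._tree.seed_node:
                    lengths.append(float(node.edge.length))
                    rows.append(m)
            self._arrays = TreeArrays(
                tip_labels=self._tip_labels,
                edge_lengths=np.asarray(lengths, dtype=float),
                edge_tips=np.vstack(rows),
            )
        return self._arrays

    # -- manipulation -------------------------------------------------------

    def copy(self) -> "Phylogeny":
        return Phylogeny.from_newick(self.to_newick())

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Restrict to ``labels``; degree-2 nodes created by pruning are
        suppressed with their incident branch lengths summed, so root-to-tip
        path lengths of retained tips are preserved."""
        keep = {str(x).strip() for x in labels}
        missing = keep - set(self._tip_labels)
        if missing:
            raise FloregionError(f"labels not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise FloregionError("cannot prune to fewer than 2 tips")
        tree = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )
        tree.retain_taxa_with_labels(sorted(keep))
        # dendropy suppresses unifurcations (summing edge lengths) on prune;
        # a leftover degree-1 seed node is collapsed here for safety.
        tree.suppress_unifurcations()
        return Phylogeny(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    def bipartition_lengths(self) -> dict[frozenset, float]:
        """Map each edge's descendant tip set to its branch length (summing
        lengths of any edges subtending identical tip sets). Used to compare
        trees as labelled topologies with lengths."""
        arr = self.arrays()
        out: dict[frozenset, float] = {}
        for e in range(arr.edge_lengths.shape[0]):
            tips = frozenset(
                lab for lab, m in zip(arr.tip_labels, arr.edge_tips[e]) if m
            )
            out[tips] = out.get(tips, 0.0) + float(arr.edge_lengths[e])
        return out


@dataclass
class OccurrenceMatrix:
    """Binary site x taxon incidence table.

    ``table`` is a pandas DataFrame with site ids as the index and taxon ids
    as columns, values in {0, 1}.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise FloregionError("duplicate site ids")
        if t.columns.has_duplicates:
            raise FloregionError("duplicate taxon ids")
        vals = t.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise FloregionError(
                f"non-binary cell at site {t.index[bad[0]]!r}, "
                f"taxon {t.columns[bad[1]]!r}: {vals[tuple(bad)]!r}"
            )
        self.table = t.astype(np.int8)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.table.index)

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.table.columns)

    @property
    def n_sites(self) -> int:
        return self.table.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.table.shape[1]

    def presence(self) -> np.ndarray:
        """Boolean (n_sites, n_taxa) presence array."""
        return self.table.to_numpy(dtype=bool)

    def taxon_set(self, site_id: str) -> frozenset:
        row = self.table.loc[site_id]
        return frozenset(str(c) for c, v in row.items() if v)

    def drop_empty(self) -> tuple["OccurrenceMatrix", dict]:
        """Drop all-zero sites and taxa; report what was removed."""
        out = self.table
        empty_sites: list = []
        empty_taxa: list = []
        while True:  # dropping sites can empty taxa and vice versa
            es = [str(s) for s in out.index[out.sum(axis=1) == 0]]
            et = [str(c) for c in out.columns[out.sum(axis=0) == 0]]
            if not es and not et:
                break
            empty_sites += es
            empty_taxa += et
            out = out.drop(index=es).drop(columns=et)
            if out.shape[0] == 0 or out.shape[1] == 0:
                raise FloregionError(
                    "matrix is empty after dropping all-zero rows/columns"
                )
        return OccurrenceMatrix(out), {
            "dropped_sites": empty_sites,
            "dropped_taxa": empty_taxa,
        }

    def restrict_taxa(self, taxa: Iterable[str]) -> "OccurrenceMatrix":
        keep = [c for c in self.table.columns if str(c) in set(map(str, taxa))]
        return OccurrenceMatrix(self.table[keep])


_TURNOVER_METRICS = {"beta_sim", "beta_jtu", "pbeta_sim", "pbeta_jtu"}


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with zero diagonal.

    Turnover metrics are range-checked to [0, 1]; other metrics (e.g. SES
    surfaces) may take any real value and may contain NaN for undefined pairs.
    """

    site_ids: tuple
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.site_ids = tuple(str(s) for s in self.site_ids)
        v = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if v.shape != (n, n):
            raise FloregionError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(np.nan_to_num(v - v.T, nan=0.0), 0.0, atol=1e-12):
            raise FloregionError("matrix is not symmetric")
        if not np.allclose(np.diag(np.nan_to_num(v, nan=0.0)), 0.0, atol=1e-12):
            raise FloregionError("diagonal is not zero")
        if self.metric in _TURNOVER_METRICS:
            off = v[~np.eye(n, dtype=bool)]
            off = off[np.isfinite(off)]
            if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
                raise FloregionError(f"{self.metric} values outside [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.site_ids)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries, scipy 'condensed' order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.site_ids)}
        idx = [pos[str(s)] for s in ids]
        return DistanceMatrix(tuple(ids), self.values[np.ix_(idx, idx)], self.metric)


@dataclass
class SiteAdjacency:
    """Unordered adjacent site pairs, for contiguity reporting only."""

    pairs: frozenset  # of frozenset({a, b})
    site_ids: tuple = ()

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple], known_sites: Iterable[str] | None = None
    ) -> "SiteAdjacency":
        known = {str(s) for s in known_sites} if known_sites is not None else None
        out = set()
        for a, b in pairs:
            a, b = str(a).strip(), str(b).strip()
            if a == b:
                raise FloregionError(f"self-adjacency for site {a!r}")
            if known is not None and (a not in known or b not in known):
                bad = [x for x in (a, b) if x not in known]
                raise FloregionError(f"adjacency references unknown sites: {bad}")
            out.add(frozenset((a, b)))
        return cls(pairs=frozenset(out), site_ids=tuple(sorted(known)) if known else ())

    def neighbors(self) -> Mapping[str, set]:
        nb: dict[str, set] = {}
        for pair in self.pairs:
            a, b = tuple(pair)
            nb.setdefault(a, set()).add(b)
            nb.setdefault(b, set()).add(a)
        return nb
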