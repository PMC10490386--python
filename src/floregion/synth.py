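"""Synthetic floras with planted regional structure.

The generator emulates the inputs of a county-level floristic survey: a
dated genus-level phylogeny and a binary site x genus incidence matrix. A
pure-birth (Yule) tree supplies an ultrametric phylogeny; occupancy is then
planted hierarchically, with clade-biased affinity at two depths: each
region has a focal clade whose tips occur in that region's sites with high
probability (``p_focal``); each realm additionally has a smaller core clade,
present at the same rate in every site of the realm, which carries the
realm-depth signal (a shared realm flora); all remaining tips occur with a
low background probability (``p_background``); finally each cell is flipped
with probability ``noise_flip``. The planted realm/region labels are
returned so downstream clustering can be scored against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .core import FloregionError, OccurrenceMatrix, Phylogeny


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic flora.

    Defaults describe a two-realm, four-region flora of 40 sites on a
    400-tip tree with strong focal-clade fidelity, sparse background
    occupancy and light observation noise.
    """

    n_tips: int = 400
    n_realms: int = 2
    regions_per_realm: int = 2
    sites_per_region: int = 10
    p_focal: float = 0.9
    p_background: float = 0.05
    realm_depth_bias: float = 1.0
    noise_flip: float = 0.01
    seed: int = 0
    min_clade_size: int | None = None  # derived from n_tips when None
    max_clade_size: int | None = None

    def __post_init__(self):
        if self.n_realms < 2:
            raise FloregionError("need at least 2 realms")
        if self.regions_per_realm < 1:
            raise FloregionError("need at least 1 region per realm")
        if self.sites_per_region < 2:
            raise FloregionError("need at least 2 sites per region")
        if not (0.0 < self.p_focal <= 1.0):
            raise FloregionError("p_focal must be in (0, 1]")
        if not (0.0 <= self.p_background < 1.0):
            raise FloregionError("p_background must be in [0, 1)")
        if self.p_focal <= self.p_background:
            raise FloregionError("p_focal must exceed p_background")
        if not (0.0 <= self.realm_depth_bias <= 1.0):
            raise FloregionError("realm_depth_bias must be in [0, 1]")
        if not (0.0 <= self.noise_flip < 0.5):
            raise FloregionError("noise_flip must be in [0, 0.5)")

    @property
    def n_regions(self) -> int:
        return self.n_realms * self.regions_per_realm

    @property
    def n_sites(self) -> int:
        return self.n_regions * self.sites_per_region

    def clade_size_bounds(self) -> tuple[int, int]:
        lo = self.min_clade_size or max(3, self.n_tips // (4 * self.n_regions))
        hi = self.max_clade_size or max(lo, self.n_tips // self.n_regions)
        return lo, hi

    def core_size_bounds(self) -> tuple[int, int]:
        """Size bounds for each realm's core clade (see plant_regions):
        smaller than region clades so region identity stays dominant."""
        lo, hi = self.clade_size_bounds()
        lo_c = max(3, lo // 2)
        return lo_c, max(lo_c, hi // 3)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth realm/region label for every generated site."""

    realm_of: dict  # site_id -> realm label
    region_of: dict  # site_id -> region label
    focal_tips: dict  # region label -> frozenset of focal-clade tips
    realm_core_tips: dict  # realm label -> frozenset of realm-core tips

    def to_dataframe(self) -> pd.DataFrame:
        sites = sorted(self.region_of)
        return pd.DataFrame(
            {
                "site": sites,
                "realm": [self.realm_of[s] for s in sites],
                "region": [self.region_of[s] for s in sites],
            }
        )


def simulate_tree(n_tips: int, seed: int | np.random.Generator) -> Phylogeny:
    """Pure-birth (Yule, rate 1) ultrametric tree on ``n_tips`` tips.

    Starting from two lineages, an exponential waiting time with rate equal
    to the current lineage count elapses between successive speciations; a
    uniformly chosen lineage bifurcates each time. After the tree reaches
    ``n_tips`` lineages one further waiting time elapses before the present,
    so the expected root-to-tip depth is sum_{k=2}^{n} 1/k.
    """
    if n_tips < 3:
        raise FloregionError("need at least 3 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    extant = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        extant.append(child)
    k = 2
    while True:
        wait = rng.exponential(1.0 / k)
        for node in extant:
            node.edge.length += wait
        if k == n_tips:
            break
        pick = int(rng.integers(k))
        parent = extant.pop(pick)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            extant.append(child)
        k += 1
    width = len(str(n_tips))
    for i, node in enumerate(extant):
        node.taxon = tns.new_taxon(label=f"t{i + 1:0{width}d}")
    return Phylogeny(tree)


def _clade_tipsets(tree: Phylogeny):
    """(node tip-set) for every internal edge, as sorted tuples of labels."""
    arr = tree.arrays()
    labels = np.asarray(arr.tip_labels)
    out = []
    for e in range(arr.edge_lengths.shape[0]):
        mask = arr.edge_tips[e]
        if mask.sum() >= 2:
            out.append(tuple(labels[mask]))
    return out


def _deep_subtrees(tree: Phylogeny):
    """Tip sets of the root's grandchild subtrees, grouped by root child.

    A 'deep subtree' is a child subtree of one of the two root children;
    planting each realm inside a distinct one creates the deep two-way split
    that the realm level of the hierarchy is meant to carry.
    """
    root = tree.dendropy_tree.seed_node
    groups = []
    for child in root.child_nodes():
        sub = []
        for gc in child.child_nodes():
            tips = tuple(
                sorted(str(lf.taxon.label).strip() for lf in gc.leaf_iter())
            )
            if len(tips) >= 2:
                sub.append(tips)
        if sub:
            groups.append(sub)
    return groups


def _select_focal_clades(tree: Phylogeny, scenario: SyntheticScenario, rng):
    """Pick, per realm, regions_per_realm focal clades plus one realm core.

    With probability ``realm_depth_bias`` each realm's clades are confined to
    one deep subtree (distinct per realm, spread across the two root children
    where possible); otherwise clades are drawn from anywhere in the tree.
    All picked clades are mutually disjoint across the whole scenario. The
    realm core is a smaller clade shared by every site of the realm (the
    realm-depth tier of the planted hierarchy). Returns
    {realm_index: (region_clades, core_clade)} or None if infeasible.
    """
    lo, hi = scenario.clade_size_bounds()
    lo_c, hi_c = scenario.core_size_bounds()
    use_deep = rng.random() < scenario.realm_depth_bias

    def disjoint_pick(candidates, k, used, bounds):
        b_lo, b_hi = bounds
        picks = []
        order = rng.permutation(len(candidates))
        for idx in order:
            tips = candidates[idx]
            if not (b_lo <= len(tips) <= b_hi):
                continue
            tipset = set(tips)
            if tipset & used:
                continue
            picks.append(tips)
            used |= tipset
            if len(picks) == k:
                return picks
        return None

    def pick_realm(candidates, used):
        picks = disjoint_pick(candidates, scenario.regions_per_realm, used, (lo, hi))
        if picks is None:
            return None
        core = disjoint_pick(candidates, 1, used, (lo_c, hi_c))
        if core is None:
            return None
        return picks, core[0]

    used: set = set()
    if use_deep:
        groups = _deep_subtrees(tree)
        by_group: dict[int, list] = {}
        for gi, grp in enumerate(groups):
            by_group[gi] = list(grp)
        if not by_group:
            return None
        assigned: list = []
        # spread realms across root children round-robin for a deep split
        gi_cycle = sorted(by_group, key=lambda g: -max(len(s) for s in by_group[g]))
        taken = set()
        need = scenario.regions_per_realm * lo + lo_c
        for r in range(scenario.n_realms):
            gi = gi_cycle[r % len(gi_cycle)]
            cands = [
                s for s in sorted(by_group[gi], key=len, reverse=True)
                if id(s) not in taken and not (set(s) & used) and len(s) >= need
            ]
            if not cands:
                return None
            subtree = cands[0]
            taken.add(id(subtree))
            sub_tree = tree.prune_to(subtree)
            got = pick_realm(_clade_tipsets(sub_tree), used)
            if got is None:
                return None
            assigned.append(got)
        return {r: assigned[r] for r in range(scenario.n_realms)}
    else:
        clades = _clade_tipsets(tree)
        out = {}
        for r in range(scenario.n_realms):
            got = pick_realm(clades, used)
            if got is None:
                return None
            out[r] = got
        return out


def plant_regions(
    tree: Phylogeny, scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[OccurrenceMatrix, PlantedTruth]:
    """Plant clade-biased regional occupancy on ``tree``.

    Each region's sites contain each tip of the region's focal clade and of
    the realm's core clade with ``p_focal`` and every other tip with
    ``p_background``; each cell then flips with ``noise_flip``. Sites that
    come out empty are resampled so every fixture is pipeline-valid.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    clades = _select_focal_clades(tree, scenario, rng)
    if clades is None:
        lo, hi = scenario.clade_size_bounds()
        raise FloregionError(
            f"infeasible scenario: could not find {scenario.n_regions} disjoint "
            f"focal clades of size {lo}..{hi} on a {tree.n_tips}-tip tree"
        )
    tips = np.asarray(tree.arrays().tip_labels)
    tip_index = {t: i for i, t in enumerate(tips)}
    n_sites = scenario.n_sites
    pres = np.zeros((n_sites, tips.size), dtype=bool)
    realm_of: dict = {}
    region_of: dict = {}
    focal: dict = {}
    width = len(str(n_sites))
    site_ids = [f"S{i + 1:0{width}d}" for i in range(n_sites)]
    cores: dict = {}
    s = 0
    for r in range(scenario.n_realms):
        realm_label = f"realm_{r + 1}"
        picks, core = clades[r]
        cores[realm_label] = frozenset(core)
        core_mask = np.zeros(tips.size, dtype=bool)
        core_mask[[tip_index[t] for t in core]] = True
        for g, clade in enumerate(picks):
            region_label = f"region_{r + 1}.{g + 1}"
            focal[region_label] = frozenset(clade)
            focal_mask = np.zeros(tips.size, dtype=bool)
            focal_mask[[tip_index[t] for t in clade]] = True
            pvec = np.full(tips.size, scenario.p_background)
            pvec[core_mask | focal_mask] = scenario.p_focal
            for _ in range(scenario.sites_per_region):
                site = site_ids[s]
                for _attempt in range(1000):
                    row = rng.random(tips.size) < pvec
                    if scenario.noise_flip > 0:
                        row ^= rng.random(tips.size) < scenario.noise_flip
                    if row.any():
                        break
                else:  # pragma: no cover - p_focal > 0 makes this unreachable
                    raise FloregionError("could not sample a nonempty site")
                pres[s] = row
                realm_of[site] = realm_label
                region_of[site] = region_label
                s += 1
    table = pd.DataFrame(pres.astype(np.int8), index=site_ids, columns=tips)
    # drop taxa that occur nowhere (background never sampled them)
    mat, _ = OccurrenceMatrix(table).drop_empty()
    return mat, PlantedTruth(
        realm_of=realm_of,
        region_of=region_of,
        focal_tips=focal,
        realm_core_tips=cores,
    )


def generate(
    scenario: SyntheticScenario, max_tree_retries: int = 20
) -> tuple[Phylogeny, OccurrenceMatrix, PlantedTruth]:
    """Simulate a tree and plant occupancy, resimulating the tree (with a
    seed derived from the scenario seed) if a draw lacks enough disjoint
    clades for the requested layout."""
    base = np.random.SeedSequence(scenario.seed)
    for attempt, child in enumerate(base.spawn(max_tree_retries)):
        rng = np.random.default_rng(child)
        tree = simulate_tree(scenario.n_tips, rng)
        try:
            mat, truth = plant_regions(tree, scenario, rng)
        except FloregionError:
            continue
        return tree, mat, truth
    raise FloregionError(
        f"scenario infeasible after {max_tree_retries} tree draws: {scenario}"
    )
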