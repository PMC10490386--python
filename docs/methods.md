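# Methods

## Turnover indices

All dissimilarities derive from a three-part decomposition of a site pair:
*a* the shared amount, *b* and *c* the amounts unique to each site. On taxon
counts these are set cardinalities; on branch lengths they come from rooted
phylogenetic diversity (PD). With P_i, P_j, P_u the PD of each site and of
their union,

    a = P_i + P_j − P_u,   b = P_u − P_j,   c = P_u − P_i,

which conserves a + b + c = P_u identically (asserted to 1e-9 relative in
tests). The indices are

    β_sim = min(b,c) / (a + min(b,c))        (Simpson / Sørensen turnover)
    β_jtu = 2·min(b,c) / (a + 2·min(b,c))    (Jaccard turnover)

β_jtu is a monotone transform of β_sim, so the two always rank site pairs
identically; both isolate replacement from richness difference (a nested
pair scores 0). A comparison where either community is empty is an error,
not a 0/1 convention: empty sites are filtered at I/O, so reaching one
signals a bug.

**PD anchoring.** PD is root-anchored by default: each tip's path runs to
the root of the dated tree, so deep shared history counts toward *a* and the
conservation identity above holds exactly. An MRCA-anchored variant
(`anchor="mrca"`, spanning subtree below the set's most recent common
ancestor) is exposed for exploration; the null model is defined on the
root-anchored form only. The root's own edge, when a Newick file carries
one, is excluded — it would add a constant to every PD.

**Computation.** The tree is indexed once into an edge × tip incidence
matrix; a site's PD is then a masked sum of edge lengths, and all pairwise
shared-branch amounts come from one matrix product. This makes the
999-permutation null a sequence of cheap column permutations of the
site × tip matrix (a tip-label shuffle and a taxon-column permutation are
the same operation), ~1 s for 40 sites × 400 tips × 999 permutations.

## Tip-shuffle null model and SES

The null permutes tip labels uniformly over all tips of the harmonized tree
(the regional pool; no within-clade constraint), preserving tree shape,
branch lengths, and every site's taxon list — taxonomic turnover is
invariant by construction (optionally asserted at run time). For each site
pair, SES = (observed − null mean) / null sd with the sample (n−1) standard
deviation of the permutation ensemble; the default ensemble size is 999.
Pairs with a degenerate null (sd = 0, e.g. any equal-branch star tree,
where every labelling gives the same turnover) get SES = NaN, are excluded
from site means, and are counted in the result. Per-site significance
applies |SES| > 1.96 to the site's mean SES against all other sites,
matching per-map-unit reporting. Under tree-independent occupancy the SES
distribution is approximately standard normal (checked: mean within ±0.15,
sd in 0.8–1.2, ~2–5% two-sided exceedance of 1.96 at 20 sites × 400 tips).

## Mantel tests

Pearson correlation of strictly-lower-triangle entries; significance from
999 simultaneous row/column permutations of the second matrix; one-sided
upper p = (1 + #{r_null ≥ r_obs}) / (1 + B) by default (the workflow's
correlations are directional), two-sided available. NaN pairs (degenerate
SES) are excluded from every correlation, observed and permuted alike.
Under independence the p-value is uniform (KS-checked in the test suite).

## Clustering and region delineation

The eight linkage variants follow R `hclust` naming. scipy provides the
Lance–Williams engine; two conventions are bridged explicitly:

* **ward.D** applies the Ward update to raw dissimilarities. scipy's `ward`
  runs the update on the squares of its input and reports square-rooted
  heights, so ward.D is computed as scipy-ward of √d with squared heights —
  an exact algebraic identity, verified against frozen R `hclust` output
  for all eight methods on a fixed 6-site matrix (1e-8).
* **UPGMC/WPGMC** heights are reported on the distance scale (scipy's
  geometric convention; R's centroid heights on squared input are the
  squares of ours). Centroid methods can produce inversions; these are
  flagged, never repaired.

Fit scores: CCC = Pearson r between input and cophenetic distances (NaN on
zero-variance input), GD = Σ(d − cophenetic)² over the lower triangle.
Method selection maximizes CCC, breaking ties by minimal GD and then by a
fixed ASCII-lexicographic method order; scores are rounded to 1e-10 before
comparison so floating-point dust cannot decide a genuine tie. On an
ultrametric input every graph-based linkage is an exact fixed point
(CCC = 1, GD = 0); the tie order places UPGMA first among them.

Dendrograms are cut by merge order (undoing the last k−1 merges), not by
height threshold: this is deterministic under tied heights and makes cuts
at different k exactly nested, so each region sits inside exactly one realm
(the 2-cut) by construction. k is chosen by maximal mean silhouette width
over k = 2 … min(15, n−1) (ties to smaller k); silhouette uses the standard
(b−a)/max(a,b) on the distance matrix with singletons scored 0. Geographic
contiguity against an optional adjacency list is a reported diagnostic
(connected components per region), never a constraint — geographic
coherence is a judgment call best left to the analyst, so the package
reports it rather than optimizing for it.

Regionalization clusters the pβ_sim matrix; β_sim clustering remains
available for the method-comparison table.

## NMDS

Kruskal stress-1 with primary treatment of ties: disparities come from an
isotonic regression of configuration distances on dissimilarity ranks,
tied blocks pre-sorted by configuration distance so ties impose no
constraint. Optimization is SMACOF (sklearn, metric=False) restarted from
100 starts; the first start is the principal-coordinates (classical MDS)
configuration — the usual warm start in ordination software, whose axes
nest across dimensionalities, which also keeps best-of-starts stress
monotone in the embedding dimension — the rest are seeded random
configurations. The lowest-stress solution is kept; coordinates are
centered, rotated to principal axes, and sign-fixed (largest-magnitude
coordinate positive per axis), all stress-invariant, so a fixed seed gives
bit-identical output.

## Synthetic floras

`simulate_tree` draws a pure-birth (Yule, rate 1) tree: from two lineages,
exponential waiting times with rate equal to the lineage count separate
successive bifurcations of a uniformly chosen lineage; one further waiting
time elapses after the n-th tip appears, so the expected depth is
Σ_{k=2}^{n} 1/k (Monte-Carlo-checked against this closed form). Pure birth
rather than a coalescent because only relative branch lengths matter to
pβ_sim and the ultrametric depth has a closed form to test against.

`plant_regions` plants clade-biased affinity at two hierarchical depths:

* **regions** — each region is assigned a focal clade (disjoint across the
  scenario; size bounds derived from n_tips: [n/(4·R), n/R] for R regions
  total) whose tips occur in the region's sites with `p_focal`;
* **realms** — each realm is additionally assigned a smaller core clade
  (bounds half/one-third of the region bounds) present at `p_focal` in all
  the realm's sites. A shared realm flora is what carries realm-level
  turnover signal in real data; two disjoint focal clades share almost no
  rooted-path length whether or not they sit in the same deep subtree, so
  without the core tier the realm level would be undetectable by design.
* everything else occurs at `p_background`, and each cell then flips with
  probability `noise_flip`.

With `realm_depth_bias` (default 1) each realm's clades are confined to a
distinct deep subtree — a child subtree of one of the two root children,
spread across the two sides — creating the deep two-way split the realm
level represents. Sites that come out empty are resampled; a tree draw
lacking enough disjoint clades triggers a fresh simulation (bounded
retries) so fixtures are always pipeline-valid.

Defaults (2 realms × 2 regions × 10 sites, 400 tips, p_focal 0.9,
p_background 0.05, noise_flip 0.01) give within-region β_sim ≈ 0.3,
between-region ≈ 0.7, between-realm ≈ 0.9 — levels comparable to county
floras — and are recovered by the pipeline (ARI = 1, exact realms) in 20/20
seeds checked.

**What the generator does not emulate:** spatial autocorrelation and
dispersal limitation within regions, richness gradients, abundance,
sampling effort differences, and taxonomic error. Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability of
clean hierarchical signal, not performance on noisy field data.

## Determinism and problem sizes

Every random stage (simulation, tip shuffles, Mantel permutations, NMDS
starts) consumes an independent substream derived from the master seed via
`SeedSequence([seed, stage_code])`, so changing one stage's seed leaves the
others bit-identical; pipeline summaries contain no timestamps and rerun
byte-identically. Test-suite problem sizes are chosen to exercise each
property at the smallest scale where it is unambiguous (e.g. 400-tip trees
for calibration, 14-site matrices for clustering fixed points); the full
pipeline at default size runs in well under a minute on one CPU.

## Known limitations

* Nestedness components and abundance-weighted dissimilarities are out of
  scope; only the turnover components are implemented.
* The MRCA-anchored PD variant is exploratory; SES is defined on the
  root-anchored form.
* Contiguity reporting needs a user-supplied adjacency list; no geometry is
  inferred.
* NMDS stress depends on the start ensemble; with few starts on hard
  matrices the reported minimum can exceed the global one (the PCoA warm
  start mitigates this).
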