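# Methods

## Diversity partition

All statistics are defined over pairs drawn from site-by-species count
data `x_si` and a species distance matrix `delta_ij` (patristic distance,
Myr; on an ultrametric tree `delta_ij = 2 ×` divergence time).  Sites are
pooled into groups (each site its own transect, or sites merged by
habitat label).  Within-group quantities average over groups with equal
weight; between-group quantities average over all unordered group pairs
with equal weight, so large groups do not dominate the coefficients —
the same convention as differentiation coefficients in population
genetics.

Two pair semantics are provided.  The default `pairs` mode draws two
*distinct* individuals without replacement within a group, matching the
verbal definition "probability that two individuals belong to different
species" over real pairs and making every quantity reproducible by
exhaustive enumeration (the test suite's oracle).  `frequency` mode draws
with replacement (`D_I = 1 − Σ f²` etc.); it has the exact property that
two groups of identical composition give zero differentiation, which the
`pairs` mode only approaches as group sizes grow.  Between-group
quantities are identical in the two modes.

Per group (pairs mode), with `n = Σ_i x_i`:

* `D_I = 1 − Σ_i x_i(x_i−1) / (n(n−1))`
* `D_P = x' delta x / (n(n−1))` (conspecific pairs contribute 0)
* `D_B = x' delta x / (n² − Σ_i x_i²)` (non-conspecific pairs only)
* `Delta = a' delta a / (s(s−1))` with incidence vector `a` and richness
  `s` — comparisons of a species with itself are excluded.

The conditional-mean identity `D_P = D_I · D_B` holds exactly in both
modes and is asserted in tests.  Coefficients are assembled as
`(total − within) / total`.  Degenerate cases: a monospecific group has no
non-conspecific pair, so its `D_B`/`Delta` is flagged not-a-value with a
warning and excluded from the within average rather than imputed as 0
(imputing 0 would fabricate clustering signal); equal within and total
inputs give a coefficient of exactly 0 — the code never nudges a
coefficient away from 0 to match a rounded external table.  Reports round
to 4 decimals; internal computation is full precision.

`APD = 1 − weighted/unweighted`, where *weighted* is
`Σ_{i≠j} p_i p_j delta_ij / Σ_{i≠j} p_i p_j` with regional relative
abundances `p_i`, and *unweighted* is the mean `delta` over distinct
species present in the pool.  Positive APD means abundant species are
phylogenetically clustered.

## Null models and tests

* `1-3x`: individuals reshuffled among sites within each stratum
  (habitat), conserving site sizes and per-stratum species totals; a
  single-site stratum is a fixed block.  Individuals are materialized as
  an explicit label list — unambiguous and cheap at inventory scales
  (~10^4 individuals).  Individual-level shuffling is implemented; a
  species-level variant of the same scheme is not.
* `2-3x`: individuals reshuffled over the whole dataset, conserving group
  totals and species grand totals (realized by a single pooled shuffle
  split by site sizes, which conserves site sizes too).
* `1s`: a uniform random bijection of species onto tip positions —
  equivalently a simultaneous row/column permutation of `delta`; the
  community matrix is untouched, so `I_ST` is exactly invariant.

Statistic/model pairings are enforced: community-randomizing models
destroy the species turnover that `B_ST`/`Pi_ST` are constructed to be
independent of, biasing them, and tip shuffles cannot test `I_ST` at all.
P-values use the add-one rule `p = (1+b)/(R+1)` with ties counted as
extreme, so the smallest attainable p at the default `R = 999` is 0.001;
one-sided and two-sided (distance from the null median) p-values are both
reported.  All randomness flows from one seed, recorded in every report.

The Mantel test correlates lower-triangle entries (Pearson by default,
Spearman optional) and permutes rows/columns of the first matrix; it is
implemented in the package so permutations are seeded, and is cross-checked
against scikit-bio's implementation in a unit test.  Lat/long coordinates
are projected onto a local equirectangular plane, accurate to well under
1% at sub-200-km extents in the tropics.

## Tree construction

`bladj_adjust` dates a rooted topology from node-age constraints: the
root must be constrained, tips are pinned at age 0, and each unconstrained
node is assigned by even interpolation along the chain from its nearest
dated ancestor to the *oldest* dated node or tip reachable through it
(ties: fewest intervening undated nodes, then label).  Anchoring on the
oldest dated descendant is the design choice where the published
branch-adjustment procedure is underspecified: it is deterministic,
reproduces the even-spacing intent, and provably never assigns a node an
age below a constraint deeper in its subtree, so the output is always
ultrametric with non-negative branch lengths and re-dating with the full
set of assigned ages is a fixed point.

`graft_taxa` attaches species under their genus node when the backbone
has one (a genus tip is first promoted to an internal node), otherwise
under their family node, expanding polytomies; species with neither are
an error, never silently attached at the root.  By default new terminal
branches extend to the present (length = attachment-node age), which
preserves ultrametricity; `zero_terminal=True` attaches at distance 0
instead, honoring the alternative reading that intra-generic branch
lengths are zero.  Polytomies are first-class everywhere; nothing is
randomly resolved.  The default ultrametricity tolerance is a relative
1e-6 of the root age.

## Synthetic communities

The generator emulates a transect inventory of a wet tropical forest:
9 sites over a ~100 km extent, 5 habitat types holding 74/8/4/11/3 % of
individuals, ~370 species on a Yule tree with a 180-Myr root, ~1200
individuals per site, log-normal regional abundances (σ = 1) giving
within-site Simpson diversity ≈ 0.98.  Mechanisms, all acting
multiplicatively on per-site sampling weights before a multinomial draw:

* **Dispersal limitation** — Gaussian kernel (default scale 25 km at
  study scale) around a random center per species; phylogeny-blind.
* **Habitat filtering** — the tree is split into as many major clades as
  habitats (largest clade opened repeatedly), clades preferring habitats;
  a species' weight off its preferred habitat is multiplied by `1 − φ`.
* **Competitive exclusion** — species are clustered by single linkage at
  an exclusion depth (default 75 Myr of divergence); per site one cluster
  member keeps full weight and the rest are multiplied by `1 − penalty`.
  At `penalty = 1` no two members of a cluster co-occur in a site.

The `small` scale used in calibration and power experiments (10 sites,
3 habitats at 40/30/30 %, 60 species, 150 individuals per site, 15 km
dispersal, abundance σ = 0.5) keeps each experiment to seconds while
leaving every signature detectable; scenario strengths are fixed in
`scenario_config` (`filtering: φ = 0.8`, `overdispersion: penalty = 1`
with a flat kernel, `mixed: φ = 0.4, penalty = 1` — strengths at which each
mechanism alone produces a detectable habitat-level `B_ST` signal but the
two together usually cancel).  What the generator
does **not** emulate: speciation/drift dynamics, within-transect spatial
structure, intraspecific aggregation beyond the multinomial, observation
error in identification, or imbalanced real phylogenies with calibrated
node ages — so passing power checks demonstrate the statistical machinery
under the stated mechanisms, not field performance on any particular
forest.

## Problem sizes and numerics

The acceptance script and test suite run the oracle comparison on 100
random instances (≤ 6 sites, ≤ 10 species, ≤ 200 individuals; agreement
to 1e-12 relative), test calibration on 200 self-generated null datasets
with 199 permutations each, and scenario-signature recovery on 100
replicates per scenario at the `small` scale — sizes chosen so the whole
suite completes in minutes on one core while Monte-Carlo error stays well
inside the asserted bounds.  Ties in permutation tests count as extreme;
NaN propagates (never silently replaced); distance matrices are validated
for symmetry and a zero diagonal on construction.

## Known limitations

* Pairwise differentiation matrices fed to the Mantel test are not
  independent entries; the Mantel permutation accounts for the row/column
  structure but the usual caveats about Mantel power apply.
* `per_clade_test` defaults to `frequency` mode so that sites holding a
  single clade individual need not be dropped; small clades have coarse
  permutation distributions (a 4-tip clade cannot reach p < ~0.04 under
  tip shuffling).
* The two-sided permutation p-value is defined by distance from the null
  median; other centerings are defensible.
* `2-3x` reshuffles individuals; abundance-clumped species make it
  liberal in principle for strongly aggregated data (a known property of
  individual-based reshuffles), which is why phylogenetic statistics are
  restricted to `1s`.
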