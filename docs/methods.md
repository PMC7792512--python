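# Methods

## The data model

Everything starts from an `AbundanceMatrix`: integer counts of
individuals per site × species, pooled over sampling rounds, with exactly
one habitat label per site. Validation rejects negative or fractional
counts, duplicate labels, missing habitat labels, and empty rows or
columns (an all-zero site has no defined evenness and would sit isolated
in every network; inputs may opt into dropping such rows with
`drop_empty=True`, which warns). Binary 0/1 matrices are accepted with a
warning, since the abundance-weighted metrics degenerate on incidence
data.

## Diversity indices

* **Richness** *S*: number of species with count > 0 at a site.
* **Evenness** *E*<sub>var</sub> = 1 − (2/π)·arctan(Var[ln *n*<sub>s</sub>]),
  the Smith–Wilson index over the *S* observed species. The population
  variance (divide by *S*) is the default, matching common
  community-ecology software; the sample-variance form is available via
  `ddof=1`. A single observed species gives variance 0, hence
  *E*<sub>var</sub> = 1. Zero counts never enter (ln 0 undefined).
  *E*<sub>var</sub> is invariant to rescaling all abundances.

## Bipartite architecture metrics

**Connectance** is the realized fraction of patch × species cells that
are nonzero.

**Weighted NODF** measures nestedness of the quantitative matrix on a
0–100 scale. Rows and columns are sorted decreasingly; an ordered pair
(upper *i*, lower *j*) contributes
100·#{k : 0 < w<sub>jk</sub> < w<sub>ik</sub>}/fill<sub>j</sub> if *j*
ranks strictly below *i*, else 0 (ties contribute nothing); the index is
the mean over all row pairs plus column pairs. Two ranking conventions
exist in the literature's implementations and they disagree off nested
matrices: ranking by **marginal totals** (the metric's published
definition; our default) and ranking by **fill** with totals as
tie-break, which is what the widely used R implementation
(`vegan::nestednodf(weighted=TRUE)`, called by the `bipartite` package)
does. Both are exposed via `variant=("totals"|"fill")`; the fill variant
is cross-checked against vegan in the test suite. On strictly nested,
strictly decreasing matrices both give 100; on checkerboards both give 0.

**Barber modularity** of a joint partition *g* of patches and species is

  Q = (1/W) Σ<sub>i,s</sub> (w<sub>is</sub> − s<sub>i</sub>t<sub>s</sub>/W) δ(g<sub>i</sub>, g<sub>s</sub>),

with row strengths *s*<sub>i</sub>, column strengths *t*<sub>s</sub> and
grand total *W*. The search (`optimize_modularity`) is a weighted label
propagation: starting from singleton row modules and random column
labels, rows and columns alternately adopt the module maximizing their
contribution; converged labelings are then agglomerated by greedy module
merging while ΔQ > 0, and propagation is re-run. The best of
`n_restarts` (default 20) random restarts is kept; the whole search is
deterministic given its seed. A single-module fallback guarantees
Q ≥ 0. On block-diagonal matrices the optimum never merges blocks (cross
terms only subtract), but note that *weighted* modularity may legitimately
**refine** a block with heterogeneous weights into several modules — the
planted module count is a lower bound, not an exact target.

**Robustness** removes species from the network in increasing order of
total abundance (ties broken by species label for determinism); a patch
is lost once its remaining species set is empty. *R* is the trapezoidal
area under the survival curve y(x) including the endpoints (0, 1) and
(1, 0). Patch loss is presence-based: the choice of when a patch counts
as lost (empty species set) is the simplest defensible rule; an
abundance-threshold rule would need a parameter the data do not
determine.

## Patefield null models and z-scores

Null matrices are drawn uniformly from the integer matrices with exactly
the observed row and column totals (Patefield's algorithm, via
`scipy.stats.random_table`; matrices with a single row or column are
fully determined by their margins and are returned as-is, working around
a scipy defect there). z = (observed − null mean)/null sd with the
population sd over replicates; sd = 0 is flagged degenerate rather than
producing an infinite z. The default is 1,000 replicates. For the
modularity z each replicate needs its own search; `null_restarts`
(default 5) controls that per-replicate effort.

A property worth knowing before interpreting modularity z-scores:
Patefield redistribution of individuals produces much denser, more even
matrices than ecological data, whose occupancy is sparse and whose
abundances are right-skewed. A sparse skewed matrix therefore scores far
above its nulls *even with no habitat structure at all* (we measure mean
z ≈ +34 on structureless simulated matrices). The z-score consequently
mixes "has modules" with "is sparse and skewed"; as planted structure is
diluted the optimized Q and the excess Q − null-mean fall monotonically,
but z itself need not, because the null sd shrinks with increasing fill.
When comparing landscapes, prefer the excess (or Q itself) as the
effect-size measure and treat z only as a significance indicator.

## Unipartite patch analyses

The projection links two patches iff they share at least one species;
the edge weight is the count of shared species (presence-based).
**Opsahl centrality** C<sub>i</sub>(α) = k<sub>i</sub><sup>1−α</sup>s<sub>i</sub><sup>α</sup>
blends degree and strength; α = 0.5 (the pipeline default) weighs the
number of connections and their total weight equally. Isolated nodes get
C = 0; ranking uses average ranks on ties.

**Community detection** wraps igraph's multilevel (Louvain), walktrap
(4-step random walks, cut at maximal modularity) and spinglass
(25 spins, γ = 1; requires a connected graph) algorithms, all on edge
weights, each seeded for determinism and reported with the
Newman–Girvan weighted modularity of its partition (evaluated by our own
direct implementation of the formula and cross-checked against igraph's
in the tests). The **mixing parameter** µ is the average over
non-isolated nodes of the fraction of their links leaving their
community, computed both by edge count and by edge weight — the
definition is not standardized, so both are reported side by side.
Partition agreement uses the adjusted Rand index.

## Habitat-effect statistics

OLS with treatment coding against a reference habitat (default: the
habitat with most sites), so the intercept is the reference mean and
each coefficient a difference of habitat means with a two-sided t-test.
Tukey's HSD runs on the pooled error variance; the compact letter
display assigns letters to the maximal cliques of the
"not-significantly-different" graph, ordered by decreasing group mean,
so groups sharing no letter differ at the chosen level. Pearson
correlations come with the usual t-test p-value.

## Synthetic landscapes

`generate_landscape` emulates a heterogeneous protected-area survey:

| parameter | default | meaning |
|---|---|---|
| habitats / sites | 5 types, (10, 10, 10, 7, 7) | 44 patches, mirroring a realistic mixed design |
| species roles | 8 specialists × 5 habitats + 34 generalists | 74 species |
| p_in | 0.7 | specialist occupancy inside its habitat |
| p_out | 0.08 | specialist occupancy elsewhere |
| p_gen | 0.35 | generalist occupancy everywhere |
| abundance | ⌈log-normal(µ=1.0, σ=1.2)⌉ | right-skewed counts ≥ 1 |

The occupancy probabilities give an expected fill ≈ 0.28 and the
log-normal tail makes site totals span two orders of magnitude, matching
the shape of real butterfly survey matrices. Sites (or species) that
come out empty are re-drawn and recorded in the `PlantedTruth` side-car,
so downstream invariants always hold. `generate_nested` builds strictly
nested, strictly decreasing matrices (weighted NODF = 100) for
exercising the nestedness code.

What the generator does **not** emulate: spatial autocorrelation between
patches, temporal (per-round) structure, detection error, and
species-abundance correlations beyond the specialist/generalist split.
Passing recovery tests therefore shows the pipeline recovers planted
compositional structure, not that it is robust to spatial confounding —
a caveat that applies equally to these methods on real data.

## Problem sizes and numerical choices

The validation suite runs recovery sweeps on 12-site × 18-species
landscapes (5 p_out grid points × 20 replicates; 15 modularity nulls per
replicate with 3 restarts), which keeps the full suite under a minute
while leaving the monotone trends (ARI falls, µ rises, modularity excess
falls) unambiguous. The acceptance script analyses the full 44 × 74
default landscape with 1,000 nulls for both z-scores. Tolerances: label
propagation stops on ΔQ ≤ 1e−12; Tukey letters use α = 0.05; E_var and
NODF comparisons in tests are exact to 1e−9 against independent
re-derivations.

## Known limitations

* The modularity search is a stochastic heuristic; Q is reproducible
  given a seed but only best-of-restarts, so a small optimality gap is
  possible on large matrices (hence comparisons against it use a ±0.02
  band).
* The modularity z-score conflates structure with sparsity/skew (see
  above); the excess Q − null-mean is reported alongside it by the
  pipeline for that reason.
* Analyses are not spatially explicit: habitat similarity and spatial
  proximity effects cannot be disentangled from the matrix alone.
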