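# habnet — species–habitat network analysis

`habnet` analyses **species–habitat networks**: bipartite graphs linking
species to the habitat patches where they occur, weighted by abundance.
It is aimed at conservation ecologists who survey a mosaic of habitat
patches (grassland successional stages, meadows, wetlands, …) and want to
go beyond per-patch diversity rankings to ask how the patches jointly
support the species pool — which patches are central hubs for generalists,
which form modules of specialists, and how stable the whole system is to
species loss.

Starting from a single site × species integer abundance matrix with one
habitat label per site, the pipeline computes:

* **Diversity** — per-site richness *S* and Smith–Wilson evenness
  *E*<sub>var</sub> = 1 − (2/π)·arctan(Var[ln *n*<sub>s</sub>]).
* **Bipartite architecture** — connectance *C*; weighted NODF nestedness
  (0–100); Barber bipartite modularity
  *Q* = (1/*W*) Σ<sub>i,s</sub> (*w*<sub>is</sub> − *s*<sub>i</sub>*t*<sub>s</sub>/*W*) δ(*g*<sub>i</sub>, *g*<sub>s</sub>),
  maximized by weighted label propagation with agglomerative refinement;
  robustness *R* (area under the patch-survival curve as species are
  removed rarest-first). Nestedness and modularity come with z-scores
  against **Patefield** fixed-margin null matrices.
* **Patch projection** — the unipartite patch network (edge weight =
  number of shared species), Opsahl weighted degree centrality
  *C*<sub>i</sub>(α) = *k*<sub>i</sub><sup>1−α</sup>·*s*<sub>i</sub><sup>α</sup>,
  community detection (multilevel/Louvain, walktrap, spinglass) and the
  mixing parameter µ.
* **Habitat effects** — OLS of each index on habitat type with treatment
  coding, Tukey HSD compact letter displays, and Pearson correlations
  between centrality and diversity.
* **Synthetic landscapes** — a generator with planted habitat modules,
  specialist/generalist species roles and skewed abundances, so the whole
  pipeline can be validated against known ground truth.

## Worked example

Generate a study-shaped landscape (44 patches in five habitat types,
74 species) and analyse it:

```sh
habnet simulate --seed 1 --out landscape.csv
habnet analyze landscape.csv --nulls 1000 --seed 1 --out results/
```

or, in Python:

```python
import habnet as hn

mat, truth = hn.generate_landscape(hn.LandscapeSpec(), seed=1)
net = hn.build_bipartite(mat)
print(f"connectance  {hn.connectance(net):.3f}")
print(f"wNODF        {hn.weighted_nodf(net):.2f}")
part = hn.optimize_modularity(net, seed=0, n_restarts=20)
print(f"modularity Q {part.quality:.3f}  ({part.n_communities} modules)")
curve, R = hn.robustness(net)
print(f"robustness   {R:.3f}")
```

prints

```
connectance  0.277
wNODF        15.00
modularity Q 0.436  (9 modules)
robustness   0.964
```

Read: about 28 % of the possible patch–species links are realized; the
network is weakly nested; the optimized bipartite partition has a clear
modular signal (compare it to its Patefield-null z-score before
interpreting); and the patch set is highly robust — losing the rarest
species rarely empties a patch, because most patches also host common
generalists. Downstream, `hn.project_unipartite` +
`hn.weighted_degree_centrality` rank patches (on this landscape mean
centrality is 104.3 and correlates with richness at Pearson r = 0.95),
and `hn.detect_communities` clusters patches by shared species.

The matrix CSV dialect is: header row, first column `site`, second column
`habitat`, then one integer column per species (`hn.read_abundance_matrix`
/ `hn.write_abundance_matrix`).

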