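# paleorange

**Ancestral-range inference with fossils: how much do extinct taxa change
what we infer about where clades originated?**

Most historical-biogeography studies reconstruct ancestral areas from the
phylogeny and ranges of living species only. When lineages have dispersed
repeatedly or gone regionally extinct, that inference can be confidently
wrong — the fossil record holds the missing signal, but fossil sampling is
itself biased in space and time. `paleorange` is a toolkit for quantifying
this trade-off on continent-scale data (South America, North America,
Eurasia, Africa, arranged on a dispersal chain SA–NA–EU–AF):

* a **DEC / DEC+J likelihood engine** (dispersal–extinction–cladogenesis,
  optionally with founder-event "jump" speciation) that treats fossils as
  dated tips, with maximum-likelihood fitting and marginal ancestral-range
  reconstruction;
* a **forward simulator** of a four-area geographic state-dependent
  speciation–extinction (GeoSSE-equivalent ClaSSE) process that retains
  extinct lineages, true node ranges and a full event log;
* **ABC rejection** over five tree summaries (tree length, root height,
  extant fraction, widespread extant species, split sister pairs) to select
  simulated trees that resemble a target, ranked by the largest absolute
  log error ALE = |ln(r_target / r_sim)|;
* **biased fossil subsampling** under a Poisson preservation model with
  per-(time bin × continent) rates, calibrated so a chosen fraction of
  extinct species is "known", plus random subsampling;
* **accuracy evaluation**: each clade of a reduced tree is matched to the
  smallest containing clade of a reference tree, and scored per continent
  as `accuracy = 1 − |P_ref(continent in range) − P_est(continent in range)|`,
  with total accuracy the product over the four continents; summaries are
  per-tree age-quantile means with cross-tree 95% HPD intervals;
* **predictability analysis**: per-tree Spearman correlations of accuracy
  with node age and with *sampling similarity* (the Fisher-exact p-value
  comparing per-continent species counts among extant vs. all species of a
  clade), compared by a paired t-test.

## Worked example

```python
from paleorange import AncestralRangeModel, SimParams, simulate_tree

params = SimParams(mu=0.2, delta=0.1, lambda1=0.3, lambda2=0.05, lambda3=0.5)
res = simulate_tree(params, n_extant_target=50, seed=42)
print(f"{res.tree.n_tips} tips ({len(res.extinct_tips())} extinct), "
      f"root age {res.tree.root_age:.2f} Ma")

model = AncestralRangeModel(res.tree, model="DEC+J")
fit = model.fit(n_restarts=3, seed=0)
print(fit.summary())
```

prints

```
74 tips (24 extinct), root age 9.60 Ma
Ancestral range model results
==============================================
Model:            DEC+J
No. tips:         74  (fossil: 24)
Log-likelihood:   -97.6825
AIC:              201.3651
Converged:        True  (3 restarts)
----------------------------------------------
param         estimate    unit
d             0.037273    expansions /pair /Ma
e             0.000000    area losses /Ma
j             0.193401    jump weight
```

`d` is the rate at which a range expands into an adjacent continent, `e`
the rate at which an occupied continent is lost, and `j` the relative
weight of jump-dispersal speciation at nodes. The fitted results object
then yields per-node marginal ancestral ranges:

```python
prof = fit.ancestral_marginals()
root = max(range(len(prof.clades)), key=lambda i: len(prof.clades[i]))
print({a: float(p) for a, p in zip(prof.space.areas, prof.inclusion[root].round(3))})
print(sorted(res.tree.root.range_))   # simulation truth
```

```
{'SA': 0.949, 'NA': 0.361, 'EU': 0.17, 'AF': 0.0}
['NA', 'SA']
```

With the 24 fossil tips in the tree, the inferred root range puts South
America in the ancestral area with probability 0.95 (North America is the
next most supported) — the simulation truth is {SA, NA}. Prune the fossils away (`paleorange.prune_to(res.tree, set())`)
and refit to see how the same question degrades on extant data alone; the
pipeline module automates that comparison across sampling scenarios.

A command-line interface wraps the same functions:

```sh
paleorange simulate --from-priors --n-extant 100 --seed 1 --out tree.nwk
paleorange fit --tree tree.nwk --geography ranges.txt --model DEC+J
paleorange run-study --seed 1 --out study_results/
```

Input formats: Newick with branch lengths in Ma (tips with shorter
root-to-tip paths are treated as fossils; an explicit tip-age TSV can
override), and a Lagrange/PHYLIP-style binary geography table
(`n_species n_areas (SA NA EU AF)` header, then `name 0110` rows).

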