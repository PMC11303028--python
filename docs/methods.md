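# Methods

This note documents the models implemented in `paleorange`, the
conventions and numerical choices behind them, and what the synthetic-data
experiments can and cannot show.

## The range-evolution model (DEC / DEC+J)

Ranges are non-empty subsets of the four continents SA, NA, EU, AF, which
sit on a dispersal chain (SA–NA, NA–EU, EU–AF adjacent; all other pairs
non-adjacent, with zero dispersal between them). For reconstruction the
state space contains all ranges of up to **three** continents — 14
observable states — plus one internal *null* state; tips may occupy any
observable state.

**Anagenetic process** (along branches): a continuous-time Markov chain in
which a range `R` expands into an adjacent area `a` at rate
`d × |{b ∈ R : b adjacent to a}|` and loses any occupied area at rate `e`
per area. A singleton range contracts into the null state at rate `e`;
null is absorbing, carries no tips, no root prior mass and no
cladogenetic events — it is pure bookkeeping for whole-range extinction
along a branch.

**Cladogenetic process** (at nodes): given ancestral range `S`, the
daughter-range pair is drawn from a weighted event set —

| event | condition | daughters | weight |
|---|---|---|---|
| narrow sympatry | `|S| = 1` | (S, S) | 1 |
| subset sympatry | `|S| ≥ 2` | ({a}, S) and (S, {a}) for each a ∈ S | 1 each |
| vicariance | `|S| ≥ 2` | every ordered split (A, S∖A) with a singleton part | 1 each |
| jump dispersal | any S | (S, {a}) and ({a}, S) for each area a adjacent to S but outside it | j each |

normalized to a probability distribution per ancestral state. DEC is the
`j = 0` submodel. This weighting is deliberately simple and symmetric in
daughter order; other software renormalizes jump weights differently, so
exact numerical agreement with any particular implementation is not a
goal — correctness is anchored in the `j = 0` limit and in exhaustive
enumeration oracles (see the test suite).

**Likelihood.** Felsenstein pruning over the 15-state space with
cladogenetic mixing at internal nodes. Fossils need no special machinery:
a tip observed at age `t > 0` terminates its branch early and contributes
an indicator vector at its observed range. Branch transition matrices
`exp(Q·t)` come from one eigendecomposition of the dense 15×15 generator
per likelihood evaluation (two small matrix products per branch), with a
fallback to scaled-and-squared `expm` whenever the eigenvector
reconstruction is poorly conditioned (row-sum error > 1e-8). Partial
likelihoods are rescaled at every node to avoid underflow. The root prior
is uniform over the 14 observable states, with no conditioning on
survival; both choices are exposed as options because the literature is
not uniform on either.

**Marginal ancestral ranges.** A down-pass (pruning) and an up-pass that
conditions each node on all data outside its subtree give exact marginal
posteriors per internal node; on trees of ≤ 4 tips these match brute-force
enumeration over all joint internal-state assignments to < 1e-8. Two
per-continent summaries are derived: *inclusion* P(continent ∈ ancestral
range), the quantity used in all accuracy calculations, and *split*, which
divides widespread mass equally among member continents (the convention
for plotting one number per continent).

**Fitting.** `AncestralRangeModel.fit()` runs bounded L-BFGS-B from
multiple deterministic random starts (default 5; bounds d, e ∈ [1e-8, 5],
j ∈ [0, 3], all per Ma). The result is flagged unconverged if no restart
reports success, rather than failing silently. Simulation-recovery tests
show d and e recovered within a factor of two on 200-tip trees in ≥ 90% of
replicates for the purely anagenetic submodel.

## The synthetic-data generator

The simulator is a four-area GeoSSE-equivalent ClaSSE process run with the
Gillespie algorithm from one endemic ancestor on a uniformly drawn
continent. Five rates, uniform across continents:

* `mu` — extinction of an endemic lineage / contraction of a widespread
  one, per occupied continent (/Ma);
* `delta` — range expansion per adjacent continent (/Ma), endemics only
  (simulated ranges are capped at two adjacent continents, mirroring the
  asymmetry that reconstruction allows three);
* `lambda1` — sympatric speciation per occupied continent; a widespread
  ancestor leaves one daughter endemic to the triggering continent and one
  retaining the full range (the GeoSSE convention);
* `lambda2` — jump-dispersal speciation per adjacent unoccupied continent
  (allowed from widespread ranges too; config-toggleable);
* `lambda3` — allopatric speciation of a widespread lineage into its two
  endemic parts.

The run stops the instant the living-lineage count first reaches the
target; runs that go globally extinct first are rejected and retried (this
is a simple first-passage stopping rule, not a full generalized sampling
approach). Extinct lineages are kept as dated tips with their range and
continent at extinction; true ranges are recorded at every internal node;
the event log carries per-event-class *exposures* (lineage-time weighted
by the number of opportunities for that event class) so realized rates can
be checked against nominal ones. Rate-recovery checks pool over **all**
runs, rejected ones included, because conditioning on survival biases the
realized extinction rate downward. In prior-sampling mode the five rates
are drawn from `mu, delta, lambda1 ~ U(0,1)`, `lambda2 ~ U(0,0.25)`,
`lambda3 ~ U(0,3)`.

What the generator does **not** emulate: time-varying or
diversity-dependent rates (real intercontinental dispersal was likely
faster in the Pleistocene than earlier), continent-specific rates,
within-continent geography, and phylogenetic error — simulated trees are
known without error. Passing tests therefore demonstrate the internal
consistency of the inference chain under the model's own assumptions, not
robustness to the many ways real data violate them.

## ABC selection of plausible trees

Candidate trees are simulated from prior draws and compared with a target
on five summaries: total tree length (extinct subtrees included), root
height, fraction of species extant, number of extant species on two
continents, and the fraction of cherries (mutual sister tips) whose
members are single-continent endemics on different continents — extinct
cherry members scored by the continent they last occupied. Each summary
contributes an absolute log error `ALE = |ln(target/candidate)|`;
candidates are ranked by the largest of the five (ALE_max) and the best k
kept, ties broken by candidate index. Count-valued summaries at zero get a
+0.5 continuity offset on both sides before the log. The "sister pairs"
denominator is cherries of any kind (extinct–extant included); the
alternative readings are countable but this is the strict one. Candidate
simulations run under an event cap and bounded retries; prior draws whose
simulations exhaust the caps (very high turnover) are retained as failed
candidates with infinite ALE_max rather than silently resampled. The
package default of 10⁴ candidates / keep 20 is a desk-scale working
default; production-scale selection is the same code with a larger
candidate count.

## Fossil preservation and subsampling

Preservation is a Poisson process with piecewise-constant rates per
(time-bin × continent) stratum (/lineage/Ma). A species alive over
segments with ranges `R(t)` accumulates intensity
`I = Σ_segments Σ_{c ∈ R} q(bin, c)/|R| × duration` — a widespread species
splits its preservation potential equally across occupied continents — and
is *known* with probability `1 − exp(−f·I)`. "Fraction of fossils known"
is therefore a species-level quantity (detected at least once), which is
the only reading consistent with the subsequent species-level inclusion
step. The global multiplier `f` is calibrated by Brent root-finding on the
monotone map `f ↦ mean detection probability` to hit a target known
fraction (expected fraction by default; the realized Bernoulli fraction is
what the tests check, to ±0.02). The built-in biased model
(`PreservationModel.synthetic_biased`) makes recent strata and North
America the best-sampled (time-bin thirds of the root age weighted 2/1/0.5
from young to old; continents weighted SA 0.5, NA 2.0, EU 1.0, AF 0.7 on a
base 0.1 /lineage/Ma) — a deliberately stylized stand-in for the
qualitative structure of the mammal record, not an empirical rate table.

Given a known set, the *included* set is a uniform subset sized as a
fraction of **all** extinct species (so 25% included of 25% known means
everything known is included); random sampling without preservation bias
is the homogeneous special case. `prune_to` then rebuilds the reduced
tree: all extant tips, the included extinct tips, unary nodes suppressed
with branch lengths summed — path lengths and divergence times among
retained tips are bit-for-bit preserved.

## Accuracy and its predictors

Every internal node (clade) of a reduced tree is matched to the MRCA of
its retained tip set in the reference tree — the smallest reference clade
containing the same species, which may subtend additional extinct ones.
Accuracy per continent is `1 − |P_ref − P_est|` on the inclusion
probabilities; total accuracy is the product over the four continents. The
formula is symmetric in its arguments; the asymmetry is only in which tree
serves as reference. Two reference modes exist: *truth* (simulation truth:
inclusion 1 for member continents, else 0) and *inferred* (the full-tree
inference — which measures the difference fossils make, not accuracy
against an unknown ground truth). When a scenario includes every fossil,
the reduced tree is the full tree and the reference fit is reused, making
the self-comparison identity exact. Records are binned by node age —
per-tree age quantiles by default, since simulated root ages differ;
absolute edges are available for common-scale data — and summarized across
trees by the mean of per-tree bin means with a 95% HPD computed as the
shortest interval containing 95% of the per-tree means. Node ages are
taken from the matched reference node so bins are comparable across
scenarios. Empty bins are reported missing, never zero.

*Sampling similarity* of a clade is the two-sided Fisher exact p-value for
the 2×4 table of per-continent species counts, extant row vs. all-species
row (extinct species scored by their range at extinction; a species counts
once per occupied continent). The rows are the quantity of interest as
defined, although they are not independent samples (the extant species are
a subset of all species); the p-value is used as a similarity score, not
as a calibrated test. Zero columns are dropped; exact enumeration of all
2×c tables with the observed margins is used up to grand total 200, and
multivariate-hypergeometric Monte-Carlo (≥ 1e5 tables, seeded) above that.
Per tree, total accuracy is Spearman-rank-correlated with node age and
with the similarity p-value (Pearson by flag); predictor strengths are
compared across trees by a paired t-test on the absolute correlations
(signed comparison by flag), with conventions: identical vectors → t = 0,
p = 1; zero-variance nonzero difference → p → 0 with a degeneracy flag.

## The simulation study

`run_simulation_study` chains the pieces: a synthetic target tree is
simulated from fixed moderate-turnover rates (mu 0.2, delta 0.1, lambda1
0.3, lambda2 0.05, lambda3 0.5 — chosen to yield a rich fossil record,
intercontinental movement and ~40% extinct species at ~100 extant tips);
candidates from prior draws are ABC-filtered against it; each kept tree is
subsampled under the scenario grid, refitted, and scored in truth mode.
Every stochastic stage receives a child seed spawned from the master seed,
so reruns are exactly reproducible; per-tree failures are isolated and
logged, never silently downgraded. The acceptance script and tests run the
study at 400 candidates / keep 20 / 100 extant tips with 2 optimizer
restarts per fit — sizes chosen so the full chain completes in minutes on
one CPU while leaving the qualitative outcomes (the old-node fossil
benefit and the predictor sign structure) stable across seeds. Under these
conditions the oldest-age-quantile mean total accuracy is consistently
higher with 25% of fossils included than extant-only, and extant-only
accuracy correlates negatively with node age and positively with sampling
similarity.

## Known limitations

* The cladogenetic weighting is one defensible convention among several;
  comparisons of fitted `j` values across software are not meaningful.
* The DEC state space grows exponentially in areas; the implementation is
  dense and intended for ≤ 8 areas.
* Model selection between DEC and DEC+J is reported (lnL, AIC) but not
  adjudicated; the statistical debate about jump-dispersal likelihoods is
  out of scope.
* The oldest-fossil-record baseline (`oldest_record_area`) is a simplified
  stand-in for occurrence-database methods: it reports the continent(s) of
  the oldest simulated occurrence, with no estimation of preservation or
  origination rates from real occurrence data.
* Empirical-style runs measure the *difference* fossils make relative to
  the full-tree inference; only simulations provide a ground truth.
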