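# Methods

## Scope and data model

The pipeline analyses sex-biased expression at three levels: per-gene
calls, per-order consensus, and per-family classification. Its inputs are
deliberately minimal: an orthogroup table in the OrthoFinder
`Orthogroups.tsv` dialect, a sexed expression table (one male-sample and
one female-sample FPKM per gene), species metadata (insect order and
sex-determination system per species), optionally a gene→chromosome-class
map, and Newick trees. Orthology inference itself, alignment construction
and maximum-likelihood tree inference are upstream of this package;
their outputs are consumed as files.

## Bias calling

A gene's direction is decided by the sign of `m − f`, gated by two
thresholds:

* `min_fpkm_floor` (default **1.0 FPKM**): if neither sex reaches the
  floor, the gene is unexpressed for calling purposes and reported
  `unbiased` with `passed_floor = False`.
* `fold_threshold` (default **1.0**, i.e. sign-only) applied to the
  pseudocounted ratio `(max+ε)/(min+ε)` with `ε = 0.01`. The sign-based
  default is deliberate: published per-gene annotations include pairs with
  ratios as low as 1.18, so any stricter default would contradict the
  annotations the analysis is meant to mirror. Upstream expression
  databases apply their own replicate-based differential-expression
  testing; the caller here is a stand-in for that unstated criterion, and
  the threshold is a config key for stricter re-analysis.
* When a gene is profiled in several tissues, a configured priority list
  (whole body > gonad > carcass > head) selects one record; ties fall back
  to file order, keeping the pipeline deterministic.

Antisymmetry (swapping m and f swaps male↔female) and scale invariance
(common rescaling of both sexes preserves the direction, floor permitting)
are enforced by property tests.

## Order consensus and family classification

Species-level directions within one order collapse to a single order
direction under one of two rules: **majority** (strict plurality among
male/female calls; unbiased calls counted but never winning; male–female
ties → unbiased) or **unanimity** (every calling species must agree; an
unbiased call breaks unanimity). Majority is the default; both are
implemented because published analyses often leave this rule implicit. A
species carrying several genes of one family first gets a species-level
direction by the same plurality rule.

A family qualifies for classification when every present species carries
exactly one gene and the family spans at least `min_orders` (default 4)
orders with at least one species each; an alternative presence criterion
(`min_total_species ≥ k`, any orders) serves larger tree-building sets.
Classification of a qualifying family:

| pattern over the 4 orders | label |
|---|---|
| all male | `consistent_male` |
| all female | `consistent_female` |
| 3 male + 1 female | `non_consistent_male` (female order deviates) |
| 3 female + 1 male | `non_consistent_female` (male order deviates) |
| any order unbiased or no_data | `unclassified` |
| anything else (2–2) | `mixed` |

The `deviating_species` are the species of the deviating order whose own
call matches the deviating direction. The `unclassified`/`mixed` labels
make the classification a partition: the count of families outside the two
consistent classes is exactly `total − consistent`, without forcing
ambiguous families into the reversal classes.

Turnover counting attributes each non-consistent family to its deviating
species. **Strict** attribution (default) counts only families with
exactly one deviating species and lists the rest in a remainder report —
the published per-species counts sum exactly to the class total, implying
one deviating species per family; **lenient** attribution credits every
deviating species and is kept for sensitivity analysis. Shares are
percentages of the class total rounded half-away-from-zero to one decimal;
the excess statistic `100(a−b)/b` rounds to a whole percent.

## Synthetic data generator

The generator emulates the study regime the analysis assumes, so every
stage can be tested against planted truth:

* **Species panel**: 13 species in 4 orders (1 aphid, 1 beetle, 2
  lepidopterans, 4 mosquitoes + 5 drosophilids), with a hard-coded default
  species tree whose order-level structure mirrors the empirical one —
  the hemipteran outermost, the beetle on a long terminal branch. The
  sampling imbalance (9 dipterans vs 1 hemipteran) is intentional: it
  drives the order-consensus edge cases the classifier must handle.
* **Latent bias states** evolve along the tree as a symmetric two-state
  (male↔female) Markov chain with rate `bias_rate_mu` (default **0.3**
  per unit branch length, chosen so a several-hundred-family panel yields
  tens of reversal families); along a branch of length `t` the state flips
  with probability `(1 − e^(−2μt))/2`. There is no latent "unbiased"
  state — unbiased observations arise only from the calling threshold.
  The chain is symmetric by default; real turnover may be asymmetric
  (female→male reversals more common), which a config extension could
  express but the default deliberately does not assume. Long branches
  accumulate more flips, which concentrates reversals on the beetle's long
  terminal branch — the pattern the turnover table is designed to expose.
* **Expression**: each sex draws an independent lognormal FPKM,
  `2^N(baseline, sd)`, with the biased sex's log2 mean shifted by
  `log2(fold)`. Defaults: baseline **4.5** (≈23 FPKM, the middle of the
  published example tables), sd **0.8**, fold **4.0**. With independent
  draws, a call flips direction with probability
  `Φ(−log2(fold)/(√2·sd))` — ≈10% at sd ≈ 1.1 for fold 4 — which is what
  makes noise-degradation experiments meaningful.
* **Occupancy**: presence per (family, species) is Bernoulli
  (`presence_prob`, default **0.35**, putting ~87% of families in ≤6 of 13
  species — the heavy species-restriction seen in real orthogroup
  spectra); present species carry one gene, or two with
  `extra_copy_prob = 0.1`; empty families are redrawn.
* **Alignments** evolve site-independently under Jukes–Cantor from a
  uniform root (default **500** sites; tests use up to 100k where closed
  forms are checked); `acceleration_factor` multiplies only the focal
  species' terminal branch.
* **Determinism**: one `numpy` Generator seeds everything; the stream is
  consumed in a fixed order (membership, then per-family states, then
  expression, then alignments), and `write_dataset` is byte-reproducible.
  To bound dataset size, alignments are written for at most
  `max_alignment_families` families (default 25).

What the generator does *not* emulate: replicate-level count noise and
library-size effects (FPKM pairs are drawn directly), gene
duplication/loss histories (extra copies are i.i.d., not tree-shaped),
rate heterogeneity across sites, indels, and correlated evolution between
families. Passing recovery tests therefore demonstrates the pipeline's
correctness under its stated model, not robustness to every artifact of
real RNA-seq.

## Trees

* **Distances**: Jukes–Cantor, `d = −(3/4)ln(1 − 4p/3)`. Saturated pairs
  (`p ≥ 0.75`) are a hard error by default, or capped at a configurable
  sentinel (default 5.0 substitutions/site).
* **Neighbor-joining**: canonical Q-criterion implementation with a
  deterministic tie-break (lexicographically smallest cluster-label pair).
  Negative branch-length estimates are clamped to zero with the deficit
  moved to the sibling branch, so output trees are non-negative by
  construction. NJ on JC distances stands in for maximum-likelihood
  inference at desk scale; the report formats are tool-agnostic, so
  externally inferred Newick trees drop in unchanged. An independent NJ
  implementation (dendropy's) is used as a cross-check oracle in the test
  suite only.
* **Congruence**: Robinson–Foulds on unrooted topologies — the size of the
  symmetric difference of nontrivial bipartition sets, with the discordant
  splits listed explicitly and normalized by `2(n−3)`. Gene-tree leaves
  are relabeled to species ids before comparison (single-copy families
  guarantee the bijection); trees violating it are skipped with a logged
  reason. Rooting is ignored: bipartitions are computed on the unrooted
  topology.
* **Acceleration screen**: per leaf, the terminal length is compared with
  the median of the other terminals (default flag threshold **3×**) and
  with a robust z-score on log lengths, `(log L − median)/(1.4826·MAD)`
  (default **2.0**). The default rule requires both (AND); when the MAD is
  zero or lengths are nonpositive the z-score is undefined and the ratio
  rule decides alone. Power at these defaults: a 5× planted terminal on an
  8-taxon, 5000-site family is recovered in >90% of replicates with a
  false-flag rate well under 10% — measured by the test suite itself.

## Pipeline and reproducibility

`run_pipeline` executes summary → calls → consensus → classification →
turnover (→ chromosome cross-tab → congruence/acceleration) and writes
each artifact as TSV/JSON. No report contains timestamps; reruns on
identical inputs are byte-identical, and the manifest records the config
hash, seed and per-artifact row counts. Input validation distinguishes
warnings (orthogroup genes without expression rows — left uncalled) from
errors (species without metadata — abort naming the offender).

## Problem sizes

Simulation-backed checks run at sizes chosen to make Monte-Carlo error
small relative to the tested effect while keeping the default suite quick:
10,000 replicates/sites for the closed-form checks (flip probability, JC
mismatch, occupancy spectrum), 500 families for classification-recovery
experiments (with full presence and single copies, isolating call noise
from occupancy effects), and 50 replicates per condition for the
acceleration power/false-positive estimates.

## Known limitations

* The bias caller is a stand-in for whatever replicate-based test produced
  the upstream per-gene annotations; absolute class counts on real data
  depend on that upstream choice.
* Order consensus with one or two species per order (as in this panel's
  Hemiptera, Coleoptera and Lepidoptera) is fragile by construction: a
  single species' call decides — or ties — its order. This mirrors the
  sampling imbalance of the underlying study rather than a fixable defect.
* NJ+JC is a consistency-grade substitute for ML inference; branch-length
  comparisons on real protein data should use the externally inferred
  trees via the drop-in report interfaces.
* The turnover attribution assigns reversals to extant species, not
  ancestral branches; no ancestral-state reconstruction is performed.
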