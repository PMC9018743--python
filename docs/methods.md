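# Methods

## Scope and model

The package reconstructs a condition-specific signaling network for every
(cell line, drug) pair by solving a prize-collecting Steiner forest (PCSF)
on a refined protein–protein interactome, and then analyses the collection
of networks through the lens of topological separation. The underlying
assumptions are:

* a drug's transcriptional and phosphoproteomic footprint implicates a set
  of proteins (terminals) whose mutual wiring through the interactome
  approximates the perturbed signaling program;
* interaction confidence is informative: the cost of including an edge is
  `c(e) = 1 − w(e)`, so high-confidence interactions are preferred;
* two drugs act similarly exactly when their networks interleave on the
  interactome, quantified by the separation score `s_AB`.

## Terminal preparation

Per gene, treated vs control replicates are compared by one-way ANOVA
(two groups, so F equals the squared pooled-variance t). Genes with raw
p < α (default α = 0.05; no multiple-testing correction, deliberately
matching the raw-threshold convention of the screen design this emulates)
are "significantly transcribed". The log2 fold change is computed on arm
means, floored at 1e−9 before the log to stay defined on the fluorescence
scale. Degenerate genes (zero variance in both arms) receive p = 1 when
arm means agree and p = 0 otherwise.

Transcription factors regulating ≥ 3 significant genes become terminals.
Their prize is the mean **absolute** log2 fold change of the significant
regulated genes: prizes must be non-negative for the prize function to be
meaningful, so the sign-free magnitude is used. Phosphoprotein terminals
take the maximal |fold change| over their significant sites (p < 0.05);
when a protein appears in both lists the proteomic prize wins. Drug
targets are appended with the mean prize of the omics-derived entries, so
they anchor the network without dominating it. A condition with no
omics-derived terminal at all is infeasible and reported as dropped:
target-only seed lists cannot support network modeling.

## Interactome refinement

Fixed order: hub removal → expression filter → link prediction →
localization filter → augmentation.

* **Hubs**: nodes with degree > 900 **and** degree > mean + 10 SD (both
  clauses; statistics over all node degrees) lose all incident edges.
  Self-loops are always removed.
* **Expression filter** (per condition): edges with an endpoint whose
  treated-arm mean expression is below 2.0 are removed; unmeasured
  proteins are kept (unknown ≠ silent).
* **Adamic/Adar**: natural logarithm in `1/log degree` (the unqualified
  "log" of the index's definition); only non-adjacent pairs with a common
  neighbor can score, and a common neighbor necessarily has degree ≥ 2, so
  no division by zero is reachable. The top-k predictions (k = number of
  edges in the processed interactome) are taken **before** the
  localization filter, matching the stated order of the procedure.
* **Localization**: predictions whose proteins share no annotated
  compartment are dropped; proteins without any annotation pass (their
  location is unknown, not incompatible).
* **Augmentation**: surviving scores are min–max scaled onto [0, 0.5] and
  appended as `origin="predicted"` edges. Degenerate scaling (single or
  all-equal scores) maps to 0.5. A scaled weight of 0 (the minimum) is
  retained with cost 1: all filtered predictions are appended, but a
  zero-confidence edge is never attractive to the solver. Predicted edges
  therefore carry costs in [0.5, 1] and appear in final networks only when
  no curated path competes — reconstructed networks contain few or none.

## PCSF

Adjusted prizes: `p′(v) = β·p(v) − μ·degree(v)`; non-terminals have
p(v) = 0 and receive the pure hub penalty. The objective implemented is

    f′(F) = Σ_{v∉F, p′>0} p′(v)  +  Σ_{v∈F, p′<0} |p′(v)|
          + Σ_{e∈F} c(e)  +  ω·κ.

This equals the classical "excluded prizes + edges + ω·κ" objective up to
the additive constant Σ_{p′≤0} p′ (which depends only on the instance, not
the forest), so the two forms share their minimizers; the form used here
makes the hub penalty of *included* negative-prize nodes explicit and
evaluates to Σ max(p′, 0) for the empty forest. Restricting the excluded
sum to positive prizes *without* charging included negative prizes would
silently disable the μ penalty — a pitfall this formulation avoids.

**Heuristic.** A virtual root offers each positive-prize terminal an
attachment of cost ω. Terminals are processed in descending p′ (ties by
id); each connects to the growing forest by the cheapest path (edge costs
plus penalties of newly included negative-prize nodes, Dijkstra with
deterministic tie-breaking) or to the root, whichever is cheaper, and only
if the connection cost does not exceed its prize; nodes may not exceed
depth D (default 10) from the root. Strong pruning then optimally trims
each rooted tree: subtrees worth less than their connecting edge are cut
(ties kept), and whole trees worth less than ω are dropped, which also
guarantees every surviving tree contains a positive-prize terminal. If the
result would score worse than the empty forest, the empty forest is
returned. The heuristic is certified against an exact oracle
(`brute_force_pcsf`, exhaustive over node subsets with per-component
MST/split optimization, ≤ 12 nodes): on random 8-node instances it attains
the optimum in ≈ 85–95% of cases and is never better than the optimum nor
worse than the empty forest.

**Grid and merge.** Default desk-scale grid: μ ∈ {0, 0.01, 0.1},
β ∈ {2, 5, 10}, ω ∈ {1, 2, 3}, D = 10 (a denser μ grid can be configured).
Each point is solved independently; solutions are ranked lexicographically
by (terminals included, −hub count at degree > 100) and all solutions tied
at the maximum are merged by node/edge union. Node roles record provenance
(terminal_tf / terminal_phospho / drug_target / steiner).

## Network comparison

Distances are unweighted hop counts on the reference interactome (the
standard network-medicine convention; the refined per-condition graphs are
used only for reconstruction). `⟨d_AB⟩` averages, over each protein of
either set, the distance to the nearest protein of the other set (0 for
shared proteins); `⟨d_AA⟩` averages nearest-neighbor distances within a
set, defined as 0 for singletons. Unreachable proteins are dropped from
the mean with a warning rather than contributing infinities. BFS results
are cached per reference graph; results are independent of caching.

Node-overlap significance is the inclusive upper hypergeometric tail with
(x, M, n, N) = (common nodes, larger network, smaller network, interactome
size). Pathway enrichment is the same tail per gene set against a
configurable universe (default: the interactome node set), flagged at raw
p < 0.05 with no multiple-testing correction, and a plain hypergeometric
rather than an EASE-style adjusted score. For pairwise comparisons only
pathways whose names contain "signaling" (configurable predicate) count.
Hierarchical clustering of score-matrix rows uses Euclidean distances with
average linkage; labels are sorted first so tied merges are deterministic.

## Drug-level evaluation

A pair is predicted "mechanistically similar" iff s_AB < threshold
(strict). Same-MoA similar pairs are TP; the threshold sweep reports the
full confusion-matrix metric set per threshold and selects the operating
point by MCC (ties to the smaller threshold); MCC with a zero denominator
is defined as 0, and a threshold predicting nothing positive is flagged
degenerate with precision reported as 0. All condition pairs are pooled
across cell lines (a per-cell-line analysis is a trivial restriction of
the matrix).

Combination rating: s_AB > 0, fewer than two shared significant signaling
pathways, both networks > 40 nodes, at least one > 100 (cutoffs sized for
full-interactome screens; desk-scale runs may rescale them). The driver
rule additionally requires ≥ 1 shared cancer-driver protein between
separated networks (separation serving as the operational surrogate for
"topologically disjoint regions"). The sensitivity analysis keeps pairs
where one condition's z-score is negative (sensitive) and the other's
positive, and s_AB > −0.45, then reports the Pearson correlation of s_AB
against |Δz|; the resistant side is not modeled.

## Synthetic cohort

The generator emulates the statistical structure of a CMap-style screen at
desk scale. Defaults: 300 proteins, 12 planted modules of 15, 24 TFs, 8
drugs in 4 MoA classes on 2 cell lines, 3 replicates, effect size 2.0
(log2-scale fluorescence units), replicate noise SD 0.5, baselines uniform
on [0, 15] so the absolute expression threshold 2.0 is meaningful.

* **Interactome**: preferential-attachment backbone (heavy-tailed degrees,
  so the hub filter has something to exercise) with confidences uniform on
  [0.4, 0.8]; planted modules are densified internally (p = 0.35) at
  confidence [0.7, 0.95]. Confidence mass is kept away from 1.0 on
  arbitrary edges because near-certain confidences on random backbone
  edges would make path costs nearly hop-free, which no real
  confidence-scored interactome exhibits. Each TF is physically anchored
  to three proteins of the module it regulates — TFs act in complexes with
  their targets' pathway neighborhoods.
* **Classes**: MoA class k perturbs modules k and k+1 (cyclically), so
  same-class drugs share both modules, adjacent classes one, distant
  classes none — a graded mechanism space rather than an all-or-nothing
  one.
* **Panels**: control = baseline + noise; treated shifts planted-module
  genes by ±effect_size (per-gene sign fixed per drug). Phospho tables mix
  true hits (small p, fold change near the effect size) on a fraction of
  module proteins with a uniform-p background; with effect_size = 0 all
  rows are background, giving an exact null for calibration checks.
* **Annotations**: module-correlated localization with a configurable
  unannotated fraction; per-drug targets inside the drug's modules;
  cancer drivers sampled from class modules.
* **Sensitivity**: z = 1.5 − 3.5 · (fraction of the drug's modules among
  the cell line's driver modules) + N(0, 0.4), so on-driver drugs are
  sensitive (z < 0) and the separation-vs-|Δz| association has a planted
  positive direction.

**What the generator does not emulate.** Real screens measure a small
shared panel (landmark genes, ~100 phosphosites), which makes seed lists
overlap globally across *all* drugs; the synthetic cohort draws
independent per-condition read-outs, so dataset-level observations that
hinge on panel sharing (for example, seed-only separation scores sitting
mostly below network-based ones) are not reproduced, and passing tests say
nothing about them. Time courses, non-landmark expression inference, and
chromatin read-outs are likewise out of scope. Dataset-scale figures of a
full screen (hundreds of networks, thousands of rated combinations) are
not reproducible at desk scale and are not targeted.

## Problem sizes and determinism

Default end-to-end runs use 16 conditions on the 300-protein interactome
(~10 s on one CPU); oracle certification uses 8-node instances where
exhaustive enumeration is exact. All randomness flows from a single seed
through `numpy.random.SeedSequence`; identical configuration and seed give
byte-identical written artifacts (verified by manifest hashes).

## Known limitations

* The PCSF heuristic is not msgsteiner's message passing; its contract is
  objective quality against the exact oracle, not algorithmic fidelity.
* Separation-based MoA classification is evaluated on planted classes;
  real MoA labels are noisier and multi-label.
* The combination size cutoffs (40/100 nodes) are meaningful at
  full-interactome scale only.
* Enrichment uses raw p-values by design; with many gene sets a corrected
  pipeline would be stricter.
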