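# Methods

This note documents the models, conventions and numerical choices behind
`tfatlas`, in the package's own terms: what each stage assumes, which knobs
matter, what the synthetic-data generator does and does not emulate, and
where design was genuinely open.

## Duplication–loss reconciliation

Given a rooted binary gene tree and a rooted binary dated species tree,
every gene node is mapped to the species tree by the LCA mapping. Events
are read off the mapping:

* **duplication** at gene node *v* iff some child of *v* maps to the same
  species node as *v*; the event is assigned to the species branch ending
  at `M(v)` (a duplication mapping to node *s* happened on the lineage
  leading to *s*).
* **losses** on the gene edge (*v*, *c*): one per species node skipped on
  the path from `M(v)` down to `M(c)`; each is assigned to the *off-path
  child branch* at the skipped node — the branch on which the lost lineage
  actually lived — so the atlas can localise losses. A speciation consumes
  the first node of the path; a duplication does not, hence the
  `depth(M(c)) − depth(M(v)) − [v is speciation]` count.

For a fixed rooted gene tree the LCA mapping minimises the duplication
count and the loss count simultaneously over all valid mappings; the test
suite re-verifies this on hundreds of random instances against an
exhaustive enumeration oracle written directly from the definitions.

**Costs.** Unit costs (c_d = c_l = 1) by default, configurable. Nothing in
the pipeline depends on the ratio except rooting and polytomy-resolution
tie-breaks.

**Stem origin.** Every orthologous group is assumed to descend from a
single copy already present at the species root (`assume_root_origin=True`
by default). Species subtrees hanging off the path from the species root
down to `M(root)` therefore contribute one stem loss each. Without this
convention, loss counts on basal branches are systematically undercounted
whenever a family disappeared from an entire basal clade.

**Rooting.** Unrooted gene trees are rooted at the edge minimising total
DL cost; ties are broken by (1) the rooting whose root maps closest to the
species root, then (2) the lexicographically smallest canonical newick,
making the choice deterministic.

## The ILS threshold

Incomplete lineage sorting produces gene-tree/species-tree discordance
concentrated on short internal branches. Rather than model the coalescent,
the pipeline treats short branches as topologically unreliable: internal
edges with length below

    T = Ne · μ_gen        [substitutions/site]

are contracted. `μ_gen` is the family's per-generation substitution rate,
estimated as the mean root-to-leaf path length divided by the root age in
generations (root age in years / generation length `g`). Defaults:
`g` = 10 years; `Ne` swept over {10⁴, 10⁵, 10⁶, 10⁷}. With a typical
mammalian-scale clock (0.002 substitutions/site/My, root at 170 Mya),
μ_gen ≈ 2×10⁻⁸ and the Ne = 10⁶ threshold is T ≈ 0.02.

Terminal edges are never weak: a leaf's species identity is observed data,
not topology to rearrange.

**Polytomy resolution.** Contracting adjacent weak edges yields disjoint
polytomies. Because the LCA mapping of a polytomy root is invariant under
resolution, each polytomy can be re-resolved independently: all (2k−3)!!
rooted binary resolutions are scored for k ≤ 6 children (`k_max`), and a
greedy pairwise agglomeration (flagged `approximate`) is used up to the
hard cap of 12, beyond which the family is skipped with a logged reason.
The original topology is always among the candidates, and the original
reconciliation is kept whenever resolution does not improve the cost, so
the rearranged cost never exceeds the unrearranged one. At Ne = 10⁷ the
threshold can contract most of a gene tree; families that blow through the
hard cap there are skipped and logged, which is why event totals at the
most aggressive threshold cover fewer families.

## Rate atlas

Branch rates are `events / branch duration (My)`. Events mapped to the
species root itself (which has no branch) are kept in separate root
counters so conservation (Σ branch counts + root counts = Σ per-family
events) holds exactly.

Windowed rates smear each branch's events uniformly over the branch's time
span — reconciliation localises events to branches, not to time points, so
a within-branch convention is unavoidable; uniform smearing conserves
totals under any complete windowing. "Mean rate in an epoch" is the
unweighted arithmetic mean over branches whose span intersects the epoch
(an overlap-weighted mean is available via `duration_weighted=True`; the
unweighted mean is the default bar statistic).

## Trait association

The presence matrix is restricted to single-copy families (no species with
≥2 copies; presence = exactly one copy) and to variable columns. For each
binary trait:

1. **Prescreen.** Pearson χ² on each 2×2 presence-by-trait table, 1 df,
   *no* continuity correction (an explicit, testable choice); survivors
   have p < α = 0.05. Degenerate margins are skipped and logged; species
   with a missing trait value are dropped for that trait, not imputed.
2. **Lasso.** L1-penalised logistic regression on the survivors,
   column-standardised, intercept unpenalised; coefficients are reported
   on the standardized scale. The optimiser is scikit-learn's saga solver.
   The penalty is chosen by k-fold (default 10) cross-validated deviance:
   the path runs over 40 log-spaced values from the exact all-zero
   threshold `λ_max = max_j |X_jᵀ(y − ȳ)|/n` down to 10⁻³·λ_max, with a
   loose tolerance along the CV path and a tight (1e-7) refit at the
   chosen λ. Both the deviance minimiser (default) and the 1-SE rule are
   available.

Species are treated as exchangeable observations: phylogenetic
non-independence is deliberately **not** corrected, mirroring the analysis
this package operationalises, and a warning is emitted on every call.

**Selection operating point.** Planted-recovery experiments (5 causal
families, |β| = 2, 96 species, 200 columns) show the deviance-minimising λ
overselects: recall ≈ 0.9, precision ≈ 0.3; the 1-SE rule trades toward
precision ≈ 0.5 at recall ≈ 0.7. A scan along accurately solved paths
shows even the truth-informed best per-dataset λ only averages
recall ≈ precision ≈ 0.8 at this signal strength — the limit is the
information in n = 96 binary observations, not the optimiser. Treat the
selected set as a candidate list, not a hypothesis test.

## Target-gene deceleration

Terminal rate of species *i* for a target gene: terminal branch length
(substitutions/site) divided by the species' terminal branch duration
(My). Target-gene trees must be single-copy. Each TF→TG interaction
contributes one pair (mean rate among TF-possessing species, mean among
TF-lacking species); groups below `min_group` = 3 species exclude the pair
(logged; used + excluded = input interactions). The paired test is a
two-sided one-sample *t* on d = without − with, with a Wilcoxon
signed-rank companion; deceleration shows as mean(d) < 0. Interaction-level
pairing is the default and is acknowledged pseudo-replication when several
TFs regulate one TG; TG-level pairing (averaging a TG's regulators) is
available via `pair_by="tg"`.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes, plus ground truth:

* **Species tree** — random expansion (pure-birth) topology; the root is
  pinned at age A and the n−2 other split ages are uniform order
  statistics on [0, A]. This keeps the mean k-th largest age exactly
  A·(m+1−k)/(m+1) (m = n−2), which the tests exploit as a closed form.
* **Gene families** — one copy at the species root; along each species
  branch every lineage duplicates at rate λ(b) and dies at rate μ(b) per
  My (defaults 0.002 and 0.003, per-branch overrides for planted
  histories). Surviving lineages become gene-tree leaves; fully extinct
  families are reported and excluded, and the >3-member filter is applied,
  matching the analysis conditioning.
* **Branch lengths** — ℓ = r·t·ε with r = 0.002 substitutions/site/My
  (≈2×10⁻⁹/site/year, a mammalian-scale average) and lognormal branch
  noise ε (σ_r = 0.3); σ_r = 0 is a strict clock.
* **ILS noise** — internal edges shorter than 0.02 substitutions/site are
  hit, with probability p_ils = 0.2, by a random NNI with the edge length
  resampled uniformly on [0, 0.02]. The 0.02 scale matches the Ne = 10⁶
  threshold under the default clock. This is phenomenological short-branch
  noise, not a coalescent simulation: the analysis treats ILS purely as
  short-branch topological noise, and the generator mirrors that.
* **Traits** — Bernoulli(logistic(β₀ + Σ β_j x_ij)) given the presence
  matrix, i.i.d. across species (no phylogenetic autocorrelation),
  matching the non-phylogenetic regression downstream.
* **Target genes** — terminal rate base·(1−δ·[TF absent])·η with lognormal
  η (σ_g); the emitted TG tree encodes rate × duration on terminal
  branches, so rate estimation round-trips exactly at σ_g = 0. Defaults
  δ = 0.3, σ_g = 0.2.

**Ground truth and observability.** Besides the raw event list, each
family's truth record carries the *observable projection*: duplications
whose both daughter lineages left survivors, located at the MRCA of those
survivors, and one loss per maximal extinct subtree hanging off a
surviving lineage, located on the branch where the extinct lineage
started. Noise-free reconciliation equals this projection exactly, per
branch and per family — the strongest end-to-end identity the tests
assert. The projection recapitulates the parsimony reading of the pruned
history using species-LCA algebra on the simulator's own lineage records;
it shares the mathematics with the reconciler but none of the code path,
so it checks pruning, rooting, branch attribution and stem-loss
bookkeeping, while the raw event list provides the fully independent
(correlation-level) comparison.

What passing these tests does *not* show: robustness to gene-tree
estimation error beyond the NNI noise model, to coalescent ILS with
branch-length distortion, to alignment artefacts, or to phylogenetically
autocorrelated traits (a Brownian-threshold trait switch is a natural
extension point).

## Planted-history experiment designs

* **Loss-spike recovery** uses two non-nested internal branches of
  moderate duration (20.9 and 42.5 My on the 16-taxon fixture tree) spiked
  at μ = 0.03/My (10× base). The magnitude matters in both directions: a
  spike on a very long branch saturates (each lineage dies at most once,
  so the *rate* stays low), and a spike on a very short branch starves
  (too few expected events). 200 families give expected spiked-branch
  rates 3–4.5 events/My against a background of ≈1.
* **Paired-test calibration** draws 500 pairs per replicate with groups of
  5 species; 1000 null replicates for type-I error, 200 at δ = 0.3,
  σ_g = 0.2 for power.
* **Association recovery** uses balanced presence columns (p = 0.5) and an
  intercept centring the trait prevalence — the identifiable version of
  the planted design; see the operating-point discussion above.

## Numerical conventions

* Species-node ages are quantised to 10⁻⁶ My (≈1 year) at construction and
  durations written to newick at that precision, making serialisation
  byte-idempotent; gene-tree lengths round-trip at 12 significant digits.
* Canonical newick orders children by smallest descendant leaf label;
  unlabeled internal species nodes get deterministic N0, N1, … labels in
  canonical preorder.
* All stochastic code takes a seed or a numpy `Generator`; the CLI derives
  everything from one master seed, and a manifest records the seed, config
  hash and package version. Identical configs give byte-identical outputs.
* Degenerate inputs: zero-length gene trees give μ_gen = 0 with a warning;
  empty survivor sets give an empty association result; all-equal paired
  differences give t = 0, p = 1; zero-width rate windows and non-positive
  branch durations are errors.

## Problem sizes

Default test and reproduction sizes: 16-taxon, 170-My species tree; 200
gene families per batch; 500 random instances for the oracle-equivalence
check (≤8 gene leaves, ≤6 taxa); 50 seeds (tests) or 25 seeds
(`scripts/acceptance.py`) for the association recovery; 1000/200
replicates for paired-test type-I/power. These sizes give stable estimates
(Monte-Carlo error well inside the asserted margins) at desk-scale
runtime.

## Known limitations

* Parsimony reconciliation only: no transfer events, no probabilistic
  (likelihood) reconciliation, no coalescent-aware mapping.
* The weak-branch threshold rearranges topology but does not revisit the
  root placement chosen before contraction.
* Greedy polytomy resolution above k_max = 6 children is a heuristic
  (flagged in the output); families above the hard cap are skipped at that
  threshold rather than approximated.
* The association stage inherits every caveat of cross-species regression
  without phylogenetic correction; its selected sets are candidate lists.
* Interaction-level pairing pseudo-replicates TGs with many regulators;
  TG-level pairing is provided but ignores regulator identity.
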