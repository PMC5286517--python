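# Methods

## The problem

Gene regulatory network (GRN) inference from expression data alone is
unreliable in eukaryotes: noise, few conditions relative to genes, and
layers of regulation beyond transcription produce many false links.  This
package refines an *initial* integrative network — expression-based
tree-regression importances intersected with a DNA-binding prior — by
exploiting a third information source, gene–gene co-functionality, under
the rationale that a regulator with a confident link to one gene is more
likely to also regulate a closely co-functional gene.  The refinement is
semi-supervised: its two hyperparameters are learned from sparse curated
gold standards rather than set by hand.

## Model

### Initial network

For each target gene, a random-forest regression of its expression profile
on all transcription factors yields one importance per TF (total impurity
reduction over splits, averaged over trees, *unnormalized* so scores stay
comparable across targets with different explainable variance).  All
TF–target scores are pooled and rank-normalized by the empirical CDF,
`v = ECDF(score) ∈ (0, 1]`; only the top fraction (default 5%) is kept, and
of those only links supported by the binding prior survive.  Ties share an
ECDF value and are kept or dropped together.  A TF is never used to predict
itself: self-regulation is unidentifiable in this design.

### Meta network and modules

Links become nodes of a *meta network*; two links connect iff they share a
regulator.  The coupling weight of a meta edge combines the targets'
co-functionality `w_ff ∈ [0, 1]` with the similarity of the link weights:

    v_Δ = w_ff · (1 − |v_a − v_b|)

This is the package's chosen combination rule: it is strictly decreasing in
the weight distance when `w_ff > 0`, increasing in `w_ff`, stays in
`[0, 1]`, and reduces to pure co-functionality at equal weights.  An
alternative, `w_ff / (1 + |v_a − v_b|)`, is available behind the
`combination="inverse_distance"` switch.  A missing co-function pair means
*unknown*, treated as zero coupling — co-function compendia cover only part
of any genome, and absent evidence should not couple links.

Each connected component (necessarily per-regulator, since meta edges only
join links with the same regulator) is reduced to its maximum spanning tree
(Kruskal; ties broken lexicographically on `(regulator, target_a,
target_b)` for platform-independent determinism).  Isolated links become
single-link modules.  Trees make exact probabilistic inference possible.

### Markov random field per module

Each link carries a binary state `x_l` (keep/remove).  With spins
`s_l = 2x_l − 1`, the module energy is the Ising form

    E(x) = − Σ_l (v_l − γ)·s_l − λ · Σ_{(l,l')∈tree} v_Δ(l,l')·s_l·s_l'

and `p(x) ∝ exp(−E(x))`.  γ is the learned weight threshold: an isolated
link reduces to `p(x=1) = σ(2(v − γ))`, i.e. removal exactly when
`v ≤ γ`.  λ scales the co-regulation coupling globally.  The sign/offset
convention is the package's core modeling assumption, fixed by the required
qualitative behaviour (favour high-weight links; reward strongly coupled
pairs for sharing a state) rather than by a printed formula.

Links with `v > γ` (strictly) are *clamped* to `x = 1` — undirected models
are closed under conditioning — so a confident link can rescue weak
co-functional neighbours but can never be voted out by a crowd of weak
ones.  Clamping is evidence (a delta potential), not graph surgery.
Marginals are exact two-pass sum-product on the tree, computed in the log
domain with per-message max-normalization; a link is retained iff
`p_l > 0.5` (strict).  `belief_propagation(..., clamp=False)` exposes the
unconditioned marginals (the singleton closed form), which imply the same
retention rule for isolated links.

### Objective

Candidate networks are scored against two gold standards:

* **Precision** `P`: fraction of retained links found among curated
  regulator→target pairs.  By default the denominator counts only links
  whose regulator occurs in the gold standard at all ("evaluable"
  predictions) — sparse curated maps say nothing about other regulators.
  This restriction is toggleable.
* **Recall** `R`: gene pairs are *co-regulated* when their regulator sets
  overlap with Jaccard coefficient strictly above 0.5.  The reference set
  holds pairs that are both co-regulated in the initial network and
  co-annotated in the benchmark; `R` is the fraction of that set still
  co-regulated after pruning.  The numerator is intersected with the
  reference because pruning can also *create* co-regulated pairs (removing
  a regulator raises a pair's Jaccard coefficient), and such new pairs are
  not recoveries; without the intersection the recall surface saturates and
  stops constraining the search.  An alternative anchoring on the whole
  co-annotation benchmark is available (`anchor="benchmark"`).
* Precision is scaled by the maximum raw precision observed on the search
  grid (frozen through annealing, capped at 1), so the precision surface
  reaches 1 despite gold-standard sparsity, and both surfaces combine as
  `f_β = (1+β²)·P̂·R / (β²·P̂ + R)` (default β = 1).

Enrichment of a prediction set is reported as fold change over the fully
connected regulator × gene background with a one-sided Fisher's exact test.

### Hyperparameter search

γ ranges over the observed weight range (grid at empirical weight
quantiles, so the grid adapts to any weight distribution); λ over
`[0.001, 2.5]`, log-spaced.  A coarse grid (default 10 × 10) locates the
best cell; simulated annealing (geometric cooling, T₀ = 1, α = 0.9, 50
levels × 4 Gaussian proposals with σ = 10% of the sub-space width,
reflected at boundaries) refines within the cell ± one grid step.  The
schedule is an engineering default, fully configurable.  The final pick is
conservative: among all visited θ with `f_β ≥ (1 − δ_f)·f_best`
(δ_f = 0.01), the smallest λ (then smallest γ) wins — a low coupling
penalty avoids over-predicting master regulators.  Grid ties resolve to the
lowest λ, then the lowest γ.

### Hold-out ensemble

`N` rounds (default 100): each samples 63.2% of the modules without
replacement (the classic .632 convention) together with the gold entries
falling inside them (a regulatory pair belongs to a split iff it is one of
the split's links; a co-annotation pair iff both genes are targets in the
split), learns θ on the training part, and applies the model to *all*
modules so every link receives a vote.  Per-round gold enrichment is
reported on the held-out modules.  The final network keeps links retained
by strictly more than `ε_p = 0.5` of the rounds.  Per-round seeds derive
from the global seed by CRC hashing, so results are independent of
execution order.

## Synthetic benchmarks

`synthetic.generate_benchmark` emulates the five inputs around a planted
truth; its defaults define the package's study conditions:

* 20 TFs, 300 genes, 40 conditions; regulons of ~12 targets drawn mostly
  disjointly with a 10% overlap fraction (heavily overlapping regulons at
  this scale make the strict Jaccard criterion degenerate; real regulons
  are largely distinct).
* Expression: TFs iid N(0, 1); targets are signed linear combinations
  (|coefficient| ~ U(0.5, 1.5)) plus N(0, 2²) noise, i.e. per-regulator
  R² ≈ 0.2 — the low signal-to-noise regime of real developmental atlases,
  which makes the expression-ranking stage genuinely fallible.
* Binding: truth plus 5 random decoy edges per true link, emulating a
  permissive motif-based prior (real binding blueprints are an order of
  magnitude larger than the final network).
* Co-functionality: Beta(5, 2) weights for truly co-regulated pairs,
  Beta(1.5, 5) for an equal number of background pairs.
* Gold standards: 30% of true links; 30% of true co-regulated pairs.

`synthetic.generate_weighted_grn` skips the expression stage: true links
draw weights biased above a planted threshold `t = 0.5` and decoys below
it (Beta(5, 2) vs Beta(2, 5); a positive `separation` maps them into
disjoint intervals for parameter-recovery experiments).

What the generator does **not** emulate: count noise (no negative
binomial), batch or platform effects, indirect regulation, feedback, or
realistic co-function network topology.  Passing tests therefore
demonstrate the machinery is correct and the method behaves as designed
under its own assumptions — not that those assumptions hold for any
particular organism.

## Numerical choices and degenerate inputs

* All boundary rules are strict: clamping `v > γ`, retention `p > 0.5`,
  Jaccard `> 0.5`, ensemble vote `> ε_p`.
* BP messages are log-domain and max-normalized; marginals match
  exhaustive enumeration to < 1e−12 on the tested tree sizes.
* Zero-variance targets yield all-zero importances (no error); an empty
  expression/binding intersection warns and returns an empty network;
  degenerate precision/recall denominators warn and return 0.
* Variance filtering uses the linear-interpolation sample quantile; the
  cutoff (default 0.5) is a package choice exposed as a parameter.
* `round(fraction · M)` modules go to the training split; splits with an
  empty side raise.

## Problem sizes used by the test suite and acceptance script

The properties are checked at desk scale, as the package's own choice of
experiment size: 200 random tree modules (≤ 12 nodes) for BP exactness,
100 random graphs (≤ 7 nodes) for spanning-tree optimality, 5 seeds of the
default benchmark with forests of 100 trees and ensembles of 10 rounds
(8 × 8 grid, 15 × 2 annealing) for the refinement-benefit comparison, and
5 seeds of the separated-weight fixture (10 × 10 grid, 20 × 2 annealing)
for threshold recovery.  Defaults for real runs remain 1000 trees, 10 × 10
grid, 50 × 4 annealing and 100 rounds.

## Known limitations

* Only tree-structured modules are supported (by construction of the
  maximum spanning tree); loopy graphs are rejected, not approximated.
* The learned γ is identified only up to the grid/annealing resolution,
  and with strongly bimodal weights any threshold inside the weight gap is
  equivalent — the reported γ is then the conservative (lowest) end of the
  equivalence region reachable by the search.
* The recall surface depends on the co-annotation benchmark's overlap with
  the initial network; when the overlap is empty the objective degenerates
  to precision alone (a warning is emitted).
* MAP states, loopy belief propagation and weighted/stacked ensembling are
  out of scope.
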