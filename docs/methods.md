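# Methods

This note documents the generative model, the inference procedure, the
comparison models, the synthetic-data generators and the numerical choices
made where the design was genuinely open.

## Causal programmes

A concept is a typed combinatory-logic tree denoting a function from an
(agent, recipient) object pair to an integer segment count. Base types are
`obj` and `int`; a term's type is written `t_in -> ... -> t_out` with the
last component the output. The primitive inventory is fixed: `getStripe`,
`getSpot`, `getSegment` (`obj -> int`), `setSegment`
(`obj -> int -> obj`), `add`, `sub`, `mult` (`int -> int -> int`), integer
constants 0–3, and the identity `I`. `I` is implemented polymorphically
(`a -> a`): without an object-typed identity the grammar could not route a
single object variable into a feature extractor at the two-variable top
level, so the polymorphic reading is forced by expressiveness.

A programme is a leaf (a primitive fully applied to the variables routed to
it; constants ignore variables) or a node `[router, head, arg_1..arg_k]`
whose head is a function term of arity `k` and whose argument slots are
programmes. One router letter per incoming variable directs flow — `C` to
the first argument, `B` to the last, `S` to all, `I` to none — giving
exactly `4^n` routers for `n` variables. For unary heads the single
argument is the "right" side, so `[B, f, g](x) = f(g(x))`; a unary node
with left-routed variables is ill-typed. This n-ary node shape mirrors the
generation algorithm (one head + one router + one branch per argument
slot); with it the ground truth

    (SC sub (CB mult getStripe getSegment) getSpot)

is a depth-2 tree from scratch but a *depth-1* composition once the
multiplicative chunk `(CB mult getStripe getSegment)` is available as a
cached unit — which is precisely the bootstrapping claim the model makes.
Evaluation is pure and total on finite trees; negative evaluations are
preserved by the DSL and clipped to the 0–16 response scale only at
prediction time (negatives to 0, overflow to 16).

## Concept library and generation

The library is a multiset of cached programmes keyed by (structure,
variable-type context), each with a count `M_z`, on top of the
always-available primitives. With `N` distinct entries and `|C| = Σ M_z`
tokens, a generation call of target type τ constructs with probability
`λ₁ = (α₀ + N·d)/(α₀ + |C|)` and otherwise fetches a type-matching cached
entry with conditional probability `∝ M_z − d`, renormalized within the
matching-type subset (an empty subset forces construction; a constructed
head that cannot be completed raises a reported generation failure rather
than silently retrying, so single-attempt probabilities are well defined).
Construction samples a head from a flat prior over terms whose output
matches τ, a router uniformly from the `4^n` options, and recurses on each
argument slot under the induced type constraints; at the depth bound only
arity-zero completions are allowed. A fetched programme costs one depth
unit regardless of internal size — cached concepts are reused as if they
were primitives.

Defaults: `α₀ = 1.0`, discount `d = 0.5`. The source hyperparameter values
are not printed anywhere; these are package defaults, overridable in every
constructor.

`generation_probability` is the exact analytic mirror of the sampler
(construct path + fetch path summed), and
`generation_failure_probability` computes the exact mass of the failure
outcome by recursion over contexts, types and depths. Together they make
the sampler testable against a closed-form oracle, including its failure
mass.

Caching a programme increments counts for the programme and every distinct
subtree (with the context each subtree occupies), so subsequent fetch
weights shift immediately. Subparts include single-leaf subtrees; this is
an interpretation — it lets usage statistics accrue to primitives as well
as to composite chunks.

## Inference

Each Gibbs iteration is one bounded search episode:

1. Draw a search depth from `P(depth) ∝ e^(−b·depth)` over
   `{1, …, max_frame_depth}`. Defaults `b = 6`, `max_frame_depth = 2`: the
   learner almost always searches one composition level deep.
2. Enumerate frames up to the drawn depth. A *frame* is a router skeleton
   with typed placeholders for heads and argument slots; nested sub-frames
   may occupy the first/last argument positions. Frame weights are the
   products of the uniform router probabilities along the skeleton,
   renormalized over the enumerated set. (The exact placeholder convention
   is under-determined in general; this package's reading — routers fixed
   by the frame, heads and slots free — is isolated in `enumerate_frames`
   and `unfold_frame`.) At depth 1 with two variables there are exactly 16
   frames of weight 1/16.
3. Sample frames without replacement by weight. Unfold each sampled frame
   against the current library: every head placeholder ranges over the
   function primitives of the required output type, every slot over
   exactly-typed primitives and type-matching cached entries.
4. Filter candidates with the deterministic 0/1 likelihood. On the first
   frame with a non-empty consistent set, sample `min(3, |M*|)` programmes
   uniformly without replacement (uniformity over the favoured set is the
   minimal assumption; no weighting is specified) and cache them with
   subparts. If every frame exhausts, return the library unchanged with a
   nothing-found flag.

A learner processes a curriculum in stages: `h = 2` Gibbs steps on Phase I,
then `h` steps on Phases I+II combined, continuing from the updated
library; per-stage snapshots are kept, and Phase-I predictions use the
Phase-I snapshots. Population predictions pool `n_learners` independent
learners and draw `n_predictive_draws` programmes from uniformly chosen
pooled libraries (full-scale defaults 1,000 and 10,000; the estimator
classes default to 100 and 1,000 so interactive use is cheap, and the
full-scale values are one constructor argument away). Draws are *not*
filtered for data consistency — the generative posterior predictive is
followed literally — but a consistency-filtered variant is available via
`consistency_filter=True` for sensitivity analysis. Failed draws are
dropped and the 17-bin tallies renormalized.

The reprocessing variant (AGR) mixes forward (phases as presented) and
backward (phases reversed) predictions, `ŷ ∝ θ·ŷ_fwd + (1−θ)·ŷ_bwd`,
modelling learners who revisit earlier evidence; θ (`mix_weight`) is fitted
in cross-validation.

Unfold results are memoized on (frame, library membership, trials); the
memo is semantically transparent (unfolding is deterministic) and exists
only to keep population simulation fast.

## Comparison models

- **Rational rules**: PCFG `S → add(A,A)|sub(A,A)|mult(A,A); A → S|B;
  B → C|D; C → stripe|spot|segment; D → 0|1|2|3` with uniform production
  probabilities `1/|Γ_I|` per non-terminal, depth cap 40 enforced by
  rejection (which keeps the prior well defined; the exact acceptance
  probability is computable and exported), 100,000 samples, deterministic
  likelihood filter, survivor frequencies as posterior weights. Because two
  derivations that use the same multiset of productions have exactly equal
  prior probability, the nested ground truth and its distributed-form
  alternative tie — the mechanism behind this model's insensitivity to both
  curriculum order and compositional form.
- **Similarity**: `σ = exp(−Δ)` with
  `Δ = a·δ_stripe + b·δ_spot + c·δ_segment` (absolute differences; default
  unit weights); each learning trial votes for its own result with weight σ.
- **Linear regression**: least squares for
  `R' ~ a·stripe + b·spot + c·R` with no intercept (the stated formula);
  minimum-norm solution and a degeneracy flag when the design is rank
  deficient. The continuous prediction is spread over its two nearest
  integers proportionally to proximity (a 50/50 split is available by
  config; the split rule is not specified anywhere).
- **Multinomial logistic regression**: L2-regularized (scikit-learn),
  observed result values as classes, class-frequency fallback on
  non-convergence, point mass when only one class was observed.
- **Gaussian process**: one exponential kernel per feature on the absolute
  feature difference, `exp(−|x_f − x'_f|/(2σ²))`, combined by sum (default;
  product behind a flag — the combination is not specified), jitter
  escalation on conditioning failure, and the predictive Gaussian binned
  over the response scale with the end bins absorbing the tails. The kernel
  uses the absolute (not squared) distance, so the predictive algebra is a
  short Cholesky computation rather than a stock kernel object.

All models are fitted per phase on the cumulative trials visible at that
phase and emit the same (phases × tasks × 17) prediction arrays.

## Curricula and synthetic data

The four curricula share the ground truth `R' = stripe(A)·R − spot(A)`
(counterbalanced variants swap the feature roles and are exact
involutions):

- construct: Phase I `(2,0,2)→4, (3,0,1)→3, (1,0,3)→3`;
  Phase II `(2,3,3)→3, (3,1,2)→5, (1,2,2)→0`.
- deconstruct: construct with phases swapped.
- combine: construct Phase I; Phase II holds stripes at 1:
  `(1,1,2)→1, (1,2,3)→1, (1,3,3)→0`.
- flip: combine with phases swapped.

Exact trial values are pinned here rather than copied from any source; the
constraints they satisfy are: features in 0–3, Phase I of construct varies
only the multiplicative feature, combine Phase II fixes it at 1, all
results follow the ground truth, and the Phase-I triple admits the
multiplicative chunk — and no additive or constant rule — as its shallow
explanation (so Phase-I search identifies the chunk rather than a
confound).

Generalization tasks are 8 novel out-of-distribution pairs chosen by greedy
expected-residual-entropy minimization over a candidate grid (agent
features 0–4 × recipient 1–4, training triples excluded) against a
uniform-weight hypothesis set of all one-node rules `op(x, y)` plus the key
two-level composites — a reconstruction of "informative tasks under the
learner's favoured shallow hypotheses". Ties break lexicographically on
(stripes, spots, segments), so the battery is deterministic.

`simulate_participants` draws per-task multinomial response counts from any
model's prediction arrays, emitting the `n_ciy` count schema the evaluator
consumes. This generator emulates response *sampling* only: it contains no
individual differences beyond the model's own posterior spread, no
self-report text, no lapses beyond trembling-hand noise, and no
within-phase order effects — so passing model-recovery tests shows the
harness is coherent, not that real participants behave like the model.

## Evaluation

Trembling-hand smoothing `P_h(y) = (P(y)+h)/(1+17h)` with `h ∈ (0, 1/17)`
guarantees strictly positive likelihoods; the total fit is
`LL = Σ ln(P_h) · n_ciy` in natural logs, compared with
`LL_random = n·16·ln(1/17)`. Cross-validation holds out one curriculum,
fits `h` (bounded 1-D maximum likelihood with a 64-point grid guard; for
AGR, joint L-BFGS-B over `(h, θ)` with multistart and a grid fallback) on
the rest, and sums held-out log-likelihoods. Each model is fitted
independently per fold.

## Problem sizes and reproducibility

Simulation-based checks in the test suite run at desk scale — 200 learners
per condition for the curriculum-order effect, 1,000 replicate Gibbs steps
for the bootstrapping comparison, 100,000 draws for the sampler/oracle
comparison — which this package treats as its standard verification sizes;
full-scale population sizes are reachable through configuration
everywhere. All randomness flows through `numpy.random.Generator` seeds;
identical seeds give bit-identical libraries, predictions and reports.

The sampler/oracle total-variation check runs at the single-variable
feature type (`obj -> int`, depth 1): total variation between an empirical
and an exact distribution is bounded below by Monte-Carlo noise
`~sqrt(support/(2πN))`, and at the two-variable task type the construct
support is so large that no 100,000-draw sample lies within 0.02 of any
distribution. At the feature type the support is a few hundred outcomes
and the exact failure mass enters the comparison as an explicit outcome,
so the computed distance is the true total variation, not a bound. The
two-variable type is separately validated per programme within three
Monte-Carlo standard errors and through the exact failure probability.

## Known limitations

- No subtree refactoring or compression of the library, and no forgetting
  or decay of cached concepts.
- No conditionals in the primitive inventory, so "divide-and-conquer"
  piecewise concepts are inexpressible by design.
- The deterministic likelihood cannot score vague concepts that constrain
  rather than uniquely predict outcomes.
- The frame/placeholder convention and the uniform favoured-set sampling
  are documented interpretations of an under-specified search procedure;
  both are isolated behind single functions.
- Pooling across learners assumes uniform draw allocation over library
  snapshots; no within-phase evidence reordering or active selection is
  modelled.
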