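# Methods

This note documents the models and procedures implemented in `spanccd`,
the parameters that matter, what the synthetic data generator does and
does not emulate, and the numerical and design choices made where the
design was genuinely open.

## Task formalization

A document is a token sequence `w_1..w_T`; predictions are sets of
labeled spans `(s, t, y)` with 1-based inclusive token indices and
`y` drawn from a type schema `Y` (character offsets, where they appear in
corpus formats, are 0-based half-open). Nested mentions — one span
strictly containing another, both annotated — are first-class: the
representation, the loss and the decoder all operate on span sets, not
tag sequences. BIOES import/export is provided for flat corpora only and
raises a representability error on nesting.

## Span encoder

**Token encoding.** The default `tiny` backend is a trainable word-level
encoder: seeded word + position embeddings followed by
`n_encoder_layers` (default 2) of 2-head scaled-dot self-attention with
parameter-free LayerNorm and a 2×-width ReLU feed-forward, hidden size
`d = 64`, dropout 0.1 during training. An optional `context_window`
restricts attention to a local band (0 = purely lexical rows), which the
tests use to verify locality. The `pretrained` backend is an adapter
contract only: it accepts an external subword-embedding provider and
pools subword vectors to words by first-subword selection; it raises a
capability error when no provider is supplied, never silently falling
back. The tiny backend is the package's own desk-scale encoder, chosen
so the full pipeline trains in minutes on one CPU; it is not a
re-implementation of a large pretrained biomedical encoder, and scores
obtained with it characterize the architecture, not state-of-the-art
accuracy.

**Token graph.** A bilinear similarity `σ(h_i' W h_j)` thresholded at
`token_sim_threshold` (default 0.7) defines a token graph; each token
adds a softmax-weighted sum of its neighbors (isolated tokens pass
through). Ablatable via `use_token_graph`.

**Span representation.** Spans up to `L_max = 5` tokens are enumerated
(`Σ_{ℓ≤min(L_max,T)} (T−ℓ+1)` candidates). Channels: start embedding,
end embedding, mean-pool, max-pool, and a learned width embedding `ψ`
(dimension defaults to `d`; `use_length_embed=False` gives the 4-channel
variant for ablation). A sigmoid gate reweights the concatenation
elementwise. Structural attention runs over a span graph whose edges
are nesting (strict containment), overlap (intersection without
containment) and adjacency (gap ≤ `max_adjacent_gap`, default 0 =
strict abutment); attention is bilinear (`W_a`) with masked softmax,
empty neighborhoods contribute a zero context vector, and the output is
`LayerNorm(r + FFN(c))`, applied `n_structural_layers` times with shared
weights. Span self-attention then runs over all spans with a learned
additive bias `φ` looked up from bucketed start distance
({0,1,2,3–4,5–8,9+}) × nesting-depth difference clipped to [−2, 2],
where a span's depth is the number of enumerated candidates strictly
containing it (computable without gold annotations). A softmax
classifier over `Y ∪ {NONE}` completes the forward pass; pruning keeps
spans with entity-ness `α = 1 − P(NONE) ≥ 0.5`, capped at the top 40.

**Stage order.** Token-graph augmentation → aggregation → gating →
structural attention → span self-attention → classification → pruning.
The order is a package choice; each stage is independently switchable.

## Training

Losses: (1) span cross-entropy over all enumerated spans, the NONE class
down-weighted by the positive/negative span-count ratio; (2) a center
loss `Σ ‖r̃ − μ_y‖²` toward per-type centroids computed from predicted
labels within the batch (EMA optional, off by default); (3) a margin
contrastive loss `Σ Σ_{y'≠y} [δ + d²(r̃, μ_y) − d²(r̃, μ_{y'})]₊` with
squared Euclidean distances throughout (consistent units with the center
loss) and margin δ = 1; (4) an auxiliary cross-entropy on the
propagation-refined distributions, which is what trains the decoder's
message-passing parameters `W_prop`, `U_prop`, `W_sim`. The propagation
head consumes the encoder's outputs through a stop-gradient so the
refinement cannot reshape the classifier it refines. The center and
contrastive terms are training-time regularizers only; decoding uses the
selection objective exclusively.

Optimization: decoupled-weight-decay Adam (weight decay 0.01, gradient
clipping at global norm 1.0), batch size 16, up to 30 epochs, early
stopping when validation exact-match F1 fails to improve for 5
consecutive epochs, best-on-validation parameters returned. An optional
`min_epochs` burn-in floor (default 1) keeps patience from firing during
the initial epochs in which a from-scratch model decodes nothing and
validation F1 is identically zero; full-size from-scratch runs set it to
15. Documents
are split 70/10/20 by default with greedy deficit allocation stratified
on each document's label multiset, so even singleton strata fill every
split proportionally. The default learning rate (3e-5) is the standard
fine-tuning magnitude for a large pretrained backbone; the from-scratch
tiny backend needs a larger step, and all in-repo runs use 1e-3–3e-3
explicitly. All randomness flows from the config seeds; two runs with
identical configs produce byte-identical logs, checkpoints and
predictions.

## Contextual Constraint Decoding

**Candidate refinement.** A span-level graph connects candidates with
`σ(r̃' W_sim r̃') ≥ ε` (default 0.7) or overlapping token intervals; the
adjacency is row-normalized and `K = 2` rounds of
`z ← σ(A W_prop z + U_prop r̃)` update the (log-probability-initialized)
scores, followed by a softmax. `K = 0` is the exact identity. Because
the update passes through a sigmoid, refined logits live in (0, 1) and
refined distributions are deliberately low-contrast; margins remain well
defined. Decoding candidates supplied without model parameters skips
the refinement rather than running it with placeholder weights.

**Ontology filtering.** Label `y` is allowed for a span iff every
sibling of `y` (same parent in the hierarchy; roots share a virtual
root) has probability below `γ = 0.5`. Labels without siblings are
always allowed; candidates with no allowed label are dropped and logged.
The allowed set is monotone nondecreasing in `γ`.

**Selection objective.** Each atom is a (candidate, allowed label) pair
scored by the NONE-margin `log P̃(y) − log P̃(NONE)` (probabilities
clamped at 1e-12). The literal sum-of-log-probabilities scoring is
available as `margin_mode="log_prob"`, but note that under it every
non-empty selection scores below the empty set whenever the context
weight is zero, since log-probabilities are nonpositive — the margin
form preserves the intended ranking. Penalties and rewards, all counted
over unordered pairs once:

* overlap: intersecting pairs with different (s, t); pairs forming a
  schema-licensed nesting — inner strictly inside outer with
  (inner_label, outer_label) a key of the nesting prior — are exempt by
  default (`overlap_mode="strict"` counts them too); weight λ₁ = 1.
* conflict: pairs whose labels are not in the admissible co-occurrence
  set C **and** that stand in a structural relation (nested, overlapping
  or abutting) — the structural indicator realizes the layout
  sensitivity of the constraint; weight λ₂ = 1. A strict mode rejects
  such pairs outright instead of penalizing.
* context reward `Σ_y η_y log(1 + Σ_{(s,t,y)} exp α_{s,t})` with
  frequency priors η (default 1) and entity-ness α; weight λ₃ = 0.1.
* nesting reward: same-label nested pairs add the schema's γ prior for
  that (inner, outer) pair.

λ defaults are package choices; nothing in the method prescribes them.

**Search.** `select_spans_exhaustive` enumerates all label-consistent
subsets (≤ 16 atoms; the verification oracle, vectorized over bitmasks).
`select_spans_beam` visits atoms in descending-margin order, keeps
`beam_width` (default 16) states by exact partial score plus an
optimistic bound (remaining positive margins — constant per depth, so it
shifts without reordering), prunes one-label-per-span violations
immediately, and rescores final states with the same vectorized scorer,
so with `beam_width ≥ 2^n` it equals the oracle exactly, tie-broken
identically (fewer spans, then lexicographic triples). The full decode
pipeline additionally drops atoms with nonpositive margin before the
search: such an atom can raise the objective only through the small λ₃
context term, and excluding it keeps beam bounds meaningful.

**Diagnostics.** The ontology projection `softmax(Ω · a(r̃))`, with Ω
the reflexive descendant matrix over the fixed (lexicographic) label
order and `a` a learned label-space adapter, is exposed as a diagnostic
score; it does not enter the selection objective by default. Ω carries
1 on the diagonal — the strict-subclass matrix has all-zero rows for
root types, which would zero their projected scores; the reflexive
closure is the minimal fix.

## Synthetic corpus generator

Each document draws a background length `L` uniformly from
`sent_len_range` (default 8–20) filled from a 27-word function/laboratory
vocabulary, then inserts `Binomial(L, mention_rate/10)` mention templates
(default rate 1.5 per 10 tokens) at distinct points, so gold mentions
never cross by construction. Templates are 1–5 token immunology surface
forms per type; cell templates containing a T-cell sub-phrase emit the
inner span as a second gold mention with probability `nest_rate`
(default 0.3), always conforming to the schema's nesting-prior keys.
With probability `ambiguity_rate` (default 0.2) a mention uses a surface
form listed under two types ("IFNG" as gene or cytokine) and a
type-specific cue token is placed immediately after it, making
disambiguation learnable with near-1.0 Bayes accuracy. Label noise
(`corrupt_labels`) flips a mention to a random sibling or drops it, each
half of the time, as a stand-in for weak supervision; labels without
siblings fall back to a random other label on the flip branch so the
configured rate is realized.

What it does **not** emulate: natural language syntax, realistic mention
frequency distributions, discontinuous mentions, crossing gold spans
(linguistically anomalous; crossings are injected only as decoder test
fixtures), or the scale and annotation idiosyncrasies of real corpora.
Passing tests on this generator demonstrates that the machinery is
correct and that the architecture can learn span boundaries, types,
nesting and cue-based disambiguation — not that it reaches any
particular accuracy on real biomedical text.

The toy schema used throughout is ENTITY-rooted with CELL (child
T_CELL), CYTOKINE, DISEASE and GENE; all cross-type pairs are admissible
except {CYTOKINE, DISEASE}, kept inadmissible deliberately so conflict
constraints are exercisable; the nesting prior licenses (T_CELL in CELL)
and (CELL in CELL).

## Numerical choices and degenerate inputs

64-bit floats everywhere; softmax computed with max subtraction;
probabilities clamped at 1e-12 before logs; parameter-free LayerNorm
(ε = 1e-5); masked softmax returns zero rows for empty neighborhoods;
empty documents decode to empty mention lists; empty candidate sets and
empty selections are valid (objective 0). Evaluation uses exact
(s, t, y) matching with set semantics; 0/0 precision or recall is
reported as 0.0 with an explicit degenerate flag so empty-prediction
runs are visible. Checkpoints are single `.npz` files embedding the
encoder config, vocabulary, label order and a schema fingerprint;
loading against a different schema fails.

## Problem sizes used by tests and the acceptance script

Beam-vs-oracle: 500 random instances with ≤ 10 atoms (exact equality)
and 200 with ≤ 12 atoms (width-16 quality). Learning: 500 training
documents, ≤ 30 epochs, evaluated on 100 held-out documents; the
exact-match F1 threshold of 0.80 is this package's own bar for "the
synthetic task is learned", not an external figure. Constraint
efficacy and the center-loss effect each use 10 seeded repetitions.
These sizes were chosen so a full run stays within minutes on one CPU
while keeping the statistical checks (3σ count bounds, 8-of-10 seed
majorities) meaningful.

## Known limitations

* The tiny backend's absolute accuracy is meaningful only on the
  synthetic task; real-corpus performance requires plugging a pretrained
  encoder into the adapter contract and fine-tuning, which is out of
  scope here.
* The sigmoid message-passing update bounds refined logits, so the
  refined distributions cannot express extreme confidence; consumers
  needing calibrated probabilities should read the raw classifier
  distributions.
* Beam search is exact only when the width covers the atom count;
  defaults favor speed (width 16), which the oracle comparison shows is
  near-optimal on instances of the tested size but carries no global
  guarantee.
* CoNLL input cannot express nesting; the reader produces flat
  documents only, and the lenient orphan-tag repair (default) silently
  opens spans where strict mode would error.
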