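# Methods

## The memory model

`chunklearn` maintains a layered sequential memory over a single input
stream.  Level 0 stores the literal input, one symbol per moment.  Each
higher layer re-represents the one below in one of two ways:

- a **chunk layer** replaces contiguous segments with superordinate symbols;
  the subtend relation Λ maps each chunk symbol to the exact subordinate
  subsequence it covers, and every moment carries a half-open span of
  base-level offsets (0-based; chosen once, since index conventions are a
  free choice).  Concatenating the grounding of any layer's moments
  reproduces the input byte-exactly — an invariant asserted throughout the
  test suite and preserved by every operation, including consolidation.
- a **categorization layer** replaces symbols with category symbols under a
  partition Π of the subordinate alphabet.  It has one moment per
  subordinate moment and *supersedes* the layer it re-represents: chained
  merges are compressed into a single categorization layer per stage, and
  whole-memory accounting (below) reads the superseding layer.  This
  compression is what makes the branch-merge arithmetic exact: merging the
  two branch symbols of `a,b,d,a,b,e` yields a memory whose total mean
  information content is exactly 0.

Layers are keyed by (δ, α): δ is a fresh dimension index allocated
sequentially for each derived layer, α the abstraction level.  With the
default text pipeline (no categorization) δ = α, mirroring the usual
presentation of stacked segmentation models.

## Information measures

Each layer is scored by a first-order (bigram) model over its own sequence,
with a start sentinel `^` prepended so the first moment has defined
information content.  For a moment τ with symbol s:

- h(τ) = −log₂ p(s | predecessor) — the surprise of the observed symbol;
- H(τ) = entropy of the successor distribution of s — the uncertainty about
  τ+1 carried by the current moment;
- h̄ = the arithmetic mean of h over the layer's moments.  Moments with
  undefined h (possible only for contexts absent from the training
  sequence) are excluded from the mean and counted separately; with static
  models trained on the layer's own sequence every moment is defined.

Two modes exist.  **Static** models use maximum-likelihood counts of the
full sequence (the post-hoc setting used for all h̄ accounting and
licensing, which keeps those decisions deterministic and order-free).
**Online** models predict before learning, with add-one smoothing over the
current alphabet plus one novelty slot; they drive boundary detection when
incremental processing is wanted.  After a full pass online counts equal
static counts, so the two modes differ only in the profiles seen
mid-sequence.

Whole-memory efficiency is Σ h̄ over *active* layers: each stage contributes
its categorization layer if one exists, else its sequence layer.  Base and
chunk layers both stay in the sum — the hierarchy is a record, not a
replacement — which is why consolidation never licenses creating new levels
(a new layer adds a positive term); level creation belongs to the waking
learning phase.

## Boundary detection and chunking

Two printed detectors are implemented verbatim:

- `simple`: flag at τ iff h(τ) < h(τ+1);
- `complex`: flag if H(τ−1) < H(τ); else flag if H(τ−1) ≥ H(τ) and
  h(τ) < h(τ+1); else no flag.

Where a referenced value is undefined (sequence edges, unseen contexts) no
boundary is asserted.  The formulas reference a *future* rise while the
prose reading would have the flagged moment start a segment; both readings
cannot hold at once, so the placement is explicit configuration:
`boundary_shift=False` (default) closes the current segment after a flagged
moment; `boundary_shift=True` is the literal "τ starts a segment" reading.
Chunk identity is by subtended content (the equality setting used by the
reference word-segmentation study), so recurring segments reuse one symbol.
Hierarchy construction repeats segmentation upward until a layer stops
compressing or `max_levels` (default 8) is reached.

## Semantic spaces and categorization

A space holds one point per alphabet symbol plus an inner product from a
small library (`dot`, `cosine`, `diag`), whose induced norm defines
distance; concept prototypes are member centroids.  Trajectories of
subordinate points are abstracted to fixed-length points by a
per-dimension discrete Fourier transform, keeping `spectral_k` (default 4)
coefficients as interleaved real/imaginary parts — so sequences of any
length live in one metric space.  The transform is a pluggable choice;
Fourier is the default because it is the canonical example of such an
abstraction.

A merge of two symbols is licensed only if (1) the layer's h̄ strictly
decreases (tolerance 1e-9), and (2) the convexity gate passes: no outside
point may lie within the candidate set's hull, approximated as the ball
around the centroid of radius (max member-to-centroid distance + ρ).
Larger ρ therefore rejects more aggressively, and rejection is monotone in
ρ.  The ball approximation is one admissible reading of "a convex hull
extended by ρ"; exact hulls in high dimension are not warranted at this
level of specification.

Candidate generation follows the shared-predecessor heuristic: pairs with a
common predecessor first, ordered by decreasing maximum moment-wise h of
their occurrences (the aggregation over occurrences is our choice; ties
break by earliest occurrence), then remaining pairs involving the newest
symbol.  The greedy step evaluates all candidates and applies the best
licensed Δh̄.  This matches an exhaustive search over *all* symbol pairs:
a pair with disjoint predecessor sets leaves the predecessor side of the
tally unchanged and can only pool successor distributions, which never
beats separate maximum-likelihood fits — so the optimum is always a
shared-predecessor pair (verified against brute force on random sequences
in the suite).

Space modes: `equality` (text default) licenses only identical symbols —
i.e. categorization is off, matching the segmentation-only reference
implementation; without this brake, Δh̄-only licensing would collapse any
alphabet to a single vacuous category.  `indicator` places symbols at
orthonormal indicator points (the gate is then neutral at small ρ), and
`custom` uses user-supplied points, enabling genuine convexity vetoes.

## Consolidation

Off-line consolidation heuristically minimizes Σ h̄ under an iteration
budget (a deterministic proxy for available time; wall-clock budgets are
out of scope).  Each iteration ranks the symbols of all active layers by
their highest-h moment (ties: lower level, then earlier occurrence) and,
walking down that order, attempts for each symbol:

1. **categorization** — the best layer-locally licensed merge involving it;
2. **re-categorization** — splitting its category two ways; the proposal
   groups members around the two whose successor distributions diverge most
   (total variation), a mechanism left open by the underlying account and
   chosen here for determinism;
3. **re-segmentation** — splitting the chunk it names, or a chunk containing
   it, wherever boundary flags now fire at chunk-internal positions under
   the current model of the source layer.

The first success is adopted and the loop restarts from the new ranking;
if nothing applies the memory is stable and the run ends (running again
applies zero operations).  Every attempt executes on a trial copy,
including the upward ripple — all stages above the modified layer are
rebuilt — and is adopted only if Σ h̄ does not increase (strict decrease for
the two categorization kinds, non-strict for segment revision, whose gain
may be structural).  The truncate-and-rebuild ripple is coarser than a
span-local recompute but semantically equivalent and fast at the scales the
generators produce.

## Synthetic corpora

The word-segmentation generator concatenates a fixed vocabulary without
delimiters, sampling tokens by Zipf-weighted frequencies (exponent 1.0 by
default, mimicking natural token-frequency skew; vocabulary sizes 10–100
and word lengths 2–9 keep bigram statistics informative at desk scale).
Gold spans tile the stream exactly and generation is byte-deterministic per
seed.

The prefix scenario instantiates the re-segmentation study: phase 1
contains each adjective and its fused negated form ("in"+adjective) among
fillers engineered, from exact count inequalities fixed in advance, so that
h(n|i) = log₂ 7 bits exceeds the within-form h(first|n) = log₂ n — no
boundary fires inside a fused form and all 2n content forms are stored
whole.  Phase 2 adds free-standing "in" (always followed by fillers) plus
bare adjectives, reversing the inequality; consolidation then splits every
stored fused chunk at the prefix edge, leaving n+1 relevant symbols.
Supported n is 2–5 (disjoint letter pools).

What the generators do *not* emulate: real orthography (letter frequencies,
shared morphology between words), long-range dependencies, noise or
approximate repetition.  A green segmentation test therefore establishes
that the mechanism extracts the statistical word structure the model
assumes, not that it competes on natural-language benchmarks; runs on real
text are supported through `ingest_text`/`ingest_file` but are
version-sensitive and outside the test suite.

## Evaluation

A gold token is found at level α when some moment at that level spans the
token's characters exactly; each token is credited once, at the lowest such
level, and scores count tokens (positions), not types.  Baseline A places
n−1 distinct boundaries uniformly at random (collisions are avoided by
sampling without replacement — the source account is silent on them);
baseline B marks each of the L−1 interior positions independently with
probability (n−1)/(L−1).  Both are single-level segmentations scored the
same way, averaged over 100 repetitions, deterministic per seed.

## Numerical conventions

Probabilities and logarithms in double precision; h̄ comparisons use an
absolute tolerance of 1e-9; certain transitions yield h = +0.0 (never
−0.0); unseen static transitions give h = ∞ and unseen contexts an explicit
undefined signal rather than 0.  Serialization fixes key order, so a
memory's JSON round-trips bit-exactly.

## Known limitations

- Single input stream; no real-time durations, no multimodal association.
- First-order models only — no higher-order n-grams or escape blending, and
  no cross-layer modulation of distributions.
- No forgetting: the literal record persists by design.
- The convexity gate uses the centroid-ball approximation, not exact hulls.
- Consolidation's search is greedy and budgeted; it reaches a local, not
  global, optimum of Σ h̄.
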