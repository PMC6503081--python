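# chunklearn

Hierarchical statistical sequence memory for unsupervised segmentation
studies: boundary-entropy chunking, information-efficiency-licensed
categorization, and off-line memory consolidation as re-representation.

## The problem

How can a learner with no lexicon discover words (or motifs, or phrases) in
an undelimited symbol stream — and later *revise* those discoveries when new
evidence arrives?  `chunklearn` implements a cognitive-modelling answer: a
layered memory that keeps a literal record of its input and re-represents it
upward, using only first-order transition statistics and two
information-theoretic licensing rules.  It is aimed at researchers in
computational cognitive modelling and unsupervised sequence learning who
want a small, fully tested, deterministic implementation to experiment with.

## The model

For each layer (an alphabet *A* with a symbol sequence), a bigram model with
a start sentinel `^` gives, at every moment τ:

- **entropy** H(τ) = −Σ p log₂ p over the successor distribution of the
  symbol at τ — uncertainty about what comes next;
- **information content** h(τ) = −log₂ p(s_τ | s_{τ−1}) — surprise of what
  actually occurred;
- **h̄**, the layer's mean information content, the quantity every
  re-representation must respect.

Three mechanisms build and maintain the hierarchy:

1. **Chunking.** A boundary detector Δ flags moments from the profiles
   (`simple`: h rises; `complex`: H rises, or H falls while h rises).
   Segments become superordinate chunk symbols, linked to their subtended
   subsequence (the Λ relation).  Spans ground every chunk in the raw input,
   losslessly.
2. **Categorization.** Symbol pairs sharing a predecessor are merge
   candidates; a merge is licensed only if h̄ strictly decreases *and* the
   resulting region in semantic space is convex within radius ρ (points are
   built by per-dimension Fourier abstraction of subordinate trajectories,
   so sequences of any length are comparable).  Accepted merges re-represent
   the layer under a partition (the Π relation).
3. **Consolidation.** Off-line, the loop takes the highest-h symbol,
   attempts categorization, then (re-)segmentation around it, restarting on
   success — including *splitting* categories and chunks when new evidence
   warrants it.  Every accepted operation must not increase Σ h̄ over the
   whole memory, and changes ripple upward through rebuilt layers.

## Worked example

```python
from chunklearn import RunConfig, apply_merge, best_licensed_merge, memory_from_symbols

memory = memory_from_symbols("abdabe", RunConfig(space_mode="indicator"))
print(memory.total_mean_ic())          # 0.3333...
best = best_licensed_merge(memory, 0)  # pair ('d', 'e'), delta -1/3 bit
apply_merge(memory, 0, best.pair)
print(memory.effective_layer(0).sequence())
print(memory.total_mean_ic())          # 0.0
```

prints

```
0.3333333333333333
['a', 'b', '{d|e}', 'a', 'b', '{d|e}']
0.0
```

In `a,b,d,a,b,e` the only uncertainty is which of `d`/`e` follows `b`
(1 bit at two of six moments, so h̄ = 1/3).  Merging the two branch symbols
into the category `{d|e}` makes every transition certain: h̄ drops to
exactly 0, which is why the merge is licensed.  Merging `(a, b)` instead
would *raise* h̄ by 2/3 bit and is rejected.

The `examples/` directory holds one short script per capability — hierarchy
building, merge licensing, prefix discovery by consolidation, segmentation
scoring against chance baselines, and semantic-space geometry — each
printing the numbers it computes and what they mean.  A flavour of
`examples/03_consolidation_prefix.py`: after a phase in which five negated
adjectives are only ever seen fused ("inbcd" …), evidence of free-standing
"in" lets consolidation split every stored chunk at the prefix edge,
shrinking the relevant lexicon from 2n = 10 symbols to n + 1 = 6 while
Σ h̄ falls monotonically.

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantity from
scratch — it builds the six-symbol toy, lets the categorizer find and
license the branch merge itself, and measures the re-represented memory's
mean information content — and writes the result as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/chunklearn/` — `memory` (layers, spans, Π/Λ, serialization),
  `bigram` (H, h, h̄), `chunker`, `spaces`, `categorize`, `consolidate`,
  `hierarchy` (learn/extend), `corpus` (synthetic generators), `evaluate`
  (token scoring, chance baselines), `textio` (ingestion, persistence).
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — the model, its parameters, numerical conventions and
  known limitations.
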