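"""License a category merge on the six-symbol toy.

In the sequence a,b,d,a,b,e the only uncertainty is which of d or e follows
b (1 bit each time).  Merging d and e into one category removes it, so the
merge is licensed: mean information content h-bar falls from 1/3 bit to 0.
Merging an arbitrary early pair instead would create new branching and is
rejected.
"""

from chunklearn import (RunConfig, apply_merge, best_licensed_merge,
                        memory_from_symbols, merge_delta_hbar)

memory = memory_from_symbols("abdabe", RunConfig(space_mode="indicator"))
print("sequence:", "".join(memory.layers[memory.base_key].sequence()))
print(f"h-bar before any merge: {memory.total_mean_ic():.4f} bits")

best = best_licensed_merge(memory, 0)
print(f"\nbest licensed merge: {best.pair}, "
      f"delta h-bar = {best.delta_hbar:+.4f} bits, "
      f"convexity ok = {best.convexity_ok}")

apply_merge(memory, 0, best.pair)
print("re-represented sequence:", memory.effective_layer(0).sequence())
print(f"h-bar after the merge: {memory.total_mean_ic():.4f} bits")

delta_ab = merge_delta_hbar(list("abdabe"), ("a", "b"))
print(f"\nfor contrast, merging (a, b) would change h-bar by {delta_ab:+.4f} "
      "bits\nand is therefore rejected by the licensing rule.")
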