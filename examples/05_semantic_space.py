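"""Semantic spaces: abstract trajectories to points, gate categorization.

A trajectory of vectors (a symbol sequence's path through the space below)
is abstracted by a discrete Fourier transform to a fixed-length point, so
sequences of different lengths become comparable.  The convexity gate then
vetoes categories that would enclose an unrelated symbol.
"""

from chunklearn import (ConvexityParams, SemanticSpace, convexity_gate,
                        spectral_abstract)

short = spectral_abstract([[1.0, 0.0]], k=2)
long_ = spectral_abstract([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]], k=2)
print("abstracted points have equal dimension regardless of length:")
print(f"  1-step trajectory -> {short.shape[0]}-d point {short.round(2)}")
print(f"  3-step trajectory -> {long_.shape[0]}-d point {long_.round(2)}")

space = SemanticSpace({"warm": [1.0], "hot": [1.2], "cold": [5.0]})
ok = convexity_gate(space, ["warm", "hot"], ConvexityParams(rho=0.5))
print(f"\n{{warm, hot}} with 'cold' far away: gate = {ok} (licensed)")

space2 = SemanticSpace({"warm": [1.0], "hot": [2.0], "tepid": [1.5]})
ok2 = convexity_gate(space2, ["warm", "hot"], ConvexityParams(rho=0.5))
print(f"{{warm, hot}} with 'tepid' in between: gate = {ok2} (vetoed - the"
      "\nregion would not be convex, so the concept is rejected).")
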