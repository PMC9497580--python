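"""Simple vs entropy-weighted averaging of classifier probabilities.

The entropy-weighted combination multiplies each classifier's vote by its
confidence weight 1 - H(p), so a classifier sitting at p = 0.5 contributes
nothing, while confident classifiers dominate.
"""

import numpy as np

from cxrtransfer import binary_entropy, entropy_weighted_average, simple_average

# three classifiers, one label: two confident, one clueless
P = np.array([[0.92], [0.88], [0.50]])

simple = simple_average(P).scores[0]
literal = entropy_weighted_average(P).scores[0]
normed = entropy_weighted_average(P, normalize=True).scores[0]

print("classifier probabilities:", P.ravel())
print("confidence weights 1-H(p):", np.round(1 - binary_entropy(P.ravel()), 3))
print(f"simple average:              {simple:.4f}")
print(f"entropy-weighted (literal):  {literal:.4f}  (range [0, K], ranking only)")
print(f"entropy-weighted (normalized): {normed:.4f}")
print("-> the clueless p=0.5 classifier drags the simple average down but is"
      " ignored by the entropy weighting.")
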