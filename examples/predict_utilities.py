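"""Predicted utilities for the nine DS3-based health states.

Evaluates the utility regression at the estimation-sample covariate means
(recycled predictions).  The printed values are EQ-5D UK utilities: 1 is
full health, 0 is dead; every state sits well below the UK population norm
of 0.86, and the spread from mild (~0.77) to severe-with-SSC (~0.52) shows
the burden skeletal complications add.
"""

from ds3markov import STATE_LABELS, default_utility_coefficients, utility_table

utilities = utility_table(default_utility_coefficients())
for label, u in zip(STATE_LABELS, utilities):
    print(f"{label:12s} {u:.4f}")
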