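"""Score cancellation sheets with the Center of Cancellation (CoC).

Builds two symmetric sheets for one fictitious patient — a complete
performance and a left-sided-omission performance — then applies the
mean-CoC rule, the neglect cutoff, and the regression-target transform.
"""

import numpy as np

from neglectwmh import (
    CancellationSheet,
    center_of_cancellation,
    classify_neglect,
    mean_coc,
    prepare_target,
)

x = np.linspace(-0.9, 0.9, 30)  # normalized horizontal target positions

complete = CancellationSheet(x, np.ones_like(x, dtype=bool))
left_neglect = CancellationSheet(x, x > -0.3)  # misses everything left of -0.3

coc_letter = center_of_cancellation(left_neglect)
coc_bells = center_of_cancellation(complete)
mean_score = mean_coc(coc_letter, coc_bells)

print(f"letter CoC (left omissions): {coc_letter:+.3f}")
print(f"bells CoC (complete):        {coc_bells:+.3f}")
print(f"mean CoC:                    {mean_score:+.3f}")
print(f"neglect (cutoff 0.082):      {classify_neglect(mean_score)}")
print(f"regression target sqrt(max(CoC,0)): {prepare_target(mean_score):.3f}")
# Positive CoC means cancelled targets sit right of the sheet centre, i.e.
# left-sided omissions; the mean over both tests is the severity measure the
# models predict, after clamping negatives and taking the square root.
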