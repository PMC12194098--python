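"""Default rater parameter presets for the synthetic generator.

Two rosters of graded-response raters in slope-intercept form, chosen to
reflect realistic severity spread on a 1-5 creativity scale: three raters
who score individual responses (one notably severe at the top of the
scale, d4 = -8.14) and five raters who score whole ideational pools
(snapshot scoring; more homogeneous severity).  Lower (more negative)
intercepts mean a rater demands more of the latent trait before granting
the next category.
"""

from __future__ import annotations

from .irt import RaterParams

#: three raters scoring each response individually
INDIVIDUAL_RATERS = (
    RaterParams("R1", 2.26, d=(1.83, -0.87, -3.12, -5.48)),
    RaterParams("R2", 2.26, d=(3.43, -1.07, -5.33, -8.14)),
    RaterParams("R3", 2.51, d=(4.24, 1.34, -1.21, -3.84)),
)

#: five raters scoring each participant-task ideational pool holistically
SNAPSHOT_RATERS = (
    RaterParams("S1", 2.71, d=(5.09, 1.20, -1.26, -4.45)),
    RaterParams("S2", 3.24, d=(7.39, 2.36, -1.43, -5.70)),
    RaterParams("S3", 2.84, d=(7.27, 2.44, -1.14, -5.29)),
    RaterParams("S4", 2.41, d=(4.17, 1.18, -1.86, -5.10)),
    RaterParams("S5", 2.80, d=(5.05, 0.72, -2.47, -5.33)),
)
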