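"""Published field-study summary statistics used as inputs.

Clutch morphology of the two study species at embryo age 3 days, as
mean / SD / range summaries over the clutches used in the excitation tests
(17 A. callidryas, 16 A. spurrelli).  These printed summaries are inputs to
the closed-form Welch comparisons; the raw per-clutch measurements were
never published, so t statistics recomputed from them agree with the
published ones only to the rounding of the table (~1e-3 absolute).
"""

from __future__ import annotations

from .cohort_stats import GroupSummary

__all__ = ["CLUTCH_DIMENSIONS"]

#: variable -> {species label -> GroupSummary}.  Units: clutch size in eggs,
#: length/width/thickness in mm.
CLUTCH_DIMENSIONS: dict[str, dict[str, GroupSummary]] = {
    "clutch_size": {
        "A_callidryas": GroupSummary(n=17, mean=40.12, sd=9.79, min=24, max=57),
        "A_spurrelli": GroupSummary(n=16, mean=33.25, sd=7.97, min=20, max=48),
    },
    "length_mm": {
        "A_callidryas": GroupSummary(n=17, mean=46.26, sd=8.16, min=32.9, max=59.7),
        "A_spurrelli": GroupSummary(n=16, mean=43.68, sd=6.36, min=33.4, max=55.4),
    },
    "width_mm": {
        "A_callidryas": GroupSummary(n=17, mean=23.94, sd=4.27, min=16.4, max=30.9),
        "A_spurrelli": GroupSummary(n=16, mean=20.40, sd=3.41, min=16.0, max=28.3),
    },
    "thickness_mm": {
        "A_callidryas": GroupSummary(n=17, mean=9.42, sd=1.26, min=7.2, max=12.4),
        "A_spurrelli": GroupSummary(n=16, mean=7.78, sd=1.12, min=5.8, max=10.1),
    },
}
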