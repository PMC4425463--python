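"""Small built-in example datasets.

The stratified cohort summary below is the worked example used in the
README and the reproduction script: normalized marker levels (mean, SE
of the mean, group size) for depression cases and controls within
strata of reported stressful-life-event count, as published for a large
case-control cohort of 11,670 women.  Feeding each row through
:func:`somamark.conditional_inference.summary_t` recomputes the
case-control t statistics of the original table from its printed
summaries alone.
"""

from __future__ import annotations

import pandas as pd

_STRATA_ROWS = [
    # marker, sle stratum, control mean, control se, control n,
    #                      case mean,    case se,    case n
    ("mtdna", "0",  -0.132, 0.019, 2487,  0.142, 0.024, 1689),
    ("mtdna", "1",  -0.156, 0.026, 1432,  0.0987, 0.027, 1441),
    ("mtdna", "2",  -0.103, 0.034,  757,  0.165, 0.033,  935),
    ("mtdna", "3",  -0.068, 0.058,  334,  0.085, 0.044,  507),
    ("mtdna", "4+",  0.062, 0.067,  221,  0.132, 0.040,  666),
    ("telomere", "0",  0.078, 0.020, 2542, -0.053, 0.025, 1722),
    ("telomere", "1",  0.098, 0.026, 1461, -0.048, 0.027, 1470),
    ("telomere", "2",  0.093, 0.035,  780, -0.069, 0.032,  952),
    ("telomere", "3",  0.042, 0.053,  342, -0.085, 0.045,  517),
    ("telomere", "4+", 0.060, 0.060,  229, -0.129, 0.038,  677),
]


def example_cohort_strata() -> pd.DataFrame:
    """Published stratified case-control summaries of the two
    normalized markers (see module docstring)."""
    return pd.DataFrame(
        _STRATA_ROWS,
        columns=["marker", "sle", "control_mean", "control_se", "control_n",
                 "case_mean", "case_se", "case_n"])
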