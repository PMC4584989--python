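"""Sociodemographic table of the emulated study sample (N = 40).

Counts are packaged so the printed percentages can be recomputed and
checked; `demographics_table` recomputes each proportion from its count.
"""

from __future__ import annotations

import pandas as pd

COHORT_N = 40

# (category, level, count n, printed percent)
DEMOGRAPHICS = [
    ("gender", "male", 33, 82.5),
    ("gender", "female", 7, 17.5),
    ("age_group", "21-25", 22, 55.0),
    ("age_group", "26-30", 11, 27.5),
    ("age_group", "31-35", 7, 17.5),
    ("education", "high_school_diploma", 11, 27.5),
    ("education", "some_college_university", 27, 67.5),
    ("education", "university_degree", 2, 5.0),
    ("hormonal_contraceptive", "yes", 4, 10.0),
    ("life_stress", "yes", 5, 12.5),
    ("gaming_hours_per_week", "under_3", 16, 40.0),
    ("gaming_hours_per_week", "3-9", 15, 37.5),
    ("gaming_hours_per_week", "10-16", 7, 17.5),
    ("gaming_hours_per_week", "17_or_more", 2, 5.0),
]


def demographics_table() -> pd.DataFrame:
    """The sample's demographic counts with percentages recomputed as
    ``100 * n / N``, alongside the printed percentages."""
    df = pd.DataFrame(DEMOGRAPHICS,
                      columns=["category", "level", "n", "printed_pct"])
    df["recomputed_pct"] = 100.0 * df["n"] / COHORT_N
    return df
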