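"""Published baseline-characteristics counts for descriptive-table arithmetic.

A frequency table from a large consumer-wearable/EHR linkage cohort
(6,042 participants included in analysis, 208,164 EHR-sharing participants
excluded), bundled so the package's percentage arithmetic for cohort
descriptives can be validated against independently printed values: each row
carries the raw count and the percentage as printed in the source table,
and ``recompute_percentages`` re-derives the percentage from the count.
"""

from __future__ import annotations

import pandas as pd

N_INCLUDED = 6042
N_EXCLUDED = 208164

# variable, category, n_included, printed_pct_included, n_excluded, printed_pct_excluded
_ROWS = [
    ("race", "black", 336, 5.6, 45661, 21.9),
    ("race", "other", 309, 5.1, 11112, 5.3),
    ("race", "white", 5072, 83.9, 108141, 51.9),
    ("sex", "female", 4379, 72.5, 126159, 60.6),
    ("sex", "male", 1579, 26.1, 77969, 37.5),
    ("ethnicity", "hispanic", 376, 6.2, 41638, 20.0),
    ("ethnicity", "not_hispanic", 5590, 92.5, 160368, 77.0),
    ("education", "college", 4317, 71.4, 82407, 39.6),
    ("education", "some_college", 1346, 22.3, 53973, 25.9),
    ("education", "no_college", 356, 5.9, 66925, 32.2),
    ("cad", "yes", 170, 2.8, 14684, 7.1),
    ("cancer", "yes", 1429, 23.7, 58050, 27.9),
    ("smoking", ">=100_cigarettes", 1932, 32.0, 84466, 40.6),
    ("alcohol", ">=1_drink", 5846, 96.8, 177735, 85.4),
    ("missing", "race", 325, 5.4, 43250, 20.8),
    ("missing", "sex", 84, 1.4, 4036, 1.9),
    ("missing", "ethnicity", 76, 1.3, 6158, 3.0),
    ("missing", "bmi", 2644, 43.8, 51496, 24.7),
    ("missing", "smoking", 108, 1.8, 6094, 2.9),
    ("missing", "education", 23, 0.4, 4859, 2.3),
    ("missing", "alcohol", 31, 0.5, 6477, 3.1),
]


def baseline_counts() -> pd.DataFrame:
    """The bundled counts table with printed percentages."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "variable",
            "category",
            "n_included",
            "printed_pct_included",
            "n_excluded",
            "printed_pct_excluded",
        ],
    )


def recompute_percentages() -> pd.DataFrame:
    """Re-derive percentages from raw counts (denominator = group size)."""
    t = baseline_counts()
    t["pct_included"] = 100.0 * t["n_included"] / N_INCLUDED
    t["pct_excluded"] = 100.0 * t["n_excluded"] / N_EXCLUDED
    t["abs_err_included"] = (t["pct_included"] - t["printed_pct_included"]).abs()
    t["abs_err_excluded"] = (t["pct_excluded"] - t["printed_pct_excluded"]).abs()
    return t
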