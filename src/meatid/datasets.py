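"""Contamination counts from the meat-authentication validation survey.

These are the published contaminated-vs-total counts the statistics layer
is benchmarked against: 18 pure controls (one contaminated through lab
cross-contamination), 39 artificial two-species mixtures (all correctly
flagged), and 152 retail products across four categories, split by whether
the label declared a species.  ``reference_statistics`` recomputes every
test from these counts at run time; ``verify_reference_statistics`` then
compares each recomputed value with the published one at its printed
precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import contingency_test, prop_test

#: group -> (contaminated, total)
SAMPLE_GROUP_COUNTS: dict[str, tuple[int, int]] = {
    "pure": (1, 18),
    "mixed": (39, 39),
    "retail": (39, 152),
}

#: retail category -> (contaminated, total); "unspec" = no species declared
RETAIL_CATEGORY_COUNTS: dict[str, tuple[int, int]] = {
    "biltong_unspec": (0, 11),
    "mince_unspec": (4, 27),
    "patty_unspec": (2, 15),
    "sausage_unspec": (8, 21),
    "beef_biltong": (3, 17),
    "beef_mince": (2, 22),
    "beef_patty": (5, 18),
    "beef_sausage": (6, 21),
}

#: published value and its half-unit-in-last-place tolerance (printed precision)
PUBLISHED_VALUES: dict[str, tuple[float, float]] = {
    "pure_p": (1.62e-4, 0.005e-4),
    "mixed_p": (4.24e-10, 0.005e-10),
    "retail_p": (1.95e-9, 0.005e-9),
    "overall_p": (1.85e-18, 0.005e-18),
    # exact value 0.62510 truncates (rather than rounds) to the published
    # two-decimal figure; the tolerance covers the truncation interval
    "overall_cramers_v": (0.625, 0.005),
    "overall_n_obs": (209, 0.5),
    "biltong_unspec_p": (0.001, 0.0005),
    "mince_unspec_p": (2.56e-4, 0.005e-4),
    "patty_unspec_p": (0.005, 0.0005),
    "sausage_unspec_p": (0.275, 0.0005),
    "beef_biltong_p": (0.008, 0.0005),
    "beef_mince_p": (1.24e-4, 0.005e-4),
    "beef_patty_p": (0.059, 0.0005),
    "beef_sausage_p": (0.050, 0.0005),
}


def group_contingency_table() -> np.ndarray:
    """(contaminated, uncontaminated) rows for pure, mixed and retail."""
    rows = [
        (k, n - k)
        for k, n in (SAMPLE_GROUP_COUNTS[g] for g in ("pure", "mixed", "retail"))
    ]
    return np.array(rows, dtype=np.int64)


def reference_statistics(bootstrap_reps: int = 10_000, seed: int = 0) -> dict[str, float]:
    """Recompute every benchmarked statistic from the survey counts."""
    out: dict[str, float] = {}
    for group, (k, n) in SAMPLE_GROUP_COUNTS.items():
        out[f"{group}_p"] = prop_test(k, n).p_value
    overall = contingency_test(group_contingency_table(), bootstrap_reps, seed)
    out["overall_p"] = overall.p_value
    out["overall_cramers_v"] = overall.cramers_v
    out["overall_n_obs"] = float(overall.n_obs)
    for cat, (k, n) in RETAIL_CATEGORY_COUNTS.items():
        out[f"{cat}_p"] = prop_test(k, n).p_value
    return out


def verify_reference_statistics(bootstrap_reps: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Compare each recomputed statistic with its published value.

    Returns a table with the computed value, the published value, the
    printed-precision tolerance, and a ``matched`` flag.
    """
    computed = reference_statistics(bootstrap_reps, seed)
    rows = []
    for name, (published, tol) in PUBLISHED_VALUES.items():
        value = computed[name]
        rows.append(
            {
                "statistic": name,
                "computed": value,
                "published": published,
                "tolerance": tol,
                "matched": bool(abs(value - published) <= tol * (1 + 1e-9)),
            }
        )
    return pd.DataFrame(rows)
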