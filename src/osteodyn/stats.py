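"""Group summaries (mean ± SD) and two-tailed two-sample t tests.

Welch's test is the default (robust to unequal variances); the
pooled-variance Student test is available by flag. Significance is judged
at α = 0.05 and reported alongside, never embedded in, the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "summarize", "two_tailed_t_test", "comparison_table"]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    group_name: str
    n: int
    mean: float
    sd: float
    sd_defined: bool  # False for n == 1, where sd is reported as 0 with this flag


def summarize(values, group_name: str = "") -> GroupSummary:
    """Arithmetic mean and sample (n−1) standard deviation."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    sd_defined = arr.size >= 2
    return GroupSummary(
        group_name=group_name,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if sd_defined else 0.0,
        sd_defined=sd_defined,
    )


def two_tailed_t_test(group_a, group_b, variant: str = "welch"):
    """Two-tailed two-sample t test; returns ``(t_statistic, p_value)``."""
    a = np.asarray(list(group_a), dtype=np.float64)
    b = np.asarray(list(group_b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"t test needs n >= 2 in each group (got {a.size} and {b.size})"
        )
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def comparison_table(groups: dict[str, list[float]], reference: str,
                     variant: str = "welch") -> pd.DataFrame:
    """Pairwise tests of every group against a reference group.

    One row per comparison with both groups' n, mean ± SD, t, p and the
    α = 0.05 significance call.
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not in groups")
    ref = groups[reference]
    ref_summary = summarize(ref, reference)
    rows = []
    for name, values in groups.items():
        if name == reference:
            continue
        s = summarize(values, name)
        t, p = two_tailed_t_test(values, ref, variant=variant)
        rows.append({
            "comparison": f"{name} vs {reference}",
            "n_a": s.n, "mean_a": s.mean, "sd_a": s.sd,
            "n_b": ref_summary.n, "mean_b": ref_summary.mean, "sd_b": ref_summary.sd,
            "t": t, "p": p, "significant": p < ALPHA,
        })
    return pd.DataFrame(rows, columns=["comparison", "n_a", "mean_a", "sd_a",
                                       "n_b", "mean_b", "sd_b", "t", "p",
                                       "significant"])
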