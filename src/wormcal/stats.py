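"""Group-comparison statistics used in the reporting stage.

Thin wrappers over scipy and statsmodels matching the conventions used
for event-locked calcium data and turn-success proportions: pooled-variance
two-tailed Student's t-test for two groups, one-way ANOVA with Tukey's HSD
for several, and pairwise 2x2 chi-squared tests with Holm or Bonferroni
correction for proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float
    values: list[float]


def summarize_group(label: str, values: Sequence[float]) -> GroupSummary:
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size >= 2 else 0.0
    return GroupSummary(label, int(v.size), float(v.mean()) if v.size else np.nan,
                        sem, v.tolist())


def compare_two(a: Sequence[float], b: Sequence[float],
                welch: bool = False) -> tuple[float, float]:
    """Two-tailed Student's t-test (pooled variance by default; set
    ``welch=True`` for unequal variances).  Returns ``(t, p)``; two groups
    with zero pooled variance and equal means give ``(0, 1)``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def compare_many(groups: Sequence[Sequence[float]],
                 labels: Sequence[str] | None = None):
    """One-way ANOVA plus Tukey HSD pairwise comparisons.

    Returns ``(F, p, table)`` where ``table`` is a DataFrame with one row
    per pair: group1, group2, meandiff, p_adj, reject.
    """
    import pandas as pd
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(groups) < 3:
        raise ValueError("need at least 3 groups (use compare_two otherwise)")
    arrays = [np.asarray(g, float) for g in groups]
    if any(g.size < 2 for g in arrays):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"g{i}" for i in range(len(arrays))]
    F, p = sps.f_oneway(*arrays)
    values = np.concatenate(arrays)
    codes = np.concatenate([[lab] * g.size for lab, g in zip(labels, arrays)])
    tk = pairwise_tukeyhsd(values, codes)
    table = pd.DataFrame(
        tk.summary().data[1:],
        columns=[str(c) for c in tk.summary().data[0]],
    )[["group1", "group2", "meandiff", "p-adj", "reject"]].rename(
        columns={"p-adj": "p_adj"}
    )
    # recompute adjusted p at full precision (the summary table rounds)
    table["p_adj"] = tk.pvalues
    return float(F), float(p), table


def compare_proportions(
    successes: Sequence[int],
    totals: Sequence[int],
    labels: Sequence[str] | None = None,
    correction: str = "holm",
    yates: bool = False,
):
    """Pairwise 2x2 chi-squared tests across groups with multiplicity
    correction (``holm`` or ``bonferroni``).

    Returns a DataFrame with chi2, raw and adjusted p per pair; pairs with
    an expected cell count below 1 are flagged in ``warning``.
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    successes = list(successes)
    totals = list(totals)
    if any(s < 0 or s > t for s, t in zip(successes, totals)):
        raise ValueError("require 0 <= successes <= totals")
    if labels is None:
        labels = [f"g{i}" for i in range(len(totals))]
    rows = []
    for i in range(len(totals)):
        for j in range(i + 1, len(totals)):
            table = np.array(
                [[successes[i], totals[i] - successes[i]],
                 [successes[j], totals[j] - successes[j]]], float
            )
            chi2, p, _, expected = sps.chi2_contingency(table, correction=yates)
            rows.append(
                {
                    "group1": labels[i], "group2": labels[j],
                    "chi2": float(chi2), "p_raw": float(p),
                    "warning": "low expected count" if expected.min() < 1 else "",
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        method = {"holm": "holm", "bonferroni": "bonferroni"}[correction]
        df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method=method)[1]
    return df
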