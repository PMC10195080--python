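"""Group comparisons: Welch's t-test and one-way ANOVA.

These are the two tests used for planned comparisons throughout the
pipeline (e.g. initial- vs final-phase event counts, per-direction
stable-branch counts across the four sectors).  Degenerate inputs with
zero within-group variance are resolved by convention rather than
propagating NaN: identical groups give p = 1; distinct means with zero
variance give p = 0 flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ArbordynError, InsufficientDataError


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    df: tuple[float, ...]
    p: float
    degenerate: bool = False


def _as_groups(values: Sequence[Sequence[float]]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in values]
    for g in groups:
        if g.size < 2:
            raise InsufficientDataError("each group needs at least 2 values")
    return groups


def compare_groups(
    values: Sequence[Sequence[float]], test: str = "t_test"
) -> GroupComparison:
    """Two-sided Welch t-test (two groups) or one-way ANOVA (≥2 groups).

    Zero within-group variance in every group: p = 1 if all means are
    equal (no evidence of difference), else p = 0 with ``degenerate``
    set (infinitely strong separation under the model).
    """
    groups = _as_groups(values)
    if test == "t_test":
        if len(groups) != 2:
            raise ArbordynError("t_test requires exactly two groups")
        a, b = groups
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 and vb == 0:
            if a.mean() == b.mean():
                return GroupComparison("t_test", 0.0, (float(a.size + b.size - 2),), 1.0, True)
            return GroupComparison("t_test", float("inf"), (float(a.size + b.size - 2),), 0.0, True)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        sa, sb = va / a.size, vb / b.size
        df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
        return GroupComparison("t_test", float(t), (float(df),), float(p))
    if test == "anova":
        if len(groups) < 2:
            raise ArbordynError("anova requires at least two groups")
        if all(g.var(ddof=1) == 0 for g in groups):
            means = [g.mean() for g in groups]
            k = len(groups)
            n = sum(g.size for g in groups)
            dfs = (float(k - 1), float(n - k))
            if all(m == means[0] for m in means):
                return GroupComparison("anova", 0.0, dfs, 1.0, True)
            return GroupComparison("anova", float("inf"), dfs, 0.0, True)
        f, p = sps.f_oneway(*groups)
        k = len(groups)
        n = sum(g.size for g in groups)
        return GroupComparison("anova", float(f), (float(k - 1), float(n - k)), float(p))
    raise ArbordynError(f"unknown test {test!r}")
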