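"""Group-comparison statistics for per-movie / per-cone / per-image values.

Normality is screened with a one-sample Kolmogorov–Smirnov test against a
normal law with the sample's own mean and SD. Group comparisons use one-way
ANOVA with Bonferroni-adjusted pairwise t-tests when every group passes
normality, otherwise a Kruskal–Wallis omnibus followed by pairwise
Mann–Whitney U tests with Bonferroni adjustment. Results carry the
significance tier (* p<=0.05 ... **** p<=1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "normality_check",
    "compare_groups",
    "significance_tier",
    "results_table",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    test: str
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    n_a: int
    n_b: int
    significance: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0 or not 0.0 <= self.p_adjusted <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted + 1e-12 < self.p_raw:
            raise ValueError("Bonferroni-adjusted p must be >= raw p")


def significance_tier(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def normality_check(values: Sequence[float], alpha: float = 0.05) -> tuple[bool, float, float]:
    """One-sample KS test against N(sample mean, sample SD).

    Returns (passed, statistic, p). Requires n >= 3 and non-degenerate
    spread.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("normality check needs n >= 3")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) sample")
    stat, p = sps.kstest(v, "norm", args=(v.mean(), sd))
    return bool(p > alpha), float(stat), float(p)


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    design: str = "auto",
) -> tuple[pd.DataFrame, list[GroupComparisonResult]]:
    """Omnibus + Bonferroni-adjusted pairwise comparison of named groups.

    ``design``: "parametric" (ANOVA + pairwise t), "nonparametric"
    (Kruskal–Wallis + pairwise Mann–Whitney U), or "auto" (parametric iff
    every group of n >= 3 passes :func:`normality_check`). Returns the tidy
    omnibus table and the pairwise results. Requires >= 2 groups with >= 2
    values each.
    """
    if design not in ("auto", "parametric", "nonparametric"):
        raise ValueError("design must be auto|parametric|nonparametric")
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs >= 2 values")

    if design == "auto":
        try:
            normal = all(normality_check(v)[0] for v in arrays.values() if len(v) >= 3)
        except ValueError:
            normal = False
        design = "parametric" if normal else "nonparametric"

    if design == "parametric":
        stat, p = sps.f_oneway(*arrays.values())
        omnibus_name = "one-way ANOVA"
        pair_test = "t-test (Bonferroni)"

        def pairwise(a, b):
            return sps.ttest_ind(a, b)
    else:
        stat, p = sps.kruskal(*arrays.values())
        omnibus_name = "Kruskal-Wallis"
        pair_test = "Mann-Whitney U (Bonferroni)"

        def pairwise(a, b):
            return sps.mannwhitneyu(a, b, alternative="two-sided")

    pairs = list(combinations(names, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        s, praw = pairwise(arrays[a], arrays[b])
        padj = min(1.0, m * float(praw))
        results.append(
            GroupComparisonResult(
                test=pair_test,
                group_a=a,
                group_b=b,
                statistic=float(s),
                p_raw=float(praw),
                p_adjusted=padj,
                n_a=len(arrays[a]),
                n_b=len(arrays[b]),
                significance=significance_tier(padj),
            )
        )
    omnibus = pd.DataFrame(
        [
            {
                "test": omnibus_name,
                "statistic": float(stat),
                "p": float(p),
                "n_groups": len(names),
                "significance": significance_tier(float(p)),
            }
        ]
    )
    return omnibus, results


def results_table(results: Sequence[GroupComparisonResult]) -> pd.DataFrame:
    """Tidy DataFrame of pairwise results (one row per comparison)."""
    return pd.DataFrame([r.__dict__ for r in results])
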