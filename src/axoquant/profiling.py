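"""Multiparametric high-content (HC) Z-score profiles and their comparison.

A condition (genotype pool x treatment x marker x readout position) is
summarized by the 11 master motility/shape parameters per movie. The HC
profile of a line/pool is the ordered 44-entry Z-score signature

    #1-11   mito distal      #12-22  mito proximal
    #23-33  lyso distal      #34-44  lyso proximal

where each parameter is expressed as a Z-score against the untreated-control
baseline at the *proximal* readout of the matching marker:

    Z(p) = (mean_cond(p) - mean_baseline(p)) / SD_baseline(p)

with the baseline spread taken over per-movie values. The proximal entries of
the untreated control itself are therefore exactly 0. Profiles of several
lines are pooled entrywise (mean +- SD across lines) and compared by two-way
ANOVA (condition x parameter index, per-line Z-scores as replicates) with
Bonferroni-adjusted pairwise condition contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .tracking import PARAMETER_NAMES

__all__ = [
    "ConditionKey",
    "PROFILE_BLOCKS",
    "profile_index",
    "condition_summary",
    "zscore_profile",
    "pool_profiles",
    "profile_anova",
    "plot_profiles",
]

# (marker, position) block order of the 44-entry profile
PROFILE_BLOCKS = (("mito", "distal"), ("mito", "proximal"), ("lyso", "distal"), ("lyso", "proximal"))


@dataclass(frozen=True)
class ConditionKey:
    """Identifies one condition cell: genotype pool, treatment, marker, position."""

    genotype: str   # "Ctrl" | "mutantFUS" | line id
    treatment: str  # "untreated" | "2Hz" | "10Hz" | "10/2Hz"
    marker: str     # "mito" | "lyso"
    position: str   # "distal" | "proximal"

    def __post_init__(self) -> None:
        for f in ("genotype", "treatment", "marker", "position"):
            if not getattr(self, f):
                raise ValueError(f"ConditionKey.{f} must be populated")


def profile_index() -> pd.DataFrame:
    """The fixed 44-row index map: index (1-based), marker, position, parameter."""
    rows = []
    i = 1
    for marker, position in PROFILE_BLOCKS:
        for p in PARAMETER_NAMES:
            rows.append((i, marker, position, p))
            i += 1
    return pd.DataFrame(rows, columns=["index", "marker", "position", "parameter"]).set_index("index")


def condition_summary(movie_summaries: pd.DataFrame, key: ConditionKey) -> pd.DataFrame:
    """Per-movie values of the 11 parameters for one condition.

    ``movie_summaries`` is a table of movie summary rows carrying metadata
    columns (genotype, treatment, marker, position). Raises ``KeyError``
    naming the condition when no movie matches.
    """
    sel = movie_summaries
    for f in ("genotype", "treatment", "marker", "position"):
        sel = sel[sel[f] == getattr(key, f)]
    if len(sel) == 0:
        raise KeyError(f"no movies for condition {key}")
    return sel[list(PARAMETER_NAMES)].reset_index(drop=True)


def zscore_profile(
    condition_tables: Mapping[tuple[str, str], pd.DataFrame],
    baseline_tables: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Assemble the 44-entry Z-score profile of one line/pool.

    ``condition_tables`` maps (marker, position) -> per-movie parameter table
    for the profiled condition; ``baseline_tables`` maps marker -> per-movie
    table of the untreated-control *proximal* baseline for that marker. Both
    the distal and proximal entries of a marker normalize against that
    proximal baseline. Raises ``ValueError`` on a zero-SD (degenerate)
    baseline entry.

    Returns a DataFrame indexed 1..44 with columns marker, position,
    parameter, z.
    """
    for marker in {m for m, _ in PROFILE_BLOCKS}:
        if marker not in baseline_tables:
            raise ValueError(f"baseline missing for marker {marker!r}")
    prof = profile_index()
    zs = np.empty(len(prof))
    for i, row in prof.iterrows():
        cond = condition_tables[(row.marker, row.position)]
        base = baseline_tables[row.marker]
        b = base[row.parameter].to_numpy(dtype=float)
        c = cond[row.parameter].to_numpy(dtype=float)
        n_b = int(np.isfinite(b).sum())  # NaN-tolerant: e.g. undefined antero/retro ratio
        sd = float(np.nanstd(b, ddof=1)) if n_b > 1 else 0.0
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(
                f"degenerate baseline: SD of {row.parameter!r} ({row.marker}) is zero or undefined"
            )
        zs[i - 1] = (float(np.nanmean(c)) - float(np.nanmean(b))) / sd
    out = prof.copy()
    out["z"] = zs
    return out


def pool_profiles(profiles: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Entrywise mean and SD of per-line profiles (SD 0 for a single line)."""
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    z = np.stack([p["z"].to_numpy() for p in profiles])
    out = profiles[0][["marker", "position", "parameter"]].copy()
    out["z"] = z.mean(axis=0)
    out["z_sd"] = z.std(axis=0, ddof=1) if len(profiles) > 1 else 0.0
    return out


def profile_anova(profiles_by_condition: Mapping[str, Sequence[pd.DataFrame]]) -> pd.DataFrame:
    """Pairwise condition comparisons of pooled HC profiles.

    For each pair of conditions, a two-way ANOVA with factors condition and
    parameter index is fit on the per-line Z-scores; the condition
    main-effect p-value is Bonferroni-adjusted by the number of pairs.
    Requires >= 2 line profiles per condition.
    """
    for cond, profs in profiles_by_condition.items():
        if len(profs) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 line profiles for ANOVA")
    long_rows = []
    for cond, profs in profiles_by_condition.items():
        for li, p in enumerate(profs):
            for idx, row in p.iterrows():
                long_rows.append((cond, li, int(idx), row.z))
    data = pd.DataFrame(long_rows, columns=["condition", "line", "param", "z"])

    pairs = list(combinations(sorted(profiles_by_condition), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        sub = data[data.condition.isin([a, b])]
        fit = ols("z ~ C(condition) + C(param)", data=sub).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        p_raw = float(table.loc["C(condition)", "PR(>F)"])
        f_stat = float(table.loc["C(condition)", "F"])
        p_adj = min(1.0, m * p_raw)
        rows.append((a, b, f_stat, p_raw, p_adj, _stars(p_adj)))
    return pd.DataFrame(
        rows, columns=["condition_a", "condition_b", "F", "p_raw", "p_adj", "significance"]
    )


def _stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def plot_profiles(pooled: Mapping[str, pd.DataFrame], ax=None):
    """Connected-line rendering of pooled profiles (thin optional layer)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    for name, prof in pooled.items():
        x = prof.index.to_numpy()
        ax.errorbar(x, prof["z"], yerr=prof.get("z_sd"), label=name, marker="o", ms=3, capsize=2)
    ax.axhline(0.0, color="grey", lw=0.8)
    for cut in (11.5, 22.5, 33.5):
        ax.axvline(cut, color="lightgrey", lw=0.8)
    ax.set_xlabel("parameter # (mito distal | mito proximal | lyso distal | lyso proximal)")
    ax.set_ylabel("Z-score vs untreated Ctrl proximal")
    ax.legend()
    return ax
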