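"""Per-cell aggregation and group inference.

The unit of statistical analysis is the cell: for each cell the median of
every event parameter is taken over the kinetics-eligible events (the
"mean of median" protocol), and only cells with more than 20 events enter
group comparisons.  Groups are compared by one-way ANOVA with a
Tukey-Kramer post test (unbalanced-safe) or, for two groups, the
Mann-Whitney rank-sum test.  Significance stars follow the usual
convention: * p<0.05, ** p<0.01, *** p<0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .amperometry import EventTable
from .config import AnalysisConfig

#: event-table columns aggregated per cell
KINETIC_PARAMETERS = (
    "amplitude_pA",
    "rise_time_50_90_ms",
    "half_width_ms",
    "charge_fC",
)
FOOT_PARAMETERS = (
    "foot_duration_ms",
    "foot_amplitude_pA",
    "foot_charge_fC",
)
FLUCT_PARAMETERS = (
    "fluctuation_frequency_kHz",
    "rms_noise_pA_per_ms",
)


@dataclass
class CellSummary:
    """Per-cell medians of event parameters plus the inclusion flag."""

    cell_id: str
    group: str
    n_events: int
    medians: dict[str, float] = field(default_factory=dict)
    included: bool = False


def summarize_cell(
    events: EventTable | pd.DataFrame,
    cell_id: str,
    group: str,
    config: AnalysisConfig | None = None,
) -> CellSummary:
    """Median of each parameter over the cell's eligible events.

    ``n_events`` counts the detection tier (every selected event); kinetic
    medians use only kinetics-eligible events, foot medians only events with
    a detected foot, and fluctuation medians only feet that qualify for the
    fluctuation analysis (duration > 2 ms).
    """
    config = config or AnalysisConfig()
    df = events.to_dataframe() if isinstance(events, EventTable) else events
    n_events = len(df)
    medians: dict[str, float] = {}
    if n_events:
        kin = df[df["kinetics_eligible"].astype(bool)]
        for p in KINETIC_PARAMETERS:
            medians[p] = float(kin[p].dropna().median()) if len(kin) else np.nan
        for p in FOOT_PARAMETERS:
            medians[p] = float(df[p].dropna().median())
        fl = df[df["foot_eligible_for_fluct"].fillna(False).astype(bool)]
        for p in FLUCT_PARAMETERS:
            medians[p] = float(fl[p].dropna().median()) if len(fl) else np.nan
    return CellSummary(
        cell_id=cell_id,
        group=group,
        n_events=n_events,
        medians=medians,
        included=n_events >= config.min_events_per_cell,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupComparison:
    """Group means of cell medians with pairwise test results."""

    parameter: str
    test: str
    group_means: dict[str, float]
    group_sems: dict[str, float]
    n_cells: dict[str, int]
    n_excluded: dict[str, int]
    pairwise_p: dict[tuple[str, str], float]
    stars: dict[tuple[str, str], str]
    anova_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group_a": a, "group_b": b, "p": p, "stars": self.stars[(a, b)]}
            for (a, b), p in self.pairwise_p.items()
        ]
        return pd.DataFrame(rows)


def compare_groups(
    summaries: list[CellSummary],
    parameter: str,
    test: str = "anova_tukey",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare cell medians of *parameter* between groups.

    Non-included cells (20 events or fewer) are dropped, and their count is
    reported so the exclusion is never silent.  ``test`` is
    ``"anova_tukey"`` (one-way ANOVA + Tukey-Kramer pairwise contrasts) or
    ``"mann_whitney"`` (two groups only).
    """
    if test not in ("anova_tukey", "mann_whitney"):
        raise ValueError(f"unknown test {test!r}")
    groups: dict[str, list[float]] = {}
    n_excluded: dict[str, int] = {}
    for s in summaries:
        n_excluded.setdefault(s.group, 0)
        if not s.included:
            n_excluded[s.group] += 1
            continue
        v = s.medians.get(parameter, np.nan)
        if np.isfinite(v):
            groups.setdefault(s.group, []).append(v)
    if len(groups) < 2:
        raise ValueError("need at least two groups of included cells")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than two included cells")

    names = sorted(groups)
    arrays = {g: np.asarray(groups[g]) for g in names}
    means = {g: float(a.mean()) for g, a in arrays.items()}
    sems = {g: float(a.std(ddof=1) / np.sqrt(a.size)) for g, a in arrays.items()}
    n_cells = {g: int(a.size) for g, a in arrays.items()}

    pairwise: dict[tuple[str, str], float] = {}
    anova_p = None
    if test == "mann_whitney":
        if len(names) != 2:
            raise ValueError("the Mann-Whitney test applies to exactly two groups")
        a, b = names
        pairwise[(a, b)] = float(sps.mannwhitneyu(arrays[a], arrays[b]).pvalue)
    else:
        anova_p = float(sps.f_oneway(*(arrays[g] for g in names)).pvalue)
        values = np.concatenate([arrays[g] for g in names])
        labels = np.concatenate([[g] * arrays[g].size for g in names])
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        for (a, b), p in zip(
            ((tukey.groupsunique[i], tukey.groupsunique[j])
             for i, j in zip(*np.triu_indices(len(names), k=1))),
            tukey.pvalues,
        ):
            pairwise[(str(a), str(b))] = float(p)

    return GroupComparison(
        parameter=parameter,
        test=test,
        group_means=means,
        group_sems=sems,
        n_cells=n_cells,
        n_excluded=n_excluded,
        pairwise_p=pairwise,
        stars={k: _stars(p) for k, p in pairwise.items()},
        anova_p=anova_p,
    )
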