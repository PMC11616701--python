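"""Population summaries and the statistical comparisons used for phenotyping.

Comparisons follow the conventions of deformability-cytometry practice:
two-tailed Mann-Whitney U tests for unpaired two-group comparisons (exact
enumeration for small tie-free samples, normal approximation with tie and
continuity corrections otherwise), one-way ANOVA followed by Tukey's multiple
comparison test for dose-response panels, and the GraphPad-style significance
stars

    P < 0.033 "*",  P < 0.0021 "**",  P < 0.0002 "***",  P < 0.0001 "****"

with strict inequalities ("ns" otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PopulationSummary",
    "TestResult",
    "summarize",
    "mann_whitney_u",
    "one_way_anova",
    "tukey_hsd",
    "star_code",
]


def star_code(p: float) -> str:
    """Significance stars for a two-tailed P value (strict thresholds)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.0002:
        return "***"
    if p < 0.0021:
        return "**"
    if p < 0.033:
        return "*"
    return "ns"


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    stars: str = field(init=False)

    def __post_init__(self) -> None:
        self.stars = star_code(self.p_value)


@dataclass
class PopulationSummary:
    """Per-group mean/SD/n of deformability, area, and their size-to-D ratio.

    ``size_to_deformability`` is mean area / mean deformability, defined only
    for groups with positive mean deformability (NaN otherwise, with
    ``ratio_defined`` False).  ``mode`` records whether statistics were pooled
    over single cells or computed as the mean of replicate means.
    """

    group: str
    n: int
    mean_deformability: float
    sd_deformability: float
    mean_area_um2: float
    sd_area_um2: float
    size_to_deformability: float
    ratio_defined: bool
    mode: str
    n_replicates: int | None = None


def _group_stats(g: pd.DataFrame) -> tuple[float, float, float, float]:
    return (
        float(g["deformability"].mean()),
        float(g["deformability"].std(ddof=1)) if len(g) > 1 else 0.0,
        float(g["area_um2"].mean()),
        float(g["area_um2"].std(ddof=1)) if len(g) > 1 else 0.0,
    )


def summarize(
    records: pd.DataFrame,
    group_by: str,
    replicate_by: str | None = None,
) -> list[PopulationSummary]:
    """Per-group summaries of a results table.

    With ``replicate_by`` given, statistics follow the bar-chart convention of
    replicate experiments: per-replicate means are computed first and the
    group value is the mean (and SD) of those replicate means.  Without it,
    single-cell values are pooled.
    """
    if group_by not in records.columns:
        raise KeyError(f"unknown group key {group_by!r}")
    if replicate_by is not None and replicate_by not in records.columns:
        raise KeyError(f"unknown replicate key {replicate_by!r}")
    out: list[PopulationSummary] = []
    for group, g in records.groupby(group_by, sort=True):
        if replicate_by is None:
            md, sd, ma, sa = _group_stats(g)
            mode, n_rep = "pooled", None
        else:
            reps = g.groupby(replicate_by)[["deformability", "area_um2"]].mean()
            md = float(reps["deformability"].mean())
            sd = float(reps["deformability"].std(ddof=1)) if len(reps) > 1 else 0.0
            ma = float(reps["area_um2"].mean())
            sa = float(reps["area_um2"].std(ddof=1)) if len(reps) > 1 else 0.0
            mode, n_rep = "replicate_mean", len(reps)
        defined = md > 0
        out.append(
            PopulationSummary(
                group=str(group),
                n=int(len(g)),
                mean_deformability=md,
                sd_deformability=sd,
                mean_area_um2=ma,
                sd_area_um2=sa,
                size_to_deformability=ma / md if defined else float("nan"),
                ratio_defined=defined,
                mode=mode,
                n_replicates=n_rep,
            )
        )
    return out


def mann_whitney_u(
    x, y, labels: tuple[str, str] = ("x", "y")
) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    Follows the standard exact/asymptotic policy: exact two-tailed P by
    enumeration of rank arrangements when the smaller sample has at most 8
    observations and there are no ties, otherwise a normal approximation with
    midrank tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult("mann-whitney-u", float(res.statistic), float(res.pvalue), labels)


def one_way_anova(groups: list, labels: tuple[str, ...] | None = None) -> TestResult:
    """One-way ANOVA F test across two or more groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for g in arrs:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(arrs)))
    if all(np.ptp(g) == 0 for g in arrs) and len({g[0] for g in arrs}) == 1:
        # all observations identical: F = 0, P = 1 (scipy emits nan here)
        return TestResult("one-way-anova", 0.0, 1.0, labels)
    res = sps.f_oneway(*arrs)
    return TestResult("one-way-anova", float(res.statistic), float(res.pvalue), labels)


def tukey_hsd(groups: list, labels: tuple[str, ...] | None = None) -> list[TestResult]:
    """Tukey's multiple-comparison test (Tukey-Kramer for unequal n).

    Returns one adjusted pairwise result per group pair, using the
    studentized-range distribution.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for g in arrs:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(arrs)))
    res = sps.tukey_hsd(*arrs)
    out: list[TestResult] = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            out.append(
                TestResult(
                    "tukey-hsd",
                    float(res.statistic[i, j]),
                    float(res.pvalue[i, j]),
                    (labels[i], labels[j]),
                )
            )
    return out
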