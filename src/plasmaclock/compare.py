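"""Delta age and between-group comparison.

Delta age is predicted minus chronological age per subject; positive
values read as a biologically older proteome.  Group differences in delta
age are tested with the two-sample Wilcoxon rank-sum (Mann-Whitney) test
by default — exact distribution for small samples without ties, normal
approximation with continuity and tie corrections otherwise — or the
paired Wilcoxon signed-rank test on request.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("plasmaclock")

__all__ = ["DeltaAgeResult", "GroupComparison", "compute_delta_age", "compare_groups"]

#: largest combined sample size at which the exact null distribution is used
EXACT_N_MAX = 25


@dataclass
class DeltaAgeResult:
    delta: pd.Series  # per-subject predicted - chronological, years
    groups: pd.Series
    group_stats: pd.DataFrame  # per-group mean/sd of chronological, predicted, delta


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    test_name: str
    group_ns: tuple[int, ...]
    mean_predicted_diff: float  # years, first group minus second


def compute_delta_age(
    predicted: pd.Series, chronological: pd.Series, groups: pd.Series
) -> DeltaAgeResult:
    """Per-subject delta age with per-group mean +/- SD summaries."""
    idx = predicted.index
    for name, series in (("chronological", chronological), ("groups", groups)):
        missing = idx.difference(series.index)
        if len(missing):
            raise KeyError(f"subjects missing a {name} value: {missing[:5].tolist()}")
    chron = chronological.loc[idx].astype(float)
    grp = groups.loc[idx]
    if predicted.isna().any() or chron.isna().any():
        raise ValueError("predicted and chronological ages must be complete")
    delta = (predicted.astype(float) - chron).rename("delta_age")
    frame = pd.DataFrame(
        {"chronological": chron, "predicted": predicted.astype(float), "delta": delta,
         "group": grp}
    )
    group_stats = frame.groupby("group", sort=True).agg(
        n=("delta", "size"),
        chronological_mean=("chronological", "mean"),
        chronological_sd=("chronological", lambda s: s.std(ddof=1)),
        predicted_mean=("predicted", "mean"),
        predicted_sd=("predicted", lambda s: s.std(ddof=1)),
        delta_mean=("delta", "mean"),
        delta_sd=("delta", lambda s: s.std(ddof=1)),
    )
    return DeltaAgeResult(delta=delta, groups=grp, group_stats=group_stats)


def compare_groups(result: DeltaAgeResult, test: str = "rank_sum") -> GroupComparison:
    """Two-sided test of delta age between exactly two groups.

    ``rank_sum`` is appropriate for independent groups; ``signed_rank``
    requires equal group sizes and pairs subjects by their stated order
    within each group.
    """
    labels = [g for g in result.group_stats.index]
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}: {labels}")
    g1, g2 = labels
    d1 = result.delta[result.groups == g1].to_numpy(dtype=float)
    d2 = result.delta[result.groups == g2].to_numpy(dtype=float)
    if min(d1.size, d2.size) < 2:
        raise ValueError("each group needs >= 2 subjects")
    pred_diff = float(
        result.group_stats.loc[g1, "predicted_mean"]
        - result.group_stats.loc[g2, "predicted_mean"]
    )
    if test == "rank_sum":
        pooled = np.concatenate([d1, d2])
        has_ties = np.unique(pooled).size < pooled.size
        exact = (pooled.size <= EXACT_N_MAX) and not has_ties
        res = stats.mannwhitneyu(
            d1, d2, alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=True,
        )
        name = "Wilcoxon rank-sum (exact)" if exact else "Wilcoxon rank-sum (normal approx.)"
    elif test == "signed_rank":
        if d1.size != d2.size:
            raise ValueError(
                "signed_rank pairs subjects by stated order and requires equal group "
                f"sizes, got {d1.size} and {d2.size}; use rank_sum for independent groups"
            )
        diffs = d1 - d2
        nonzero = diffs[diffs != 0]
        exact = (d1.size <= EXACT_N_MAX) and np.unique(np.abs(nonzero)).size == nonzero.size
        res = stats.wilcoxon(
            d1, d2, alternative="two-sided",
            method="exact" if exact else "approx",
            correction=not exact,
        )
        name = "Wilcoxon signed-rank (exact)" if exact else "Wilcoxon signed-rank (normal approx.)"
    else:
        raise ValueError(f"unknown test {test!r}; use 'rank_sum' or 'signed_rank'")
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name=name,
        group_ns=(d1.size, d2.size),
        mean_predicted_diff=pred_diff,
    )
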