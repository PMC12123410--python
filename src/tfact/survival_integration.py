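"""Patient stratification and Kaplan-Meier / log-rank survival comparison.

Three grouping schemes are supported: a median split of one molecular score
(ties at the median go to "low"), a combined stratum counting across TFs how
many times a patient falls on the worse-prognosis side, and a quadrant
scheme crossing two median splits (transcriptomic activity vs phospho score)
to separate concordant from discordant patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time

from .io_formats import SurvivalTable

__all__ = [
    "StratifiedCohort",
    "KMResult",
    "median_split",
    "km_logrank",
    "worst_direction",
    "combined_strata",
    "quadrant_groups",
]


@dataclass
class StratifiedCohort:
    labels: pd.Series  # patient -> group label
    scheme: str
    scores: pd.DataFrame | None = None  # the score(s) the labels came from


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> KM survival function (timeline, estimate)
    statistic: float  # log-rank chi-square, k-1 df
    p: float
    df: int
    group_sizes: dict[str, int]
    dropped: list[str]  # patients missing from the survival table


def median_split(score: pd.Series) -> pd.Series:
    """Label patients low/high at the median; ties at the median go to low.

    For even n the median is the midpoint of the two middle values, so a tie
    only occurs when values coincide with it.
    """
    if len(score) < 4:
        raise ValueError("need at least 4 patients for a median split")
    values = score.to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise ValueError("degenerate split: all scores equal")
    med = float(np.median(values))
    return pd.Series(np.where(values <= med, "low", "high"), index=score.index)


def km_logrank(strata: StratifiedCohort, survival: SurvivalTable) -> KMResult:
    """Kaplan-Meier curves per group plus the k-group log-rank test."""
    labels = strata.labels
    present = labels.index.intersection(survival.data.index)
    dropped = sorted(set(labels.index) - set(present))
    if dropped:
        warnings.warn(f"{len(dropped)} patient(s) missing from survival table dropped")
    labels = labels.loc[present]

    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups for a log-rank test")
    times = survival.data.loc[present, "time"]
    events = survival.data.loc[present, "event"]
    sizes = labels.value_counts().to_dict()
    if min(sizes.values()) < 2:
        small = min(sizes, key=sizes.get)
        raise ValueError(f"group {small!r} has fewer than 2 patients")

    curves = {}
    for g in sorted(map(str, groups)):
        mask = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        sf = kmf.survival_function_
        curves[str(g)] = sf.rename(columns={sf.columns[0]: "estimate"})

    res = multivariate_logrank_test(times, labels, events)
    return KMResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        df=len(groups) - 1,
        group_sizes={str(k): int(v) for k, v in sizes.items()},
        dropped=dropped,
    )


def worst_direction(
    labels: pd.Series, survival: SurvivalTable
) -> str:
    """Which side (high/low) of a median split has the worse prognosis.

    Compared by restricted-mean survival time up to the last observed time;
    the side with the smaller RMST is "worst".
    """
    present = labels.index.intersection(survival.data.index)
    labels = labels.loc[present]
    horizon = float(survival.data.loc[present, "time"].max())
    rmst = {}
    for g in ("low", "high"):
        mask = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(survival.data.loc[present, "time"][mask],
                survival.data.loc[present, "event"][mask])
        rmst[g] = float(restricted_mean_survival_time(kmf, t=horizon))
    return "low" if rmst["low"] < rmst["high"] else "high"


def combined_strata(
    labels_by_tf: dict[str, pd.Series], worst: dict[str, str]
) -> pd.Series:
    """Count, per patient, the TFs for which they sit on the worse-prognosis side.

    With two TFs the labels are 0 (worst side of neither), 1, 2 (worst side
    of both).
    """
    if set(labels_by_tf) != set(worst):
        raise ValueError("labels_by_tf and worst_direction must cover the same TFs")
    tfs = sorted(labels_by_tf)
    patients = labels_by_tf[tfs[0]].index
    counts = pd.Series(0, index=patients, dtype=int)
    for tf in tfs:
        labels = labels_by_tf[tf]
        missing = set(patients) - set(labels.index)
        if missing or set(labels.index) - set(patients):
            raise ValueError(f"TF {tf!r}: patient labels do not cover the cohort")
        counts += (labels.loc[patients] == worst[tf]).astype(int)
    return counts


def quadrant_groups(activity: pd.Series, p_plus: pd.Series) -> pd.Series:
    """Quadrants of the activity-vs-phospho-score plane, split at the medians.

    Ties go to "low" on each axis, matching median_split.  Q2 = both high and
    Q4 = both low (the concordant quadrants); Q1 = activity high only and
    Q3 = phospho high only (discordant).
    """
    common = activity.index.intersection(p_plus.index)
    if not len(common) == len(activity) == len(p_plus):
        raise ValueError("activity and phospho scores must cover the same patients")
    ax = median_split(activity.loc[common]) == "high"
    ay = median_split(p_plus.loc[common]) == "high"
    label = np.where(
        ax & ay, "Q2", np.where(~ax & ~ay, "Q4", np.where(ax, "Q1", "Q3"))
    )
    return pd.Series(label, index=common)
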