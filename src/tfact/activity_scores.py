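"""Count normalization and per-sample TF activity scores.

The normalization ("vst-simple") is a median-of-ratios size factor followed
by log2(x/sf + 1): it removes library-size differences and compresses
variance, the two properties the downstream scores rely on.  A TF's activity
in a sample is the sum of normalized expression over its direct positive
targets minus the sum over its negative targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .regulon_inference import Regulon

logger = logging.getLogger(__name__)

__all__ = [
    "vst",
    "activity_score",
    "activity_matrix",
    "score_structure",
    "ActivityMatrix",
    "ScoreStructure",
]


def vst(counts: pd.DataFrame) -> pd.DataFrame:
    """Simplified variance-stabilizing transform of a genes x samples count matrix.

    Size factor per sample = median, over genes with a nonzero geometric mean
    across samples, of count/geomean(gene); transformed value =
    log2(count/size_factor + 1).
    """
    arr = counts.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if not arr.any():
        raise ValueError("all-zero count matrix")

    with np.errstate(divide="ignore"):
        loggeo = np.log(arr).mean(axis=1)
    usable = np.isfinite(loggeo)  # genes with no zero count
    if not usable.any():
        raise ValueError("no gene has all-nonzero counts; cannot estimate size factors")
    ratios = arr[usable] / np.exp(loggeo[usable])[:, None]
    size_factors = np.median(ratios, axis=0)
    if np.any(size_factors <= 0):
        raise ValueError("non-positive size factor")
    out = np.log2(arr / size_factors[None, :] + 1.0)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def activity_score(expr_vst: pd.DataFrame, direct_regulon: Regulon) -> pd.Series | None:
    """Per-sample activity: sum of positive-target expression minus negative.

    Targets absent from the matrix are dropped with a warning; returns None
    when no target is present (a no-score outcome).
    """
    modes = direct_regulon.modes
    present = modes.index.intersection(expr_vst.index)
    if len(present) < len(modes):
        missing = sorted(set(modes.index) - set(present))
        warnings.warn(
            f"TF {direct_regulon.tf}: {len(missing)} target(s) absent from matrix"
        )
    if len(present) == 0:
        return None
    m = modes.loc[present].to_numpy(dtype=float)
    x = expr_vst.loc[present].to_numpy(dtype=float)
    return pd.Series(m @ x, index=expr_vst.columns)


@dataclass
class ActivityMatrix:
    scores: pd.DataFrame  # tf x sample
    condition: pd.Series  # sample -> "tumor" | "nat"

    def tumor_columns(self) -> pd.DataFrame:
        return self.scores.loc[:, self.condition[self.condition == "tumor"].index]

    def nat_columns(self) -> pd.DataFrame:
        return self.scores.loc[:, self.condition[self.condition == "nat"].index]


def activity_matrix(
    expr_vst_tumor: pd.DataFrame,
    expr_vst_nat: pd.DataFrame,
    direct_regulons: dict[str, Regulon],
) -> ActivityMatrix:
    """Activity scores for every TF over all tumor and NAT samples.

    Tumor columns are suffixed ``-T`` and NAT columns ``-N`` so the same
    patient can appear under both conditions.  TFs with no scoreable target
    are dropped with a log entry.
    """
    rows_t, rows_n, kept = [], [], []
    for tf, reg in direct_regulons.items():
        st = activity_score(expr_vst_tumor, reg)
        sn = activity_score(expr_vst_nat, reg)
        if st is None or sn is None:
            logger.info("TF %s dropped from activity matrix: no usable targets", tf)
            continue
        rows_t.append(st)
        rows_n.append(sn)
        kept.append(tf)
    if not kept:
        raise ValueError("no TF produced an activity score")
    tum = pd.DataFrame(rows_t, index=kept)
    nat = pd.DataFrame(rows_n, index=kept)
    tum.columns = [f"{c}-T" for c in tum.columns]
    nat.columns = [f"{c}-N" for c in nat.columns]
    scores = pd.concat([tum, nat], axis=1)
    condition = pd.Series(
        ["tumor"] * tum.shape[1] + ["nat"] * nat.shape[1], index=scores.columns
    )
    return ActivityMatrix(scores=scores, condition=condition)


@dataclass
class ScoreStructure:
    coordinates: pd.DataFrame  # sample x component
    explained_variance_ratio: np.ndarray
    correlation: pd.DataFrame  # tf x tf, Pearson on tumor columns


def score_structure(
    activity: ActivityMatrix, n_components: int | None = None, standardize: bool = True
) -> ScoreStructure:
    """PCA over samples plus the TF-TF correlation matrix on tumor columns.

    PCA treats samples as observations and TFs as features; by default each
    TF row is centered and scaled to unit variance first.  Constant TF rows
    are excluded from the correlation matrix with a warning.
    """
    scores = activity.scores
    if scores.shape[0] < 2 or scores.shape[1] < 3:
        raise ValueError("need >= 2 TFs and >= 3 samples")

    x = scores.to_numpy(dtype=float).T  # samples x TFs
    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    k = n_components or min(x.shape)
    pca = PCA(n_components=min(k, min(x.shape)), svd_solver="full")
    coords = pca.fit_transform(x)
    coordinates = pd.DataFrame(
        coords,
        index=scores.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )

    tumor = activity.tumor_columns()
    const = tumor.std(axis=1) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant TF row(s) excluded from correlation"
        )
        tumor = tumor.loc[~const]
    correlation = tumor.T.corr(method="pearson")
    return ScoreStructure(
        coordinates=coordinates,
        explained_variance_ratio=pca.explained_variance_ratio_,
        correlation=correlation,
    )
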