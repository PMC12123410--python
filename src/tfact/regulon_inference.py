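"""Signed TF regulon inference from normal-tissue coexpression.

A candidate edge TF--gene is kept when the two-sided Pearson test passes a
stringent p-value threshold on the full data AND reaches that threshold in a
majority of bootstrap resamples.  The edge mode is the sign of the full-data
correlation.  TFs whose surviving regulon is smaller than ``min_targets``
are excluded, mirroring the convention of excluding TFs with too few
inferred targets before any downstream analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["RegulonEdge", "Regulon", "InferenceParams", "edge_pvalue", "infer_regulons"]


@dataclass
class RegulonEdge:
    mode: int  # +1 activated, -1 repressed
    r: float
    p: float
    support: float  # fraction of bootstraps where the edge re-passed the threshold


@dataclass
class Regulon:
    tf: str
    targets: dict[str, RegulonEdge] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValueError(f"regulon of {self.tf!r} contains the TF itself")

    @property
    def modes(self) -> pd.Series:
        return pd.Series({t: e.mode for t, e in self.targets.items()}, dtype=int)

    def __len__(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class InferenceParams:
    p_threshold: float = 1e-8
    n_bootstraps: int = 1000
    min_targets: int = 20
    min_support: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0,1)")
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")


def edge_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation under the null.

    Uses t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom; |r| = 1
    returns exactly 0.
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _critical_r(p_threshold: float, n: int) -> float:
    """|r| above which the two-sided Pearson p falls below p_threshold."""
    t_crit = stats.t.isf(p_threshold / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def _row_standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale rows to unit norm; returns (standardized, nonconstant mask)."""
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1)
    ok = norm > 0
    xc[ok] /= norm[ok, None]
    xc[~ok] = 0.0
    return xc, ok


def infer_regulons(
    expr_nat: pd.DataFrame,
    tf_ids: list[str],
    params: InferenceParams = InferenceParams(),
    seed: int = 0,
) -> dict[str, Regulon]:
    """Infer signed regulons from a normalized genes x samples matrix.

    Zero-variance genes are excluded before correlation; TFs absent from the
    matrix or with constant expression are skipped with a warning.
    """
    n = expr_nat.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for regulon inference")

    genes = expr_nat.index
    x = expr_nat.to_numpy(dtype=float)
    xs, nonconst = _row_standardize(x)

    tf_rows: dict[str, int] = {}
    for tf in tf_ids:
        if tf not in genes:
            warnings.warn(f"TF {tf!r} absent from expression matrix; skipped")
            continue
        i = genes.get_loc(tf)
        if not nonconst[i]:
            warnings.warn(f"TF {tf!r} has constant expression; skipped")
            continue
        tf_rows[tf] = i

    if not tf_rows:
        return {}

    tf_list = list(tf_rows)
    tf_idx = np.array([tf_rows[t] for t in tf_list])
    r_full = xs[tf_idx] @ xs.T  # n_tf x n_genes
    np.clip(r_full, -1.0, 1.0, out=r_full)

    r_crit = _critical_r(params.p_threshold, n)
    gene_ok = nonconst.copy()
    cand = np.abs(r_full) >= r_crit
    cand &= gene_ok[None, :]
    for k, i in enumerate(tf_idx):  # a TF is never its own target
        cand[k, i] = False

    # bootstrap support, computed only over the union of candidate targets
    cand_cols = np.flatnonzero(cand.any(axis=0))
    support = np.zeros_like(r_full)
    if cand_cols.size:
        rng = np.random.default_rng(seed)
        hits = np.zeros((len(tf_list), cand_cols.size), dtype=np.int64)
        y = x[cand_cols]
        xt = x[tf_idx]
        for _ in range(params.n_bootstraps):
            idx = rng.integers(0, n, size=n)
            tb, t_ok = _row_standardize(xt[:, idx])
            yb, y_ok = _row_standardize(y[:, idx])
            rb = tb @ yb.T
            passed = np.abs(rb) >= r_crit
            passed &= t_ok[:, None] & y_ok[None, :]
            hits += passed
        support[:, cand_cols] = hits / params.n_bootstraps

    regulons: dict[str, Regulon] = {}
    for k, tf in enumerate(tf_list):
        targets: dict[str, RegulonEdge] = {}
        for j in np.flatnonzero(cand[k]):
            if support[k, j] < params.min_support:
                continue
            r = float(r_full[k, j])
            targets[str(genes[j])] = RegulonEdge(
                mode=int(np.sign(r)),
                r=r,
                p=edge_pvalue(r, n),
                support=float(support[k, j]),
            )
        if len(targets) < params.min_targets:
            logger.info("TF %s dropped: %d targets < min_targets", tf, len(targets))
            continue
        regulons[tf] = Regulon(tf=tf, targets=targets)
    return regulons
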