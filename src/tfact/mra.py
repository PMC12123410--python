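"""Master regulator analysis: per-TF normalized enrichment scores against a
paired tumor-vs-NAT differential signature.

The signature maps each gene to a signed z on the standard-normal scale
(paired t statistic pushed through the t CDF).  The NES of a regulon with m
usable targets is sum(mode_t * z_t) / sqrt(m): positive when positive-mode
targets are up and negative-mode targets are down in tumor.  Under the null
of iid standard-normal target z's the NES is itself standard normal, which
gives the analytic two-sided p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regulon_inference import Regulon

__all__ = ["Z_CAP", "paired_signature", "nes", "mra_all", "MRAResult"]

Z_CAP = 8.0  # |z| assigned when the difference has zero variance but nonzero mean


@dataclass
class MRAResult:
    table: pd.DataFrame  # index tf; columns nes, p, n_targets_used
    significant: list[str]  # TFs with p <= alpha, preserving table order


def paired_signature(tumor: pd.DataFrame, nat: pd.DataFrame) -> pd.Series:
    """Per-gene signed z from the paired t statistic of (tumor - NAT).

    Zero-variance differences map to +/-Z_CAP if the mean is nonzero and to 0
    if every difference is zero.  Both matrices must share index and columns
    (column j = patient j).
    """
    if not tumor.index.equals(nat.index) or not tumor.columns.equals(nat.columns):
        raise ValueError("tumor and NAT matrices must share genes and patients")
    n = tumor.shape[1]
    if n < 3:
        raise ValueError("need at least 3 patients for a paired signature")

    d = tumor.to_numpy(dtype=float) - nat.to_numpy(dtype=float)
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)

    z = np.zeros(d.shape[0])
    ok = sd > 0
    t = mean[ok] * np.sqrt(n) / sd[ok]
    # two-sided-consistent signed z: map the t CDF quantile through the normal PPF
    p_lower = stats.t.cdf(t, df=n - 1)
    z[ok] = stats.norm.ppf(p_lower)
    z[~ok] = np.sign(mean[~ok]) * Z_CAP
    np.clip(z, -Z_CAP, Z_CAP, out=z)
    return pd.Series(z, index=tumor.index)


def nes(regulon: Regulon, signature: pd.Series) -> tuple[float, float, int] | None:
    """NES, analytic two-sided p and number of usable targets.

    Targets absent from the signature are dropped; returns None when no
    target is usable (a no-score outcome, not an error).
    """
    usable = [(t, e.mode) for t, e in regulon.targets.items() if t in signature.index]
    if not usable:
        return None
    m = len(usable)
    z = signature.loc[[t for t, _ in usable]].to_numpy(dtype=float)
    modes = np.array([mode for _, mode in usable], dtype=float)
    score = float(modes @ z / np.sqrt(m))
    p = float(2.0 * stats.norm.sf(abs(score)))
    return score, max(p, np.finfo(float).tiny), m


def mra_all(
    regulons: dict[str, Regulon], signature: pd.Series, alpha: float = 0.05
) -> MRAResult:
    """NES/p for every regulon plus the significant subset at level alpha."""
    if not regulons:
        raise ValueError("need at least one regulon")
    rows = {}
    for tf, reg in regulons.items():
        res = nes(reg, signature)
        if res is None:
            continue
        score, p, m = res
        rows[tf] = {"nes": score, "p": p, "n_targets_used": m}
    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table = table.astype({"n_targets_used": int})
    significant = [tf for tf in table.index if table.at[tf, "p"] <= alpha]
    return MRAResult(table=table, significant=significant)
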