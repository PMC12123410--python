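"""Substrate-level kinase activity from patient phosphosite fold changes.

For each patient, a kinase's activity is a KSEA-style z-score comparing the
mean fold change of its observed substrates with the patient's global site
background: z = (substrate mean - background mean) * sqrt(m) / background sd.
Significance is controlled per patient across kinases by Benjamini-Hochberg.
The statistic is named "ksea-z" in all outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import KinaseSubstrateMap, PhosphoTable

__all__ = [
    "KinaseActivity",
    "kinase_z",
    "kinase_activity_matrix",
    "kinase_significance",
    "kinase_substrate_concordance",
    "group_kinase_profile",
]

MIN_BACKGROUND_SITES = 10


@dataclass
class KinaseActivity:
    z: pd.DataFrame  # kinase x patient; NaN where no substrate observed
    q: pd.DataFrame  # matched BH-adjusted q-values
    n_substrates: pd.Series  # kinase -> substrates in the map


def kinase_z(phospho_fc_patient: pd.Series, ksmap: KinaseSubstrateMap) -> pd.Series:
    """Per-kinase z for one patient's site -> log2FC vector.

    Sites with missing values are excluded from both substrate sets and the
    background.  Kinases with no observed substrate get NaN.
    """
    observed = phospho_fc_patient.dropna()
    if len(observed) < MIN_BACKGROUND_SITES:
        raise ValueError(
            f"need >= {MIN_BACKGROUND_SITES} observed sites for a stable background"
        )
    bg_mean = float(observed.mean())
    bg_sd = float(observed.std(ddof=1))
    if bg_sd == 0:
        raise ValueError("background has zero standard deviation")

    out = {}
    site_index = observed.index
    for kinase, substrates in ksmap.substrates.items():
        subs = site_index.intersection(sorted(substrates))
        m = len(subs)
        if m == 0:
            out[kinase] = np.nan
            continue
        out[kinase] = (float(observed.loc[subs].mean()) - bg_mean) * np.sqrt(m) / bg_sd
    return pd.Series(out)


def kinase_activity_matrix(
    phospho: PhosphoTable, ksmap: KinaseSubstrateMap, alpha: float = 0.05
) -> KinaseActivity:
    """ksea-z and BH q-values for every kinase across all patients."""
    cols = {
        patient: kinase_z(phospho.log2fc[patient], ksmap)
        for patient in phospho.patient_ids
    }
    z = pd.DataFrame(cols)
    q, _ = kinase_significance(z, alpha=alpha)
    n_sub = pd.Series({k: len(v) for k, v in ksmap.substrates.items()})
    return KinaseActivity(z=z, q=q, n_substrates=n_sub.loc[z.index])


def kinase_significance(
    z: pd.DataFrame, alpha: float = 0.05, scope: str = "patient"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided normal p per entry, BH-adjusted; returns (q, kept mask).

    ``scope="patient"`` (default) adjusts across kinases within each patient;
    ``scope="global"`` adjusts over the whole matrix at once.
    """
    p = pd.DataFrame(
        2.0 * stats.norm.sf(np.abs(z.to_numpy(dtype=float))),
        index=z.index, columns=z.columns,
    )
    q = pd.DataFrame(np.nan, index=z.index, columns=z.columns)
    if scope == "patient":
        for col in p.columns:
            mask = p[col].notna()
            if mask.any():
                q.loc[mask, col] = stats.false_discovery_control(
                    p.loc[mask, col].to_numpy(), method="bh"
                )
    elif scope == "global":
        flat = p.to_numpy().ravel()
        mask = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        adj[mask] = stats.false_discovery_control(flat[mask], method="bh")
        q = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    kept = q <= alpha
    return q, kept


def kinase_substrate_concordance(
    activity: pd.DataFrame, phospho: PhosphoTable, ksmap: KinaseSubstrateMap
) -> pd.DataFrame:
    """Pearson correlation across patients of each kinase's activity with each
    mapped substrate's fold change.

    Rows are (kinase, site) pairs; constant vectors yield NaN with a warning.
    """
    patients = [p for p in activity.columns if p in phospho.log2fc.columns]
    if len(patients) < 4:
        raise ValueError("need >= 4 patients with both kinase and phospho values")
    rows = []
    for kinase in activity.index:
        if kinase not in ksmap.substrates:
            continue
        a = activity.loc[kinase, patients].to_numpy(dtype=float)
        for site in sorted(ksmap.substrates[kinase]):
            if site not in phospho.log2fc.index:
                continue
            fc = phospho.log2fc.loc[site, patients].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(fc))
            if ok.sum() < 4:
                continue
            if np.std(a[ok]) == 0 or np.std(fc[ok]) == 0:
                warnings.warn(f"constant vector for ({kinase}, {site}); skipped")
                rows.append({"kinase": kinase, "site": site,
                             "r": np.nan, "p": np.nan, "n": int(ok.sum())})
                continue
            r, p = stats.pearsonr(a[ok], fc[ok])
            rows.append({"kinase": kinase, "site": site,
                         "r": float(r), "p": float(p), "n": int(ok.sum())})
    return pd.DataFrame(rows, columns=["kinase", "site", "r", "p", "n"])


def group_kinase_profile(
    activity: pd.DataFrame, patient_groups: pd.Series, conf: float = 0.95
) -> pd.DataFrame:
    """Group-wise mean kinase activity with a t confidence interval.

    Rows are (kinase, group); empty groups or all-NaN cells yield NaN means.
    """
    rows = []
    for kinase in activity.index:
        for group in sorted(patient_groups.unique()):
            patients = patient_groups.index[patient_groups == group]
            patients = [p for p in patients if p in activity.columns]
            vals = activity.loc[kinase, patients].dropna().to_numpy(dtype=float)
            n = len(vals)
            if n == 0:
                mean = lo = hi = np.nan
            else:
                mean = float(vals.mean())
                if n > 1 and vals.std(ddof=1) > 0:
                    half = stats.t.ppf(0.5 + conf / 2, df=n - 1) * vals.std(ddof=1) / np.sqrt(n)
                    lo, hi = mean - half, mean + half
                else:
                    lo = hi = mean
            rows.append({"kinase": kinase, "group": group, "n": n,
                         "mean": mean, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows, columns=["kinase", "group", "n", "mean", "ci_low", "ci_high"])
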