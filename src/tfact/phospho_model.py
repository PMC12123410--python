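"""Sparse regression linking phosphosite fold changes to TF activity.

For each TF, the eligible predictors are phosphosites quantified in every
patient whose protein shares at least one pathway with the TF.  An
L1-penalized linear model (fitted on an 80% training split, with the penalty
chosen by 5-fold cross-validation over a descending log-spaced grid) selects
the sites; the nonzero coefficients' SIGNS then partition the sites into the
positive and negative groups whose summed fold changes give the two
phosphorylation scores per patient.

Three outcomes are possible per TF: ``fitted`` (nonzero coefficients),
``no_predictors`` (empty eligible set) and ``all_zero`` (the cross-validated
optimum keeps no site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .io_formats import PathwayCollection, PhosphoTable

logger = logging.getLogger(__name__)

__all__ = [
    "PhosphoModel",
    "PhosphoScore",
    "eligible_predictors",
    "fit_tf_model",
    "phospho_scores",
]

N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-3
MIN_PATIENTS = 20


@dataclass
class PhosphoModel:
    tf: str
    status: str  # fitted | no_predictors | all_zero
    selected: dict[str, float] = field(default_factory=dict)  # site -> coefficient
    lambda_chosen: float = float("nan")
    eligible_sites: list[str] = field(default_factory=list)
    split_seed: int = 0
    holdout_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.status == "fitted" and not self.selected:
            raise ValueError("fitted model must select at least one site")
        if self.status == "no_predictors" and self.eligible_sites:
            raise ValueError("no_predictors model cannot have eligible sites")

    @property
    def positive_sites(self) -> set[str]:
        return {s for s, b in self.selected.items() if b > 0}

    @property
    def negative_sites(self) -> set[str]:
        return {s for s, b in self.selected.items() if b < 0}


@dataclass
class PhosphoScore:
    """Per-patient sums of fold changes over the positive/negative site groups."""

    p_plus: pd.Series
    p_minus: pd.Series


def eligible_predictors(
    tf: str, phospho: PhosphoTable, pathways: PathwayCollection
) -> list[str]:
    """Sites complete in all patients whose protein shares a pathway with the TF."""
    tf_pathways = pathways.pathways_of(tf)
    if not tf_pathways:
        return []
    eligible = []
    for site in phospho.site_ids:
        if not phospho.complete_sites[site]:
            continue
        protein = phospho.protein_of_site[site]
        if pathways.pathways_of(protein) & tf_pathways:
            eligible.append(site)
    return eligible


def _train_test_split_stratified(
    y: np.ndarray, test_frac: float, rng: np.random.Generator, n_bins: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """80/20 split stratified by response quantile, deterministic given rng."""
    n = len(y)
    order = np.argsort(y, kind="stable")
    bins = np.array_split(order, n_bins)
    test = []
    for b in bins:
        k = int(round(test_frac * len(b)))
        if len(b) and k:
            test.extend(rng.choice(b, size=k, replace=False))
    test_idx = np.sort(np.array(test, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return train_idx, test_idx


def _centered_path(x: np.ndarray, y: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Coefficient path on mean-centered data (the intercept is recovered as
    ybar - xbar @ beta); at alphas[0] = lambda_max every coefficient is zero."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    _, coefs, _ = lasso_path(xc, yc, alphas=alphas)
    return coefs


def _lambda_grid(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Descending log-spaced grid from lambda_max (all-zero) to its 1e-3 multiple."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    lambda_max = np.max(np.abs(xc.T @ yc)) / n
    if lambda_max <= 0:
        lambda_max = 1e-12
    return np.geomspace(lambda_max, LAMBDA_MIN_RATIO * lambda_max, N_LAMBDA)


def fit_tf_model(
    tf: str,
    activity_tumor: pd.Series,
    phospho: PhosphoTable,
    pathways: PathwayCollection,
    seed: int = 0,
    standardize: bool = False,
    one_se: bool = True,
) -> PhosphoModel:
    """Fit the per-TF sparse model; fully deterministic given the seed.

    The response is the TF's tumor activity score per patient; predictors are
    the eligible sites' log2 fold changes (unstandardized by default — they
    already share the log2 scale).  The penalty is chosen by the
    one-standard-error rule on the 5-fold CV curve (the selection-oriented
    convention; the raw CV-MSE minimum badly overselects in this regime and
    is available with ``one_se=False``).
    """
    eligible = eligible_predictors(tf, phospho, pathways)
    if not eligible:
        return PhosphoModel(tf=tf, status="no_predictors", split_seed=seed)

    patients = [p for p in activity_tumor.index if p in phospho.log2fc.columns]
    if len(patients) < MIN_PATIENTS:
        raise ValueError(
            f"TF {tf!r}: only {len(patients)} usable patients (< {MIN_PATIENTS})"
        )
    y = activity_tumor.loc[patients].to_numpy(dtype=float)
    x = phospho.log2fc.loc[eligible, patients].to_numpy(dtype=float).T

    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    train_idx, test_idx = _train_test_split_stratified(y, 0.2, rng)
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_te, y_te = x[test_idx], y[test_idx]

    alphas = _lambda_grid(x_tr, y_tr)
    kf = KFold(n_splits=5, shuffle=True, random_state=int(rng.integers(2**31)))
    cv_mse = np.zeros((5, N_LAMBDA))
    for fold, (fit_i, val_i) in enumerate(kf.split(x_tr)):
        coefs = _centered_path(x_tr[fit_i], y_tr[fit_i], alphas)
        mu = y_tr[fit_i].mean()
        pred = x_tr[val_i] @ coefs + (mu - x_tr[fit_i].mean(axis=0) @ coefs)
        cv_mse[fold] = ((pred - y_tr[val_i, None]) ** 2).mean(axis=0)

    mean_mse = cv_mse.mean(axis=0)
    if one_se:
        se = cv_mse.std(axis=0, ddof=1) / np.sqrt(5)
        best = int(np.argmin(mean_mse))
        ok = mean_mse <= mean_mse[best] + se[best]
        choice = int(np.flatnonzero(ok)[0])  # grid descends: first ok = largest lambda
    else:
        choice = int(np.argmin(mean_mse))
    lam = float(alphas[choice])

    coefs_full = _centered_path(x_tr, y_tr, alphas)
    beta = coefs_full[:, choice]
    nonzero = np.flatnonzero(beta)
    if nonzero.size == 0:
        return PhosphoModel(
            tf=tf, status="all_zero", lambda_chosen=lam,
            eligible_sites=eligible, split_seed=seed,
        )

    intercept = y_tr.mean() - x_tr.mean(axis=0) @ beta
    if len(test_idx):
        resid = y_te - (x_te @ beta + intercept)
        ss_tot = ((y_te - y_te.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else float("nan")
    else:
        r2 = float("nan")
    logger.info("TF %s: lambda=%.4g, %d sites, holdout R2=%.3f",
                tf, lam, nonzero.size, r2)

    selected = {eligible[j]: float(beta[j]) for j in nonzero}
    return PhosphoModel(
        tf=tf, status="fitted", selected=selected, lambda_chosen=lam,
        eligible_sites=eligible, split_seed=seed, holdout_r2=float(r2),
    )


def phospho_scores(model: PhosphoModel, phospho: PhosphoTable) -> PhosphoScore:
    """Sum fold changes over positive- and negative-coefficient sites.

    Coefficients are used only for their sign, never as weights.
    """
    if model.status != "fitted":
        raise ValueError(f"TF {model.tf!r}: cannot score a {model.status} model")
    fc = phospho.log2fc
    pos = sorted(model.positive_sites & set(fc.index))
    neg = sorted(model.negative_sites & set(fc.index))
    zero = pd.Series(0.0, index=fc.columns)
    p_plus = fc.loc[pos].sum(axis=0) if pos else zero.copy()
    p_minus = fc.loc[neg].sum(axis=0) if neg else zero.copy()
    return PhosphoScore(p_plus=p_plus, p_minus=p_minus)
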