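"""Synthetic paired tumor/NAT cohort with planted ground truth.

The generator emulates the statistical structure every downstream stage
assumes, at the scale of a 100-patient paired cohort:

* latent per-patient TF activities, standard normal in NAT and shifted in
  tumor;
* signed regulons whose target counts follow the activity on the log scale,
  drawn negative-binomial, with a subset of targets marked as direct via
  super-enhancer records in tissue "lung";
* phosphosite log2 fold changes linear in the tumor-minus-NAT activity
  difference for planted true sites, pure noise for decoys;
* a pathway collection placing each TF with its true-site proteins, and
  decoy proteins elsewhere;
* a kinase-substrate map in which one planted kinase per TF drives that TF's
  true sites;
* exponential survival whose log-hazard is proportional to the tumor
  activity of one designated TF.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionBundle,
    KinaseSubstrateMap,
    PathwayCollection,
    PhosphoTable,
    SERecord,
    SETable,
    SurvivalTable,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "generate_lasso_problem",
    "truth_eval",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generator knobs; defaults mirror the cohort scale the pipeline targets."""

    n_patients: int = 100
    n_genes: int = 2000
    n_tfs: int = 20
    targets_per_tf: int = 50
    frac_negative_targets: float = 0.3
    frac_direct: float = 0.4  # fraction of targets with SE support
    effect_beta: float = 1.0  # log2 expression units per activity unit
    tumor_activity_shift: float = 1.5
    nb_dispersion: float = 0.1
    n_true_sites_per_tf: int = 5
    n_decoy_sites: int = 200
    phospho_noise_sd: float = 0.5
    hazard_log_hr_per_activity: float = 0.7
    censor_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_genes", "n_tfs", "targets_per_tf",
                     "n_true_sites_per_tf", "n_decoy_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_negative_targets", "frac_direct", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_tfs * self.targets_per_tf > self.n_genes - self.n_tfs:
            raise ValueError("targets_per_tf x n_tfs exceeds available genes")


@dataclass
class GroundTruth:
    """Everything planted: consumed only by evaluation code, never by the pipeline."""

    targets: dict[str, dict[str, int]]  # tf -> gene -> mode
    direct: dict[str, set[str]]  # tf -> SE-supported subset of targets
    activity_tumor: pd.DataFrame  # tf x patient latent activity
    activity_nat: pd.DataFrame
    true_sites: dict[str, dict[str, float]]  # tf -> site -> linear weight
    true_kinase_of_tf: dict[str, str]
    hazard: pd.Series  # patient -> true hazard rate
    survival_tf: str  # the TF whose tumor activity drives the hazard

    def target_set(self, tf: str) -> set[str]:
        return set(self.targets[tf])


@dataclass
class Cohort:
    expression: ExpressionBundle
    phospho: PhosphoTable
    se_table: SETable
    pathways: PathwayCollection
    ks_map: KinaseSubstrateMap
    survival: SurvivalTable
    truth: GroundTruth
    config: CohortConfig = field(repr=False, default=None)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture.

    var = mean + dispersion * mean^2; dispersion -> 0 recovers Poisson.
    """
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one full cohort; bit-identical for identical config (seed included)."""
    rng = np.random.default_rng(config.seed)
    P, G, T, K = (config.n_patients, config.n_genes, config.n_tfs,
                  config.targets_per_tf)

    patients = [f"PAT{i + 1:03d}" for i in range(P)]
    tf_names = [f"TF{i + 1:02d}" for i in range(T)]
    other_genes = [f"G{i + 1:05d}" for i in range(G - T)]
    genes = tf_names + other_genes

    # latent activities: NAT standard normal, tumor shifted
    a_nat = rng.normal(0.0, 1.0, size=(T, P))
    a_tum = rng.normal(config.tumor_activity_shift, 1.0, size=(T, P))

    # disjoint target blocks, modes, direct subsets
    targets: dict[str, dict[str, int]] = {}
    direct: dict[str, set[str]] = {}
    pool = list(other_genes)
    n_neg = int(round(config.frac_negative_targets * K))
    n_dir = int(round(config.frac_direct * K))
    for ti, tf in enumerate(tf_names):
        block = pool[ti * K:(ti + 1) * K]
        modes = np.array([-1] * n_neg + [1] * (K - n_neg))
        rng.shuffle(modes)
        targets[tf] = {g: int(m) for g, m in zip(block, modes)}
        dsel = rng.choice(K, size=n_dir, replace=False)
        direct[tf] = {block[j] for j in dsel}

    # expression: log2-scale linear predictor, NB counts around 2**eta
    baseline = rng.uniform(4.0, 8.0, size=G)  # log2 counts
    eta_nat = np.tile(baseline[:, None], (1, P)).astype(float)
    eta_tum = eta_nat.copy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    for ti, tf in enumerate(tf_names):
        # the TF's own transcript tracks its activity with mild noise
        i = gene_pos[tf]
        eta_nat[i] += config.effect_beta * (a_nat[ti] + rng.normal(0, 0.1, P))
        eta_tum[i] += config.effect_beta * (a_tum[ti] + rng.normal(0, 0.1, P))
        for g, mode in targets[tf].items():
            j = gene_pos[g]
            eta_nat[j] += mode * config.effect_beta * a_nat[ti]
            eta_tum[j] += mode * config.effect_beta * a_tum[ti]
    counts_nat = _nb_counts(rng, np.exp2(eta_nat), config.nb_dispersion)
    counts_tum = _nb_counts(rng, np.exp2(eta_tum), config.nb_dispersion)
    expression = ExpressionBundle(
        counts_tumor=pd.DataFrame(counts_tum, index=genes, columns=patients),
        counts_nat=pd.DataFrame(counts_nat, index=genes, columns=patients),
    )

    # super-enhancers marking the direct subsets (two SEs per TF, tissue lung)
    records = []
    for ti, tf in enumerate(tf_names):
        dgenes = sorted(direct[tf])
        half = max(1, len(dgenes) // 2)
        for si, chunk in enumerate((dgenes[:half], dgenes[half:])):
            if not chunk:
                continue
            records.append(
                SERecord(
                    se_id=f"SE_{tf}_{si + 1}",
                    tissue="lung",
                    tf_ids=frozenset({tf}),
                    gene_ids=frozenset(chunk),
                )
            )
    se_table = SETable(records=records)

    # phospho: true sites linear in (a_tum - a_nat); decoys pure noise
    delta = a_tum - a_nat  # T x P
    site_rows, site_ids, protein_of_site = [], [], {}
    true_sites: dict[str, dict[str, float]] = {tf: {} for tf in tf_names}
    residues = np.array(list("STY"))
    for ti, tf in enumerate(tf_names):
        for si in range(config.n_true_sites_per_tf):
            protein = f"SUB{ti + 1:02d}{chr(ord('A') + si)}"
            res = residues[rng.integers(0, 3)]
            site = f"{protein}_{res}{int(rng.integers(1, 999))}"
            # first site per TF responds positively so the planted kinase
            # (which drives phosphorylation up) always has a substrate
            sign = 1.0 if si == 0 else float(rng.choice([-1.0, 1.0]))
            w = float(rng.uniform(0.5, 1.5)) * sign
            fc = w * delta[ti] + rng.normal(0, config.phospho_noise_sd, P)
            site_ids.append(site)
            site_rows.append(fc)
            protein_of_site[site] = protein
            true_sites[tf][site] = w
    decoy_sites = []
    for di in range(config.n_decoy_sites):
        protein = f"DEC{di + 1:04d}"
        res = residues[rng.integers(0, 3)]
        site = f"{protein}_{res}{int(rng.integers(1, 999))}"
        fc = rng.normal(0, config.phospho_noise_sd, P)
        site_ids.append(site)
        site_rows.append(fc)
        protein_of_site[site] = protein
        decoy_sites.append(site)
    log2fc = pd.DataFrame(np.array(site_rows), index=site_ids, columns=patients)
    # a tenth of decoy sites get missing values, exercising the completeness rule
    n_incomplete = config.n_decoy_sites // 10
    for site in decoy_sites[:n_incomplete]:
        hole = rng.integers(0, P)
        log2fc.loc[site, patients[hole]] = np.nan
    phospho = PhosphoTable(log2fc=log2fc, protein_of_site=protein_of_site)

    # pathways: one per TF holding the TF and its true-site proteins;
    # decoy proteins grouped into separate pathways with no TF member
    pathways: dict[str, frozenset[str]] = {}
    for tf in tf_names:
        members = {tf} | {protein_of_site[s] for s in true_sites[tf]}
        pathways[f"PW_{tf}"] = frozenset(members)
    decoy_proteins = sorted({protein_of_site[s] for s in decoy_sites})
    for k in range(0, len(decoy_proteins), 25):
        chunk = decoy_proteins[k:k + 25]
        if chunk:
            pathways[f"PW_DECOY{k // 25 + 1:02d}"] = frozenset(chunk)
    pathway_collection = PathwayCollection(pathways=pathways)

    # kinase-substrate map: one planted kinase per TF driving that TF's
    # positively-responding sites (a kinase raises phosphorylation of all its
    # substrates, so coherently-moving sites only), plus decoy kinases
    substrates: dict[str, frozenset[str]] = {}
    true_kinase_of_tf = {}
    for tf in tf_names:
        kin = f"KIN_{tf}"
        substrates[kin] = frozenset(
            s for s, w in true_sites[tf].items() if w > 0)
        true_kinase_of_tf[tf] = kin
    for k in range(5):
        picks = rng.choice(len(decoy_sites), size=min(8, len(decoy_sites)),
                           replace=False)
        substrates[f"KIN_DECOY{k + 1}"] = frozenset(decoy_sites[j] for j in picks)
    ks_map = KinaseSubstrateMap(substrates=substrates)

    # survival: exponential, log-hazard proportional to one TF's tumor activity
    survival_tf = tf_names[0]
    base_rate = math.log(2.0) / 36.0  # median ~36 months at activity 0
    hazard = base_rate * np.exp(config.hazard_log_hr_per_activity * a_tum[0])
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        # independent exponential censoring calibrated so that the expected
        # censored fraction matches censor_rate at the cohort's mean hazard
        c_rate = float(hazard.mean()) * config.censor_rate / (1.0 - config.censor_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=P)
    else:
        censor_time = np.full(P, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    survival = SurvivalTable(
        data=pd.DataFrame({"time": time, "event": event}, index=patients)
    )

    truth = GroundTruth(
        targets=targets,
        direct=direct,
        activity_tumor=pd.DataFrame(a_tum, index=tf_names, columns=patients),
        activity_nat=pd.DataFrame(a_nat, index=tf_names, columns=patients),
        true_sites=true_sites,
        true_kinase_of_tf=true_kinase_of_tf,
        hazard=pd.Series(hazard, index=patients),
        survival_tf=survival_tf,
    )
    return Cohort(
        expression=expression,
        phospho=phospho,
        se_table=se_table,
        pathways=pathway_collection,
        ks_map=ks_map,
        survival=survival,
        truth=truth,
        config=config,
    )


def generate_lasso_problem(
    n_patients: int = 100,
    n_true_sites: int = 5,
    n_decoy_sites: int = 200,
    noise_sd: float = 0.5,
    seed: int = 0,
    tf: str = "TF01",
) -> tuple[pd.Series, PhosphoTable, PathwayCollection]:
    """Planted sparse-regression fixture where ALL sites are eligible predictors.

    Unlike the cohort generator (whose decoy proteins live in pathways without
    the TF), every site here sits on a protein sharing one pathway with the
    TF, so sparse selection must reject the decoys on the data alone.
    Returns (response, phospho table, pathways); the response is a linear
    combination of the first ``n_true_sites`` sites' fold changes plus noise,
    with weights drawn exactly as in the cohort generator's phospho model
    (magnitudes uniform on [0.5, 1.5], random signs).
    """
    rng = np.random.default_rng(seed)
    patients = [f"PAT{i + 1:03d}" for i in range(n_patients)]
    n_sites = n_true_sites + n_decoy_sites
    fc = rng.normal(0.0, 1.0, size=(n_sites, n_patients))
    site_ids = []
    protein_of_site = {}
    for i in range(n_sites):
        kind = "TRUE" if i < n_true_sites else "DEC"
        protein = f"{kind}{i + 1:04d}"
        site = f"{protein}_S{i + 1}"
        site_ids.append(site)
        protein_of_site[site] = protein

    weights = rng.uniform(0.5, 1.5, n_true_sites) * rng.choice(
        [-1.0, 1.0], n_true_sites
    )
    y = weights @ fc[:n_true_sites] + rng.normal(0, noise_sd, n_patients)
    response = pd.Series(y, index=patients)

    phospho = PhosphoTable(
        log2fc=pd.DataFrame(fc, index=site_ids, columns=patients),
        protein_of_site=protein_of_site,
    )
    pathways = PathwayCollection(
        pathways={"PW_ALL": frozenset([tf] + list(protein_of_site.values()))}
    )
    return response, phospho, pathways


def truth_eval(
    predicted_sets: dict[str, set[str]], truth_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Set precision/recall per TF for predicted regulons/direct subsets/sites.

    Empty predictions yield precision NaN (undefined) and recall 0.
    """
    unknown = set(predicted_sets) - set(truth_sets)
    if unknown:
        raise ValueError(f"unknown TF id(s): {sorted(unknown)}")
    rows = {}
    for tf, pred in predicted_sets.items():
        true = truth_sets[tf]
        tp = len(pred & true)
        precision = tp / len(pred) if pred else float("nan")
        recall = tp / len(true) if true else float("nan")
        rows[tf] = {"precision": precision, "recall": recall,
                    "n_pred": len(pred), "n_true": len(true)}
    return pd.DataFrame.from_dict(rows, orient="index")


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)


def write_cohort(cohort: Cohort, out_dir) -> dict[str, str]:
    """Write all seven artifacts in the io_formats dialects plus truth.json.

    Returns a name -> path manifest.  TF list and ground truth are written as
    plain text/JSON; everything round-trips through io_formats readers.
    """
    from pathlib import Path
    import json

    from . import io_formats as io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tumor_counts": out / "counts_tumor.tsv",
        "nat_counts": out / "counts_nat.tsv",
        "pairing": out / "pairing.tsv",
        "phospho": out / "phospho_log2fc.tsv",
        "se_table": out / "se_table.tsv",
        "gmt": out / "pathways.gmt",
        "ks_map": out / "kinase_substrates.tsv",
        "survival": out / "survival.csv",
        "tf_list": out / "tf_list.txt",
        "truth": out / "truth.json",
    }
    io.write_expression(cohort.expression, paths["tumor_counts"],
                        paths["nat_counts"], paths["pairing"])
    io.write_phospho(cohort.phospho, paths["phospho"])
    io.write_se_table(cohort.se_table, paths["se_table"])
    io.write_gmt(cohort.pathways, paths["gmt"])
    io.write_ks_map(cohort.ks_map, paths["ks_map"])
    io.write_survival(cohort.survival, paths["survival"])
    tf_names = sorted(cohort.truth.targets)
    paths["tf_list"].write_text("\n".join(tf_names) + "\n")
    truth = cohort.truth
    truth_json = {
        "targets": truth.targets,
        "direct": {tf: sorted(s) for tf, s in truth.direct.items()},
        "true_sites": truth.true_sites,
        "true_kinase_of_tf": truth.true_kinase_of_tf,
        "survival_tf": truth.survival_tf,
        "activity_tumor": {tf: [round(v, 10) for v in row]
                           for tf, row in truth.activity_tumor.iterrows()},
        "activity_nat": {tf: [round(v, 10) for v in row]
                         for tf, row in truth.activity_nat.iterrows()},
        "patients": list(truth.activity_tumor.columns),
        "config": config_to_dict(cohort.config) if cohort.config else None,
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
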