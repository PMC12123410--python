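"""End-to-end orchestration: io -> regulons -> direct targets -> MRA ->
activity -> phospho models -> survival -> kinases, with seeded determinism
and a manifest of everything written.

Every stage writes its artifacts under the output directory and appends a
stage record (row counts, dropped entities, seeds) to the manifest.  A stage
failure aborts the run with the stage name and offending entity in the
message.  Reruns with the same inputs and seeds are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io_formats as io
from .activity_scores import activity_matrix, score_structure, vst
from .direct_targets import filter_all
from .kinase_activity import (
    group_kinase_profile,
    kinase_activity_matrix,
    kinase_substrate_concordance,
)
from .mra import mra_all, paired_signature
from .phospho_model import fit_tf_model, phospho_scores
from .regulon_inference import InferenceParams, infer_regulons
from .survival_integration import (
    StratifiedCohort,
    combined_strata,
    km_logrank,
    median_split,
    quadrant_groups,
    worst_direction,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_all", "tf_funnel_report"]

STAGES = [
    "io", "regulon", "direct_targets", "mra",
    "activity", "phospho_model", "survival", "kinase",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    tumor_counts: str
    nat_counts: str
    pairing: str
    tf_list: str  # one TF id per line
    phospho: str
    se_table: str
    gmt: str
    ks_map: str
    survival: str
    out_dir: str
    tissue: str = "lung"
    inference: InferenceParams = field(default_factory=InferenceParams)
    alpha_nes: float = 0.05
    alpha_km: float = 0.05
    alpha_fdr: float = 0.05
    seed_bootstrap: int = 0
    seed_lasso: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_nes", "alpha_km", "alpha_fdr"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0,1)")


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label, float_format="%.10g")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seeds": {"bootstrap": config.seed_bootstrap, "lasso": config.seed_lasso},
        "stages": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    # -- io ----------------------------------------------------------------
    try:
        bundle = io.read_expression(config.tumor_counts, config.nat_counts,
                                    config.pairing)
        tf_ids = [ln.strip() for ln in Path(config.tf_list).read_text().splitlines()
                  if ln.strip()]
        phospho = io.read_phospho(config.phospho)
        se_table = io.read_se_table(config.se_table, config.tissue)
        pathways = io.read_gmt(config.gmt)
        ksmap = io.read_ks_map(config.ks_map)
        survival = io.read_survival(config.survival)
    except Exception as e:  # noqa: BLE001 - rewrap with stage name
        raise PipelineError("io", str(e)) from e
    record("io", n_genes=len(bundle.gene_ids), n_patients=bundle.n_patients,
           n_tfs_input=len(tf_ids), n_sites=len(phospho.site_ids),
           n_se_records=len(se_table), n_pathways=len(pathways),
           n_kinases=len(ksmap))

    # -- regulon inference on NAT ------------------------------------------
    try:
        nat_vst = vst(bundle.counts_nat)
        tumor_vst = vst(bundle.counts_tumor)
        regulons = infer_regulons(nat_vst, tf_ids, config.inference,
                                  seed=config.seed_bootstrap)
        io.write_regulons(regulons, out / "regulons.tsv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("regulon", str(e)) from e
    record("regulon", n_tfs=len(regulons),
           n_edges=int(sum(len(r) for r in regulons.values())),
           dropped=sorted(set(tf_ids) - set(regulons)))

    # -- direct-target filtering -------------------------------------------
    try:
        direct_regulons, summary = filter_all(regulons, se_table)
        io.write_regulons(direct_regulons, out / "direct_regulons.tsv")
        _write_tsv(pd.DataFrame(summary.rows), out / "direct_summary.tsv")
    except Exception as e:
        raise PipelineError("direct_targets", str(e)) from e
    record("direct_targets", n_tfs=len(direct_regulons),
           dropped=sorted(set(regulons) - set(direct_regulons)))

    # -- MRA ----------------------------------------------------------------
    try:
        signature = paired_signature(tumor_vst, nat_vst)
        mra_result = mra_all(direct_regulons, signature, alpha=config.alpha_nes)
        _write_tsv(mra_result.table.sort_index(), out / "mra.tsv", "tf")
    except Exception as e:
        raise PipelineError("mra", str(e)) from e
    significant = sorted(mra_result.significant)
    record("mra", n_tfs=len(mra_result.table), n_significant=len(significant),
           dropped=sorted(set(mra_result.table.index) - set(significant)))

    # -- activity scores ----------------------------------------------------
    try:
        sig_regulons = {tf: direct_regulons[tf] for tf in significant}
        if not sig_regulons:
            raise ValueError("no TF passed the NES screen")
        act = activity_matrix(tumor_vst, nat_vst, sig_regulons)
        structure = score_structure(act)
        scores_out = act.scores.sort_index().copy()
        scores_out.loc["__condition__"] = act.condition
        _write_tsv(scores_out, out / "activity.tsv", "tf")
        _write_tsv(structure.coordinates, out / "activity_pca.tsv", "sample")
        _write_tsv(structure.correlation.sort_index().sort_index(axis=1),
                   out / "activity_correlation.tsv", "tf")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("activity", str(e)) from e
    record("activity", n_tfs=int(act.scores.shape[0]),
           n_samples=int(act.scores.shape[1]),
           dropped=sorted(set(sig_regulons) - set(act.scores.index)))

    # -- phospho models -----------------------------------------------------
    patients = bundle.patient_ids
    models, score_rows = {}, []
    try:
        for tf in sorted(act.scores.index):
            response = act.tumor_columns().loc[tf]
            response.index = [c[:-2] for c in response.index]  # strip "-T"
            model = fit_tf_model(tf, response, phospho, pathways,
                                 seed=config.seed_lasso)
            models[tf] = model
            if model.status == "fitted":
                ps = phospho_scores(model, phospho)
                for p in patients:
                    score_rows.append({"patient": p, "tf": tf,
                                       "p_plus": ps.p_plus.get(p, np.nan),
                                       "p_minus": ps.p_minus.get(p, np.nan)})
        models_json = {
            tf: {"status": m.status, "lambda": m.lambda_chosen,
                 "holdout_r2": m.holdout_r2,
                 "selected": {s: round(c, 10) for s, c in sorted(m.selected.items())}}
            for tf, m in models.items()
        }
        (out / "phospho_models.json").write_text(
            json.dumps(models_json, indent=2, sort_keys=True, allow_nan=True))
        _write_tsv(pd.DataFrame(score_rows,
                                columns=["patient", "tf", "p_plus", "p_minus"]),
                   out / "phospho_scores.tsv")
    except Exception as e:
        raise PipelineError("phospho_model", str(e)) from e
    fitted = sorted(tf for tf, m in models.items() if m.status == "fitted")
    record("phospho_model", n_models=len(models), n_fitted=len(fitted),
           statuses={tf: m.status for tf, m in sorted(models.items())},
           dropped=sorted(set(models) - set(fitted)))

    # -- survival -----------------------------------------------------------
    try:
        strata_rows, result_rows = [], []
        labels_by_tf, worst_by_tf, km_significant = {}, {}, []
        tumor_act = act.tumor_columns().copy()
        tumor_act.columns = [c[:-2] for c in tumor_act.columns]
        for tf in fitted:
            labels = median_split(tumor_act.loc[tf])
            res = km_logrank(StratifiedCohort(labels, f"median:{tf}"), survival)
            labels_by_tf[tf] = labels
            worst_by_tf[tf] = worst_direction(labels, survival)
            strata_rows += [{"patient": p, "scheme": f"median:{tf}", "label": l}
                            for p, l in labels.items()]
            result_rows.append({"scheme": f"median:{tf}",
                                "groups": "low,high", "chisq": res.statistic,
                                "df": res.df, "p": res.p})
            if res.p <= config.alpha_km:
                km_significant.append(tf)
        if len(km_significant) >= 2:
            combo = combined_strata(
                {tf: labels_by_tf[tf] for tf in km_significant},
                {tf: worst_by_tf[tf] for tf in km_significant})
            res = km_logrank(
                StratifiedCohort(combo.astype(str), "combined"), survival)
            strata_rows += [{"patient": p, "scheme": "combined", "label": l}
                            for p, l in combo.items()]
            result_rows.append({"scheme": "combined",
                                "groups": ",".join(map(str, sorted(combo.unique()))),
                                "chisq": res.statistic, "df": res.df, "p": res.p})
        # quadrant scheme needs a non-degenerate positive phospho score:
        # take the first fitted TF whose model selected positive-coefficient
        # sites (a negative-only model has P+ identically zero)
        quadrant_tf = None
        for tf in fitted:
            if models[tf].positive_sites:
                quadrant_tf = tf
                break
        if quadrant_tf is not None:
            ps = phospho_scores(models[quadrant_tf], phospho)
            quads = quadrant_groups(tumor_act.loc[quadrant_tf], ps.p_plus)
            res = km_logrank(StratifiedCohort(quads, f"quadrant:{quadrant_tf}"),
                             survival)
            strata_rows += [{"patient": p, "scheme": f"quadrant:{quadrant_tf}",
                             "label": l} for p, l in quads.items()]
            result_rows.append({"scheme": f"quadrant:{quadrant_tf}",
                                "groups": "Q1,Q2,Q3,Q4",
                                "chisq": res.statistic, "df": res.df, "p": res.p})
        _write_tsv(pd.DataFrame(strata_rows,
                                columns=["patient", "scheme", "label"]),
                   out / "strata.tsv")
        _write_tsv(pd.DataFrame(result_rows,
                                columns=["scheme", "groups", "chisq", "df", "p"]),
                   out / "survival_results.tsv")
    except Exception as e:
        raise PipelineError("survival", str(e)) from e
    record("survival", n_schemes=len(result_rows),
           km_significant=km_significant, worst_direction=worst_by_tf)

    # -- kinase activity ----------------------------------------------------
    try:
        ka = kinase_activity_matrix(phospho, ksmap, alpha=config.alpha_fdr)
        _write_tsv(ka.z.sort_index(), out / "kinase_z.tsv", "kinase")
        _write_tsv(ka.q.sort_index(), out / "kinase_q.tsv", "kinase")
        conc = kinase_substrate_concordance(ka.z, phospho, ksmap)
        _write_tsv(conc, out / "kinase_concordance.tsv")
        if quadrant_tf is not None:
            profile = group_kinase_profile(ka.z, quads)
            _write_tsv(profile, out / "kinase_group_profile.tsv")
    except Exception as e:
        raise PipelineError("kinase", str(e)) from e
    record("kinase", n_kinases=int(ka.z.shape[0]),
           n_significant_entries=int((ka.q.to_numpy() <= config.alpha_fdr).sum()),
           n_concordance_pairs=len(conc))

    funnel = tf_funnel_report(manifest, tf_ids)
    _write_tsv(funnel, out / "tf_funnel.tsv")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def tf_funnel_report(manifest: dict, tf_ids: list[str]) -> pd.DataFrame:
    """Per-stage TF counts: input -> inferred regulon -> SE-supported ->
    NES-significant -> fitted phospho model, with drops accounted."""
    st = manifest["stages"]
    counts = [
        ("input", len(tf_ids), ""),
        ("regulon>=min_targets", st["regulon"]["n_tfs"],
         f"{len(st['regulon']['dropped'])} below min_targets or skipped"),
        ("se_supported", st["direct_targets"]["n_tfs"],
         f"{len(st['direct_targets']['dropped'])} without SE-bound targets"),
        ("nes_significant", st["mra"]["n_significant"],
         f"{len(st['mra']['dropped'])} not significant"),
        ("phospho_fitted", st["phospho_model"]["n_fitted"],
         f"{len(st['phospho_model']['dropped'])} no_predictors/all_zero"),
    ]
    df = pd.DataFrame(counts, columns=["stage", "n_tfs", "drop_reason"])
    if (df["n_tfs"].diff().dropna() > 0).any():
        raise PipelineError("funnel", "TF counts increased between stages")
    return df
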