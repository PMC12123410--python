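# tfact

Transcription-factor (TF) activity inference from paired tumor / normal-
adjacent-tissue (NAT) omics, for systems-biology analyses of matched patient
cohorts. The package chains the stages such a study needs into one tested,
seeded pipeline:

1. **Regulon inference** — signed TF target sets from NAT coexpression.
   An edge TF–gene is kept when the two-sided Pearson test passes
   `p ≤ 1e-8` on the full data *and* re-passes it in ≥ 50% of 1000 bootstrap
   resamples; the mode is sign(r), and TFs with fewer than 20 surviving
   targets are excluded.
2. **Direct-target filtering** — each regulon is intersected with the genes
   regulated by super-enhancers (SEs) bound by that TF in the tissue of
   interest, as stated by an SE annotation table.
3. **Master regulator analysis (MRA)** — a paired tumor-vs-NAT signature
   z(g) (paired t statistic mapped through the t CDF) is summarized per TF
   as a normalized enrichment score, NES = Σ_t mode_t·z_t / √m, with an
   analytic two-sided normal p-value. NES > 0 means the TF's activated
   targets are up and its repressed targets are down in tumors.
4. **Per-sample activity scores** — for each TF and sample,
   score = Σ over positive direct targets of the variance-stabilized
   expression minus the Σ over negative targets; plus PCA and the TF × TF
   activity-correlation matrix.
5. **Phospho modeling** — per TF, an L1-penalized regression (5-fold CV over
   a 100-point lambda grid, one-SE rule, 80/20 train/test split) selects the
   phosphosites whose tumor/NAT log2 fold changes predict the TF's tumor
   activity; predictors are restricted to sites quantified in all patients
   and located on proteins sharing a pathway with the TF. The selected
   sites' coefficient *signs* define two per-patient phosphorylation scores
   P⁺ and P⁻ (plain sums of fold changes).
6. **Survival stratification** — median splits of activity scores,
   combined strata counting worst-prognosis-side memberships across TFs,
   and quadrant groups crossing activity with P⁺; Kaplan–Meier curves and
   log-rank tests throughout.
7. **Kinase activity** — a KSEA-style substrate z-score per kinase and
   patient, z = (substrate mean − background mean)·√m / background sd, with
   Benjamini–Hochberg FDR control across kinases within each patient, and
   kinase–substrate concordance correlations.

A synthetic-cohort generator (`tfact.synthetic_data`) plants every piece of
ground truth the stages estimate — signed regulons, SE-supported direct
subsets, latent activities, activity-driven phosphosites, kinase–substrate
maps, and activity-linked survival — so the whole pipeline is validated
end-to-end against known answers.

## Worked example

```bash
tfact demo --seed 7 --out demo
```

generates a 100-patient cohort (2000 genes, 20 TFs with 50 targets each,
tumor activity shift 1.5) and runs every stage. Highlights from the written
artifacts:

* `results/tf_funnel.tsv` — all 20 TFs survive every filter on this cohort:

  ```
  stage                  n_tfs  drop_reason
  input                  20
  regulon>=min_targets   20     0 below min_targets or skipped
  se_supported           20     0 without SE-bound targets
  nes_significant        20     0 not significant
  phospho_fitted         20     0 no_predictors/all_zero
  ```

* `results/mra.tsv` — every TF has a large positive NES (e.g. TF01:
  NES = 35.78, p ≈ 2.5e-280 over 20 direct targets), as expected when the
  planted tumor shift saturates the paired signature at the z-cap of 8.

* `results/survival_results.tsv` — the median split of TF01 (the TF whose
  activity drives the planted hazard, log-HR 0.7) separates survival at
  chi² = 18.26, p = 1.9e-05, while a non-planted TF such as TF02 shows
  p = 0.92.

Regulon recovery on this cohort is exact: precision = recall = 1.0 and
mode-sign accuracy = 1.0 against the planted targets (see
`tests/test_regulon_inference.py`).

## CLI

`tfact` exposes each stage (`synth`, `io-validate`, `normalize`, `regulon`,
`direct`, `mra`, `activity`, `phospho`, `survive`, `kinase`), the full
pipeline (`run-all --config cfg.yaml`), and the one-command `demo`.

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
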