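# Methods

This note documents the statistical procedures, the synthetic-data model the
package is validated against, the defaults and why they were chosen, and the
known limitations.

## Regulon inference

Given a variance-stabilized NAT expression matrix (genes × samples) and a TF
list, a candidate edge TF–g is scored by the Pearson correlation r over
samples, with the usual two-sided test t = r√(n−2)/√(1−r²) on n−2 df. An
edge is retained iff p ≤ `p_threshold` (default 1e-8) on the full data *and*
the edge re-reaches that threshold in at least `min_support` (default 0.5)
of `n_bootstraps` (default 1000) resamples of the samples with replacement.
The mode of a retained edge is sign(r). TFs retaining fewer than
`min_targets` (default 20) edges are dropped before any downstream stage; no
minimum is applied again after SE filtering.

Bootstrap support is a stability filter: it can only remove edges, never add
them, so the expected false-edge count per TF is at most
(n_genes − 1)·p_threshold. Zero-variance genes are excluded from the
candidate pool; TFs absent from the matrix or constant are skipped with a
warning; fewer than 4 samples is an error (the t test needs n ≥ 4).

The procedure is deliberately transparent — plain correlation, explicit
bootstrap, explicit thresholds — so that every edge decision can be
recomputed by hand. Mutual-information networks and pruning heuristics (DPI
and the like) are out of scope.

## Direct-target filtering

The SE table states, per super-enhancer, the bound TFs and the regulated
genes in a given tissue (filtered case-insensitively at read time). The
direct-target set of a TF is the union of regulated genes over SEs that list
the TF as bound; a regulon is filtered by intersection with that set, with
edge statistics carried through unchanged. Binding is taken as given — the
package does no motif scanning and no coordinate arithmetic. TFs whose
filtered regulon is empty are reported as filtered-out, not raised.

## Paired signature and MRA

For each gene, the per-patient difference d = tumor − NAT gives a paired
t statistic, mapped through the t CDF (n−1 df) and the standard-normal
quantile to a signed z. Zero-variance differences map to ±`Z_CAP` (= 8) when
the mean is nonzero, to 0 when all differences are zero; all z are clipped
to ±8. The cap keeps degenerate genes finite without letting them dominate.

The NES of a regulon with m usable targets is Σ_t mode_t·z_t / √m. Under the
null that target z's are iid standard normal, NES ~ N(0,1), which yields the
analytic two-sided p. The statistic is unweighted — bootstrap support and |r|
do not enter — because sign semantics are the only regulon property the
score depends on. A 100 000-draw permutation oracle (random signed gene sets
from the same signature) agrees with the analytic p to ±0.02 in the test
suite. Targets missing from the signature are dropped and counted; a TF with
zero usable targets is a no-score outcome, not an error.

## Normalization and activity scores

Counts are normalized with a simplified variance-stabilizing transform,
named `vst-simple` in outputs: per-sample size factors are the
median-of-ratios against each gene's geometric mean (genes with any zero
count are excluded from the size-factor computation), and the transformed
value is log2(count/size_factor + 1). This keeps the two properties the
downstream scores rely on — library-size removal and variance compression —
with no fitted dispersion model.

A TF's activity in a sample is Σ over positive direct targets of the
transformed expression minus Σ over negative targets. Scores are linear in
the expression matrix and negate exactly under a mode flip. Raw scores feed
the survival stages (median splits are equivariant under monotone
transforms, so no per-TF scaling is applied there); within
`score_structure` only, TF rows are centered and unit-scaled before PCA
(a `standardize=False` escape hatch exists). The TF × TF correlation matrix
is computed on tumor columns only; constant rows are excluded with a
warning. Dendrogram cutting and cluster naming are out of scope.

## Phospho modeling

Eligible predictors for a TF are phosphosites (ids normalized to
`PROTEIN_RESIDUEPOS`, residue ∈ {S,T,Y}) that are quantified in every
patient and whose protein shares at least one pathway with the TF in the
supplied GMT collection. The response is the TF's tumor-sample activity
score per patient; NAT scores are never used as responses. Predictors enter
unstandardized (fold changes already share the log2 scale); a
`standardize=True` flag exists.

The fit is an L1-penalized least squares on an 80% training split
(stratified by response quintile, seeded). The penalty grid has 100
log-spaced values from λ_max (the smallest penalty with an all-zero
solution, computed on centered data) down to 1e-3·λ_max. λ is chosen by
5-fold cross-validation (seeded folds) with the **one-standard-error rule**:
the largest λ whose mean CV MSE is within one standard error of the minimum.
The raw CV-minimum is available via `one_se=False` but badly overselects
when used for support recovery — on planted data (5 true sites among 200
decoys, n = 100) it admits ~15–20 spurious sites per fit, a behavior we
reproduced with an independent R glmnet implementation (`lambda.min`:
11–28 false selections on identical data), whereas the one-SE rule keeps
~5 with perfect recall of the planted sites. The 20% holdout R² is logged
but nothing downstream depends on it.

Three outcomes per TF: `fitted` (nonzero coefficients at the chosen λ),
`no_predictors` (empty eligible set — e.g. a TF whose pathways contain no
quantified substrate), and `all_zero` (the CV-chosen λ keeps nothing; on
pure-noise inputs this occurs in ≥ 90% of replicates).

The phosphorylation scores use coefficient signs only: P⁺(patient) is the
plain sum of fold changes over positive-coefficient sites, P⁻ over
negative-coefficient sites.

## Survival stratification

`median_split` labels a patient low iff score ≤ median (even n: midpoint of
the two middle values); ties at the median go to "low" — a fixed rule that
keeps splits deterministic. Groups are compared by the k-group log-rank test
(k−1 df) with Kaplan–Meier curves per group; log-rank is the only test
fitted — no Cox models. The worse-prognosis side of a split is determined
from the data as the side with the smaller restricted-mean survival time up
to the last observed time, never hard-coded. Combined strata count, per
patient, the TFs for which the patient sits on the worse side. Quadrant
groups cross the activity median split with the P⁺ median split: Q2 = both
high, Q4 = both low (concordant), Q1/Q3 discordant.

## Kinase activity

For one patient, a kinase with m observed substrates gets
z = (mean substrate fold change − mean over all observed sites)·√m / sd over
all observed sites — a KSEA-style statistic, named `ksea-z` in outputs. It
is exactly invariant to adding a constant to, or positively rescaling, all
of a patient's fold changes. At least 10 observed sites are required for a
stable background. Two-sided normal p-values are BH-adjusted across kinases
*within each patient* (a `scope="global"` alternative exists), and entries
with q ≤ 0.05 are flagged. Concordance is the Pearson correlation, across
patients, of a kinase's z with each mapped substrate's fold change. No
network propagation or site-functional weighting is performed; the
substrate map is caller-supplied and no kinase–substrate database is
bundled.

## Synthetic cohort

The generator emulates a 100-patient paired design with planted truth;
every draw flows from one seed.

* **Latent activity**: a_{tf,patient} ~ N(0,1) in NAT and N(shift,1) in
  tumor, with `tumor_activity_shift` = 1.5 by default. All TFs receive the
  shift — setting it to 0 produces the null cohort used for calibration
  checks. Tumor and NAT activities are drawn independently.
* **Expression**: each TF owns a disjoint block of `targets_per_tf` (50)
  target genes, 30% with negative mode; the log2-scale linear predictor is
  baseline_g + mode·β·a (β = `effect_beta` = 1), the TF's own transcript
  tracks its activity with sd-0.1 noise, and counts are negative-binomial
  (gamma–Poisson, dispersion 0.1) around the exponentiated predictor.
  Baselines are uniform on 4–8 log2 units (~16–256 counts).
* **Super-enhancers**: 40% of each TF's targets (`frac_direct`) are marked
  direct via two lung-tissue SE records bound by that TF.
* **Phospho**: each TF has 5 true sites with fold change
  w·(a_tumor − a_NAT) + N(0, 0.5), |w| ~ U(0.5, 1.5) with random sign (the
  first site per TF is forced positive); 200 decoy sites are N(0, 0.5)
  noise, a tenth of them with a missing value to exercise the completeness
  rule. The GMT places each TF with its true-site proteins in one pathway
  and decoy proteins in separate TF-free pathways.
* **Kinases**: one planted kinase per TF whose substrates are that TF's
  positively-responding true sites (a kinase drives phosphorylation up, so
  only coherently moving sites are its substrates), plus 5 decoy kinases on
  decoy sites.
* **Survival**: exponential event times with log-hazard
  0.7·a_tumor of one designated TF (the first; recorded in the ground
  truth), baseline median ~36 time units; independent exponential censoring
  calibrated to the target censored fraction (0.4) at the cohort's mean
  hazard. With `censor_rate=0` every event is observed.

What the generator does **not** emulate: real count marginals, batch
effects, shared targets between TFs, pathway overlap beyond the planted
one-pathway-per-TF structure, missingness beyond complete/incomplete flags,
non-proportional hazards. Passing tests therefore demonstrate correctness
of the estimators under the planted model, not performance on real cohorts.

A separate fixture, `generate_lasso_problem`, plants the sparse-regression
problem with *all* sites eligible (true and decoy proteins share one pathway
with the TF), so selection must reject decoys on the data alone.

## Numerical choices and degenerate inputs

* Pearson p at |r| = 1 is exactly 0; bootstrap resamples with constant rows
  count as failures for the edge.
* Signature z-cap = 8 (normal two-sided p ~ 1e-15, far past any threshold
  in use).
* NES p is floored at the smallest positive double so it is never 0.
* Lambda grid on centered data so λ_max is exact; coefficients at the chosen
  λ are taken from a path fit on the full training split.
* Median ties → "low"; quadrant ties follow the same rule on each axis.
* All-zero count matrices, degenerate splits, sub-minimum sample counts and
  zero-background-sd phospho vectors raise errors naming the offending
  entity; empty SE filter results and no-score TFs are reported, not raised.

## Pipeline and problem sizes

`run_all` executes io → regulon → direct targets → MRA (α = 0.05 screen) →
activity → phospho models → survival (median, combined over KM-significant
TFs, quadrant on the first fitted TF with a usable P⁺) → kinases
(FDR ≤ 0.05), writing TSV/JSON artifacts and a manifest with per-stage
counts, drops and seeds (no timestamps — reruns are byte-identical). The
default demo cohort (2000 genes, 20 TFs, 100 patients, 1000 bootstraps)
runs in well under a minute on one CPU; the acceptance script's replicate
counts (100 power replicates, 1000 null replicates, 50 noise fits) were
chosen to keep Monte-Carlo error small at desk scale.

## Known limitations

* The regulon stage is a correlation network: indirect co-regulation is
  only removed insofar as the SE filter removes it.
* The NES null assumes target z's are iid standard normal; heavy
  correlation among a TF's targets in real data inflates |NES|.
* The one-SE LASSO still admits a handful of spurious sites when the signal
  is strong (see above); selected-site lists should be treated as
  candidates, not as a controlled-FDR set.
* Kinase z treats substrates as exchangeable and ignores site-level
  functional weights.
* Survival analysis assumes proportional hazards and uninformative
  censoring, as planted.
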