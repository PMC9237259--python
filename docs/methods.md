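# Methods

## Setting and data model

The package analyzes four-group c-Fos mapping experiments: per-animal
counts of c-Fos-positive cells in 30 brain regions (grouped into cortex,
basal ganglia, hippocampus, thalamus, hypothalamus, midbrain, hindbrain),
group labels (untreated "Naive", MPTP-lesioned, MPTP + acupuncture, MPTP +
sham acupuncture), and optional outcome columns: rotarod latency (seconds,
capped at 480), cylinder-test rearings, striatal tyrosine-hydroxylase (TH)
optical density (`th_st`), and nigral TH-positive cell count (`th_sn`).
Region abbreviations are the canonical join key everywhere; full names are
display-only. Group labels default to the four above (stored ASCII,
case-sensitive) but are configurable.

The packaged summary table carries each region's group mean ± SEM at
n = 6/group. Because the study's raw per-animal table is not publicly
deposited, every per-animal computation in the test suite and the
acceptance script runs on synthetic cohorts drawn from that summary (see
below); results on real cohort files use the identical code path via
`read_cohort`.

## Summary-based ANOVA

For groups g with mean m_g, SEM s_g and size n_g:

* SS_between = Σ n_g (m_g − m̄)², df = G − 1, with m̄ the n-weighted grand
  mean;
* MS_within = Σ (n_g − 1)(s_g² n_g) / Σ (n_g − 1), df = N − G;
* F = MS_between / MS_within, p from the F(df_between, df_within) tail.

This is algebraically identical to the raw-data decomposition whenever the
summaries were computed from the raw values (any n), which the suite
verifies against an independent raw-data route (`scipy.stats.f_oneway`) to
1e−10. Zero pooled variance with unequal means is reported as F = ∞, p = 0
rather than overflowing. Tukey HSD post hoc p-values come from the
studentized-range distribution (`scipy.stats.tukey_hsd`), cross-checked
against statsmodels in the tests. No multiple-testing correction is applied
across the 30 per-region ANOVAs by default — that mirrors the per-region
reporting convention of this experiment class — and correlation-report
significance stars default to α = 0.001 while the ANOVA stage uses 0.05;
both are arguments, not constants.

## Networks, centralities, hubs

Edges are within-group cross-animal correlations. Thresholding is strict
(r > τ) on signed r by default; "absolute" mode (|r| > τ) is a flag, since
negative-edge handling is a genuine reporting ambiguity in this literature.
Defaults: τ = 0.6 whole-brain, τ = 0.5 for the seven motor regions.
Isolated nodes are always retained. Degree is the binary count of incident
supra-threshold edges (a summed-|r| "strength" variant is a flag);
betweenness is unnormalized shortest-path betweenness on the binarized
graph, each unordered pair counted once, pairs in different components
contributing zero (a 1 − r distance-weighted variant is a flag). Binary
degree is the default because the hub criterion "degree ≥ 5" only makes
sense for integer counts.

Hub rule: degree ≥ 5 AND betweenness min-rank ≤ 10 (descending ranks, ties
share the minimum rank, so boundary ties are all included — with 30 regions
rank ≤ 10 is the top third). The hub set equals the intersection of the two
qualified lists; the package reproduces the published single MPTP hub
(AcbSh) and the eight acupuncture hubs (M1, DG, CA3, Cg1, PHA, VL, VTA,
LC) from the published qualification lists.

The ego-network view restricts to a seed region (default M1) and its direct
neighbors, but attaches node and edge betweenness computed on the *full*
graph, so the seed view retains whole-network context.

### The PLS backend

The original analysis derived edges from a partial-least-squares step whose
published description is not detailed enough to reimplement uniquely, so
Pearson-across-animals is the default edge definition and a mean-centered
task PLS is provided as a labeled alternative (`method="pls_lv"`): SVD of
the group-mean deviation matrix, permutation p-values per latent variable
by label shuffling (p = (1 + #{s_perm ≥ s_obs}) / (1 + n_perm)), bootstrap
salience ratios by within-group resampling with per-LV sign alignment
(defaults n_perm = n_boot = 1,000). Its derived network correlates the
regions' rank-(G−1) LV reconstructions across animals.

Two consequences are worth stating plainly. First, group-mean PLS measures
*between-group* covariation: with these marginals, regions whose published
within-group correlation is strongly positive (e.g. M1–DLS) have opposite
group-mean profiles (M1 falls after the lesion, DLS rises), so the PLS
backend cannot be expected to reproduce the sign of Pearson edges, and the
suite instead verifies that saliences align/anti-align with the group-mean
profiles. Second, a "null" cohort with zero within-group correlations but
the real four-group marginals is *not* null for the permutation test —
group means genuinely differ — so LV1 is correctly significant there; null
calibration is tested on exchangeable cohorts with identical marginals in
every group.

## Synthetic cohorts

Per group, activity is multivariate normal: mean = summary mean,
SD = SEM·√n (n from the summary; 6 here), correlation matrix assembled from
user specs (unspecified pairs 0), then truncated at zero. Gaussian
marginals were chosen over count distributions because Pearson correlation
is the analysis target and most regional means sit several SDs above zero;
where they do not (SNpc at 1.3 ± 0.3), truncation is material, the
truncated fraction is recorded per region in `meta`, and a
`TruncationWarning` fires above 1%. Slightly non-PSD user matrices (min
eigenvalue ≥ −1e−4) are repaired by eigenvalue clipping plus rescaling to
unit diagonal; anything worse is rejected as a spec error.

Outcome columns are linear-Gaussian: target = mean + Σ w_i·(activity_i −
mean_i) + N(0, σ²), clipped to the physical range (rotarod 0–480 s). The
noise level for a desired correlation r with a single driver follows
σ_noise = σ_signal·√(1/r² − 1), verified by simulation to ±0.02 at
n = 5,000.

Recovery scenarios plant 7×7 motor-circuit correlation matrices with
exactly 9 (untreated-like), 3 (lesioned-like) or 7 (acupuncture-like)
supra-0.5 pairs; supra pairs sit at r ≥ 0.6 and sub pairs at r ≤ 0.35, so
every pair has ≥ 0.1 margin from the threshold. The strongest entries equal
the published values (DLS–DMS 0.986, SNr–M1 0.783, M1–DMS 0.742; M1–DLS
0.727; Sm–DMS 0.904, SNr–Sm 0.719, SNr–DMS 0.719); the remaining entries
are explicit constructions chosen once for positive-definiteness (minimum
eigenvalues 0.010 / 0.026 / 0.036), not estimates of the real data. The
`whole_brain_null` scenario zeroes all 435 off-diagonal correlations in
every group while keeping the real marginals.

At n = 1,000 the sampling SD of r near 0.65 is ≈ 0.02, so the 0.1 margin
makes exact edge-set recovery essentially certain; the suite requires
≥ 95% over 100 seeds. At the study's own n = 6 the sampling SD of r is
≈ 0.3–0.4 and recovery is verified to be unreliable — a power observation
worth keeping in mind when interpreting any n = 6 correlation network.

## Behavior prediction

GLM is ordinary least squares on standardized features (the continuous
rotarod target makes the Gaussian-identity family the minimal reading of
"generalized linear modeling"); the ensembles are scikit-learn
ExtraTrees/RandomForest/GradientBoosting and XGBoost with fixed seeded
hyperparameters (n_estimators = 200, library defaults otherwise) — no
tuning, by design. Protocol: one seeded 0.75:0.25 split; 5-fold CV within
the training portion (a flag switches CV to the full set, since published
descriptions of this protocol are often ambiguous); held-out R² and RMSE;
models ranked by descending R² with RMSE as tie-break. Importances:
|standardized coefficients| for GLM, impurity importances for the
ensembles; reported both as L1 proportions and max-normalized relative
values — the two conventions are linked by relative = proportion /
max(proportion), which is exactly how published percentage tables
(21.3 / 15.7 / 13.5 …) map onto published relative importances
(1 / 0.740 / 0.635). The published R² = 0.727 / RMSE ≈ 61 s values are not
reproduction targets: they derive from the undeposited ~24-animal dataset,
far too small for stable resampling-based metrics, so the package's claims
are limited to recovery on planted-signal synthetic cohorts (strongest
planted driver recovered as top importance in ≥ 95% of seeded runs at
n = 500) and the normalization arithmetic.

## Pipeline

`run_pipeline` executes load/simulate → per-region ANOVA + Tukey →
per-group networks, hubs, motor subnetwork, M1 ego network → optional ML →
summary, writing a bundle directory with a MANIFEST (sha256 per artifact,
config hash excluding the output path, seed). Reruns of the same config
and seed are checksum-identical. Stage failures raise an error naming the
stage and leave earlier artifacts plus an incomplete-flagged MANIFEST.

## Problem sizes and limitations

Default verification sizes — 10,000 animals/group for marginal and
correlation recovery, 1,000 for edge-set recovery (100 seeds), 500 for
importance ordering (100 seeds), 50 repetitions × 500 permutations for PLS
null calibration — were chosen as the smallest sizes at which Monte-Carlo
error is negligible relative to the tested tolerances; the full suite runs
in about a minute on one core.

The generator reproduces first- and second-order statistics only: no count
discreteness, no heavy tails, no between-region mean structure beyond the
summary table, no mechanistic MPTP neurotoxicology. Passing recovery tests
therefore demonstrates that the *pipeline* is correct and well-calibrated,
not that the original n = 6 networks are statistically stable — the small-n
recovery test quantifies exactly that instability. Known inconsistencies in
the source material (behavior ANOVAs printed with df implying n = 5/group
against legends stating n = 6; a figure legend's r² values disagreeing with
the r values printed in the accompanying text) are flagged here and
deliberately not reconciled; neither quantity is treated as a target.
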