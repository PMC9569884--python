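# Methods

This note documents the statistical model, the algorithmic choices, and
the limits of what the synthetic cohorts can demonstrate.

## Study design being modeled

A matched case-control discovery cohort: each NEC infant is paired with a
non-NEC control, and stool samples from both are pooled into three
pre-diagnosis periods (A: −10..−7 days, B: −6..−3, C: −2..0). The default
design is 7 pairs × 2 conditions × 3 periods = 42 runs. Periods are
treated as repeated observations of the same subject, not as a factor:
the screen and the panel selection pool all 42 runs into a single binary
comparison (21 NEC vs 21 control), and period structure only re-enters in
the error breakdowns and the per-period Dunnett comparisons.

## Synthetic cohort generator

Per protein *i* and run *s*:

    log2 x_is = mu_i + u_subject(s) + beta_i * 1[NEC] + eps_is

* `mu_i ~ N(baseline_log2_mean, sigma_protein)` = N(14, 2) for null
  proteins — a plausible spread of DIA-NN normalized intensities on a
  log2 scale of arbitrary units.
* Planted markers (40 up, 40 down by default) draw their baseline from
  N(17.5, 0.8): candidate markers in a screen of this kind are by
  construction proteins quantified in essentially all runs, so they are
  planted in the reliably quantified upper abundance range where a
  4-fold down-regulation does not push them below the dropout zone.
* `u ~ N(0, sigma_subject=0.3)` per subject (14 subjects). Matched pairs
  share period structure but not `u`, so pairs partially co-cluster
  without being forced to.
* `beta_i = ±log2(effect_fold)`, default effect_fold 3 (screens in this
  package's validation use 4); observed discovery fold-change ratios
  span roughly 0.2–5, so the default sits inside that range rather than
  being fitted.
* `eps ~ N(0, sigma_noise=0.4)`.
* Dropout is missing-not-at-random: each observation is missing with
  probability `expit(steepness * (midpoint − log2 x))`, steepness 1.0,
  midpoint 12.2. The midpoint was set analytically so that ~45% of 1100
  proteins survive the <10% missingness filter (≈ 490 of 1085, the
  regime this design targets); it was fixed once and is not a tuning
  dial.
* Precursors per protein are ~Geometric(1/15) clipped to [1, 100]
  (mean ≈ 15). A precursor inherits its parent's per-run signal plus a
  per-precursor offset N(−2, 1.5) log2 units and N(0, 0.2) independent
  noise, with independent dropout under the same logistic — so
  low-abundance proteins also have weak precursor support.
* ~15% of protein groups carry a second, shared gene label, emulating
  multi-gene DIA-NN protein groups; this gives the redundancy cap
  something to act on.

What the generator does **not** emulate: batch/center effects, missing
runs (incomplete designs), correlated marker panels beyond the shared
subject effect, non-normal heavy-tailed abundance noise, and any
dependence of the effect size on the period (an optional `period_drift`
exists for stress tests but defaults to 0). Passing tests on these
cohorts therefore demonstrate the pipeline's correctness and its behavior
under the intended statistical regime — not clinical performance on real
stool proteomes.

## Screening cascade

Order matters and follows the discovery recipe: missingness filter →
zero imputation → AUC gate → imputed-zero bias filter → precursor
support → redundancy cap. Details:

* **Missingness**: strict bound, `missing/n < 0.10`; at n = 42 this is
  ≥ 38 quantified values. Integer arithmetic with a 1e-9 guard avoids
  float-rounding artifacts at exact multiples.
* **Folded AUC**: computed from the rank-sum statistic, ties get half
  credit; direction "up" when raw AUC ≥ 0.5. The direction is carried
  separately so decreased markers report AUC ≥ 0.7 like increased ones.
* **Imputed-zero bias**: a marker whose missing values concentrate in
  one class gets its AUC from imputation rather than quantification;
  ≥ 4 imputed zeros within a single class (the maximum possible under
  the ≥38/42 rule) excludes the marker. "At least 4" rather than
  "exactly 4" is used, which matters only for non-default configs.
* **Precursor support**: at least one precursor with ≥ 35 quantified
  values; proteins absent from the precursor matrix fail the gate.
* **Redundancy**: among markers passing all earlier gates, at most two
  protein groups may share any gene entry; the highest-AUC members are
  kept, ties broken by smaller p then lexicographic id.
* Mann–Whitney p (exact for combined n ≤ 12 without ties, asymptotic
  with tie correction otherwise) and BKY two-stage q-values (α = 0.05)
  are reported but are not gates.
* Statistics are computed on linear-scale zero-imputed values; AUC and
  Mann–Whitney are rank-based and unaffected by monotone transforms,
  and the fold-change ratio is conventionally quoted on the linear
  scale, so no log transform is applied by default.

A known property of this design, documented rather than patched: with 42
samples clustered into 14 subjects, the null distribution of the folded
AUC is wider than the i.i.d. rank statistic suggests (the subject effect
is a random intercept shared by three runs). Monte Carlo under the
generator's default noise gives P(folded AUC ≥ 0.7 | null) ≈ 9% versus
≈ 3% for independent samples. A screen of ~420 null survivors therefore
admits a few dozen chance passes no later gate can identify, and the
candidate set contains a substantial null fraction. This is a property
of small clustered cohorts, not of the implementation; the same caveat
applies to the original design this pipeline reproduces.

## Panel selection

"Impact on communal ROC" is realized as greedy forward selection per
direction arm: seed with the arm's best individual AUC (ties: lower p,
then id), then repeatedly add the candidate maximizing the arm's
communal AUC — the folded AUC of the composite score, defined as the
mean of per-marker z-scores with down markers sign-flipped. z-scores
(not ranks) are used so the communal AUC and the final relative score
share one standardization. Panels must reach their requested size, so a
greedy step that lowers the communal AUC is still taken and logged.
Smaller panels re-run the same procedure restricted to the parent
panel's members, guaranteeing nesting. One seed per arm is used (seeding
with several top markers is a plausible alternative; one-seed is the
simplest procedure consistent with "keeping the protein groups with the
best individual AUC").

## Multivariate evaluation

* **PCA** is on the marker correlation matrix — standardized variables,
  eigenvalues summing to the marker count — so "proportion of variance"
  is eigenvalue/p. Eigenvector signs are fixed by making the
  largest-magnitude loading positive. Trailing zero eigenvalues (p > n)
  are kept as zeros.
* **Parallel analysis** (Horn): 1000 seeded iterations of same-shaped
  standard-normal data, per-rank 95th percentile, leading-run stopping
  rule (retention stops at the first non-exceeding PC). Fewer than 100
  iterations triggers a warning.
* **PC regression**: logistic regression on (PC1, PC2) with a ridge
  penalty of 1e-6 (sklearn C = 1e6) so complete separation — the
  expected outcome for a good panel — stays numerically defined;
  threshold 0.5.
* **Hierarchical clustering**: sample-sample distance 1 − Pearson r
  (not 1 − |r|: anti-correlated profiles should be maximally distant),
  complete linkage, cut at two clusters. Cluster→condition mapping
  minimizes total misassignments (equivalent to majority voting; exact
  ties charge the errors to the smaller class).
* **K-means**: Euclidean, k = 2, best of 10 seeded restarts.
* **LDA**: explicit pooled within-class scatter; pseudo-inverse when
  markers ≥ n − 2 (the usual case at p = 36, n = 42); equal priors
  (classes are balanced by design); Wilks' Λ = 1/(1 + λ₁) from the
  single discriminant eigenvalue; significance by Bartlett's
  approximation −(n − 1 − (p + g)/2)·ln Λ with p(g − 1) df.

## Signature scoring

* **Rankit**: the Hazen plotting position (r − ½)/n is used — it is the
  one whose bound at n = 42 is ±2.2571 ≈ ±2.26; Blom's (r − 3/8)/(n + ¼)
  would give ±2.22 and is therefore not the convention in use.
  Ties receive average ranks.
* **Relative score**: z-standardization is across all 42 samples (one
  scale for the whole heatmap), `S = mean z_up − mean z_down`. Swapping
  the arms negates the score exactly; arm means average to zero over
  samples by construction.
* **Paired t**: the pairing unit is the direction-adjusted marker
  z-value of case vs matched control at the same period, pooled across
  the pair's periods (36 × 3 = 108 differences per pair). Pooling is
  used because each pair receives one test spanning its whole
  observation window; a per-period variant is a trivial restriction.
  All-zero differences report t = 0, p = 1 with a degenerate flag.
* **Dunnett**: groups are {pooled control, NEC-A, NEC-B, NEC-C}; each
  NEC period is compared against the pooled control with the
  multivariate-t Dunnett distribution (seeded), alongside the one-way
  ANOVA F.

## Determinism and problem sizes

A single pipeline seed fans out to fixed per-stage seeds (simulation,
parallel analysis, K-means restarts, Dunnett), so stages are
individually reproducible and a full rerun is byte-identical. Validation
suites run the full 1100-protein, 42-sample design for screening checks
(20 replicate seeds) and reduced designs (200–300 proteins, panels of
8–12) where only orchestration is under test; these sizes keep each
suite in seconds-to-minutes while leaving every statistical regime
(missingness ~45%, balanced 21/21 outcome, p ≫ n panels) intact.

## Known limitations

* The screen's null contamination on small clustered cohorts (above) —
  a validation cohort, not a tighter filter, is the remedy.
* Greedy communal-AUC selection is not best-subset; on synthetic cohorts
  with many AUC-1.0 markers many panels are equivalent and the
  deterministic tie-break, not biology, picks among them.
* No cross-validation is performed anywhere, faithfully to the
  exploratory design; every reported error rate is resubstitution and
  optimistically biased.
* Dunnett p-values from the multivariate-t integration are stochastic at
  the 1e-4 level; they are seeded for reproducibility.
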