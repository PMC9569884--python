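"""Evaluate a marker panel with the multivariate battery.

Correlation-matrix PCA with Horn's parallel analysis, logistic regression
on the first two PC scores, complete-linkage clustering on 1 - Pearson r,
K-means (k=2), and LDA with Wilks' lambda; misassignments are broken down
by pre-diagnosis period (A = earliest, C = closest to diagnosis).
"""

from necsig import (
    CohortConfig, filter_missingness, generate_cohort, impute_zeros,
    screen_markers, select_nested_panels, standardize, pca, parallel_analysis,
    pc_regression, hierarchical_two_clusters, kmeans_two_clusters, lda_evaluate,
)

cohort = generate_cohort(CohortConfig(effect_fold=4.0, seed=1))
stats = screen_markers(cohort.pg, cohort.pr, cohort.samples)
values = impute_zeros(filter_missingness(cohort.pg)).to_frame()
panel = select_nested_panels(stats, values, cohort.samples.is_case, [36])[0]

z = standardize(values.loc[panel.ids])
res = pca(z)
print(f"PC1 explains {100 * res.proportion_of_variance[0]:.1f}% of the variance, "
      f"PC2 {100 * res.proportion_of_variance[1]:.1f}% "
      f"(cumulative {100 * res.cumulative_proportion[1]:.1f}%)")
kept = parallel_analysis(z, n_iterations=1000, seed=0)
print(f"parallel analysis retains the first {kept} PC(s) above the 95th "
      "percentile of same-shaped noise")

for report in (
    pc_regression(res.scores, cohort.samples),
    hierarchical_two_clusters(z, cohort.samples),
    kmeans_two_clusters(z, cohort.samples, seed=0),
    lda_evaluate(z, cohort.samples),
):
    extra = ""
    if report.wilks_lambda is not None:
        extra = f"  Wilks' lambda={report.wilks_lambda:.4f} (chi2 p={report.chi_square_p:.2g})"
    print(f"{report.method:14s} misassigned={report.misassigned_total} "
          f"by period {report.misassigned_by_period}{extra}")
print("-> 0 misassignments everywhere means the panel separates the cohort "
      "perfectly, including the earliest period")
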