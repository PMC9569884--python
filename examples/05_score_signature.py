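"""Score samples with the composite relative-score signature.

Per sample: mean z over up markers minus mean z over down markers.  A
positive score indicates a case-like profile.  Per matched pair, a
two-tailed paired t test on the direction-adjusted marker z-values; per
period, Dunnett's many-to-one comparison of each NEC period against the
pooled controls.
"""

from necsig import (
    CohortConfig, dunnett_by_period, filter_missingness, generate_cohort,
    impute_zeros, paired_t_by_pair, relative_score, screen_markers,
    select_nested_panels, standardize,
)

cohort = generate_cohort(CohortConfig(effect_fold=4.0, seed=1))
stats = screen_markers(cohort.pg, cohort.pr, cohort.samples)
values = impute_zeros(filter_missingness(cohort.pg)).to_frame()
panel = select_nested_panels(stats, values, cohort.samples.is_case, [36])[0]
z = standardize(values.loc[panel.ids])

scores = relative_score(z, panel)
nec = scores.loc[cohort.samples.is_case, "relative_score"]
ctrl = scores.loc[~cohort.samples.is_case, "relative_score"]
print(f"relative score, NEC:     {nec.mean():+.2f} (range {nec.min():+.2f}..{nec.max():+.2f})")
print(f"relative score, control: {ctrl.mean():+.2f} (range {ctrl.min():+.2f}..{ctrl.max():+.2f})")
print(f"every NEC sample above every control: {nec.min() > ctrl.max()}")

pair_tests = paired_t_by_pair(z, panel, cohort.samples)
print(f"\npaired t per pair (n = {pair_tests.n_paired.iloc[0]} marker x period "
      "differences):")
for _, row in pair_tests.iterrows():
    print(f"  pair {int(row.pair_id)}: t={row.t:6.1f}  p={row.p_value:.2g}")

period = dunnett_by_period(scores["relative_score"], cohort.samples, seed=0)
print(f"\nANOVA F={period.f_statistic:.1f}; Dunnett-adjusted p vs pooled controls:")
for per in period.periods:
    print(f"  period {per} (mean {period.group_means[per]:+.2f}): "
          f"p={period.adjusted_p[per]:.3g}")
print("-> significance at the earliest period (A) means the signature flags "
      "cases 7-10 days before diagnosis")
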