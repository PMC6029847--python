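"""Cohort analysis: two-group tests plus the missing-data multivariate
correlation between tissue stiffness and cross-link density.

Generates a synthetic 32-donor cohort (15 control, 17 fibrotic) in which log
stiffness and log mature cross-link density are correlated at rho = 0.72
while collagen concentration is uncoupled, blanks 10% of cells at random,
and runs the full cohort pipeline.
"""

from fibromech import CohortSpec, StudyConfig, run_cohort_analysis

config = StudyConfig(seed=1, cohort_spec=CohortSpec(missing_rate=0.10))
report = run_cohort_analysis(config)

print(f"donors: {report.manifest['groups']}")
print("\ngroup comparisons (variable, method, p):")
for t in report.group_tests:
    print(f"  {t.comparison[0]:<24s} {t.method:<13s} p = {t.p:.4g}")

r, p, n = report.key_pair
print(f"\nstiffness vs mature cross-links (EM-MVN): r = {r:.3f}, p = {p:.2g}, n_eff = {n}")
rc, pc, _ = report.correlation.pair("stiffness_kpa", "collagen_ug_per_mg")
print(f"stiffness vs collagen concentration       : r = {rc:.3f}, p = {pc:.2g}")
print("\nThe coupling the analysis is built to expose: stiffness tracks mature")
print("pyridinoline cross-link density, not total collagen concentration.")
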