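"""Intervention analysis: enzyme IC50 fits and dose-dependent stiffness.

Fits 4PL inhibition curves for two lysyl-oxidase-like enzymes and runs the
repeated-measures dose comparison of spheroid Young's modulus against
vehicle (3 donors, 2 replicates, Dunnett's post-test).
"""

from fibromech import StudyConfig, run_invitro_analysis

report = run_invitro_analysis(StudyConfig(seed=1))

print("4PL inhibition fits:")
for enzyme, fit in sorted(report.ic50_fits.items()):
    print(f"  {enzyme}: IC50 = {fit.ic50 * 1e3:.2f} nM, hill = {fit.hill:.2f}")

print(f"\nRM-ANOVA across doses: F = {report.rm_result.omnibus.statistic:.2f}, "
      f"p = {report.rm_result.omnibus.p:.2g}")
print("Dunnett vs vehicle (adjusted p):")
for comp in report.rm_result.comparisons:
    print(f"  {comp.comparison[0]:>8s}: p_adj = {comp.p_adjusted:.4g}")
print("\nA significant top-dose contrast marks the inhibitor-driven drop in")
print("tissue stiffness that parallels the loss of mature cross-links.")
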