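"""Run the complete analysis battery on a simulated cohort.

Pipeline: simulate 50 agents through the exp1 schedule, apply the 90%
memory-test inclusion rule, compute per-cue response ratios, and run the
sensitivity tests, the within- and between-subject overtraining contrasts
and the correlation analyses.
"""

from operant import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(variant="exp1", n_participants=50, seed=7))

print(f"cohort: n = {report.n_total}, included = {report.n_included}, "
      f"first-test groups = {report.group_sizes}")
print("\nmean response ratios (0.5 = habitual persistence, 1 = suppression):")
for cue, s in report.ratios.items():
    print(f"  {cue:12s}: {s['mean']:.3f} (SD {s['sd']:.3f}, n {s['n']})")

print("\ntests (one-tailed):")
for label, t in report.tests.items():
    print(f"  {label:30s} t({t['df']:.1f}) = {t['statistic']:6.2f}, "
          f"p = {t['p_one_tailed']:.4f}, effect = {t['effect_size']:.2f}, "
          f"BF10 = {t['bf10']:.3g}")

print("\ncorrelations:")
for label, c in report.correlations.items():
    print(f"  {label:42s} r = {c['r']:6.3f}, p = {c['p']:.3g} (n = {c['n']})")
# For a goal-directed cohort the sensitivity tests reject decisively
# (responding drops under degradation) while the overtrained-vs-standard
# contrasts support the null: extended training did not blunt sensitivity.
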