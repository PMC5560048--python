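"""Group comparison with the two-branch test dispatch on a simulated cohort.

Simulates control and immobilised cohorts (truth-level generative model),
then compares reporter volumes between groups: Shapiro-Wilk decides the
branch (Student t / Mann-Whitney for two groups), and each group is
summarised as mean with its 95% confidence interval.
"""

from jointquant import compare_groups, generate_cohort

table, _ = generate_cohort(15, {"control": "control", "immobilised": "immobilised"}, seed=4)
volumes = table[table.measure == "volume_um3"]
groups, labels = [], []
for label, sub in volumes.groupby("group"):
    labels.append(label)
    groups.append(sub["value"].to_numpy())

report = compare_groups(groups, labels=labels)
print(f"test dispatched: {report.test_used}  statistic={report.statistic:.3f}  p={report.p_value:.4g}")
for g in report.groups:
    print(f"  {g.label:12s} n={g.n:2d}  mean {g.mean:7.0f} um^3  95% CI [{g.ci_lower:.0f}, {g.ci_upper:.0f}]")
# The immobilised preset scales reporter volume down 40%; at n=15/group the
# comparison should usually reject the null.
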