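"""Entropy-based pruning of member models and whole groups.

Adds a deliberately corrupted (label-shuffled) group to three informative
ones and fits the group-selecting variant: the selection report shows the
corrupted group's inflated cross-entropy loss and its removal.
"""

from intervalens import DatasetSpec, IntervalEnsembleClassifier, generate
from intervalens.metrics import split_and_scale
from intervalens.robustness import study_groups

spec = DatasetSpec(n_samples=150, n_features=500, n_informative=100, seed=3)
X, y = generate(spec)
X_tr, X_te, y_tr, y_te, _ = split_and_scale(X, y, seed=3)

ens = IntervalEnsembleClassifier(
    variant="pom_egrp", groups=study_groups(seed=3), random_state=3
).fit(X_tr, y_tr)

report = ens.selection_report_
print("group mean cross-entropy losses (nested 10x2-fold CV on train):")
for name, mean in zip(report.group_names, report.group_means):
    flag = "kept" if report.group_names.index(name) in report.kept_groups else "DROPPED"
    print(f"  {name:>8}: {mean:8.3f}   {flag}")
print(f"average of group means: {report.group_mean_average:.3f}")
print("surviving groups:", [g.name for g in ens.fitted_groups_])

# The SHUFFLED group's members were trained on permuted labels, so their
# held-out cross-entropy loss is far above the group average and the whole
# group is pruned; each surviving group keeps its two best members plus
# any member at or below its group's average loss.
for g, kept in zip(report.group_names, report.kept_models):
    print(f"  members kept in {g}: {kept}")
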