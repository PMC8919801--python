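"""Predict severity from tapping features with cross-validated ridge.

The target here is the generative severity scalar the cohort was built
with, so the correlation measures how much of the phenotype the feature
pipeline recovers end to end.
"""

import warnings

import fingertap as ft

warnings.simplefilter("ignore")

dataset = ft.generate_cohort(ft.small_cohort_spec(40, 0, 40, seed=5))
signals, _, _ = ft.preprocess_cohort(dataset)
table, _ = ft.features_table(signals, "paper-total")
meta = ft.add_common_scores(dataset.manifest).set_index("session_id").loc[table.index]

report = ft.regress_severity(
    table, meta["severity_dominant"], meta["subject_id"],
    target="generative severity", k=10, seed=5, n_bootstrap=200,
)

m = report.metrics
print(f"r = {m['r']:.3f}, r2 = {m['r2']:.3f} (n={m['n']})")
print(f"95% CI for r: {m['r_ci'][0]:.2f} to {m['r_ci'][1]:.2f}")
# r is the Pearson correlation between pooled out-of-fold predictions and
# the true severities; r2 is its square.  The common arm scores
# (meta['common_arm_dominant']) can be regressed the same way.
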