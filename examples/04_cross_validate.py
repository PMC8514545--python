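"""Subject-grouped cross-validation with a label-randomization null.

Evaluates the ensemble on a small synthetic cohort with tenfold
subject-grouped CV (all of a subject's samples stay in one fold), then
re-runs the CV under subject-level label shuffles.  The real AUROC should
be near 1 on this calibration; the null should hover near 0.5.
"""

import idarcyto as ic

design = ic.CohortDesign(
    n_subjects={"HEALTHY": 12, "H24": 12, "BSI": 12}, seed=2
)
table = ic.simulate_feature_table(design)
y = table["label"].to_numpy()
subjects = table["subject_id"].to_numpy()

cfg = ic.TrainConfig(n_bootstrap=8, n_estimators=80, seed=0)
res = ic.cross_validate(table, y, subjects, None, cfg,
                        ic.CVScheme(k=6, grouping="SUBJECT", seed=0))
print(f"subject-grouped CV AUROC: {res.auroc:.3f} "
      f"(95% CI {res.ci[0]:.3f}-{res.ci[1]:.3f})")

null = ic.randomization_null(table, y, subjects, cfg,
                             ic.CVScheme(k=6, seed=0), n_shuffles=5, seed=1)
print(f"label-shuffle null AUROCs: {[round(a, 2) for a in null]}")
print(f"null mean: {null.mean():.3f}")

op = ic.operating_point(res.scores, y, cutoff=54.5)
print(f"\nat cutoff > 54.5: sensitivity {op.sensitivity:.0f}%, "
      f"specificity {op.specificity:.0f}%, PPV {op.ppv:.0f}%, NPV {op.npv:.0f}%")
print("\nA real signal scores near 1.0 while shuffled labels fall to ~0.5,")
print("showing the CV estimate is not driven by leakage or overfitting.")
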