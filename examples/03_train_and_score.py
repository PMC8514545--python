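"""Train the bootstrap ensemble on a small cohort and score it.

Simulates a compact cohort (healthy + postoperative + bloodstream
infection), extracts the 101 features, fits a reduced bootstrap ensemble
and prints the mean 0-100 score per condition.  Infectious samples should
score high, noninfectious ones (including sterile surgical inflammation)
low — that separation, not inflammation per se, is what the score encodes.
"""

import idarcyto as ic

design = ic.CohortDesign(
    n_subjects={"HEALTHY": 6, "H24": 6, "BSI": 6}, seed=7
)
table = ic.simulate_feature_table(design)

model = ic.fit_idar(
    table, table["label"].to_numpy(),
    ic.TrainConfig(n_bootstrap=8, n_estimators=100, seed=0),
    subjects=table["subject_id"].to_numpy(),
)
scores = model.score_table(table)

out = table[["subject_id", "condition", "label"]].assign(idar=scores["idar"].round(1))
print(out.to_string(index=False))
print("\nmean score by condition:")
print(out.groupby("condition")["idar"].mean().round(1).to_string())
print("\nBSI samples sit near 100, healthy and 24h-postsurgery samples near 0:")
print("the ensemble separates infection from sterile inflammation.")
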