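"""Cross-validated comparison of Model A (Cox) and Model B (forest).

Grouped five-fold cross-validation (all landmark rows of a patient share a
fold) of the relapse-specific Harrell concordance, with 100-replicate
patient-level bootstrap confidence intervals on the pooled out-of-fold
predictions.
"""

import crlandmark as cl
from crlandmark.forest import ForestConfig

cohort = cl.generate_cohort(cl.default_cohort_config(seed=4), 1200)
report = cl.compare_models(
    cohort,
    landmark_grid=[1.0, 3.0, 5.0],
    cox_terms=["age", "bmi", "pM", "pN", "pT", "anastomotic_dehiscence",
               "combined_resection", "perioperative_treatment", "transfusion"],
    cox_interactions=["pM"],
    forest_config=ForestConfig(ntree=100, mtry=5, nodesize=30, seed=4),
    k=5,
    B=100,
    seed=4,
    causes=(1,),
)
print(report[["model", "cause", "c_pooled", "ci_low", "ci_high", "c_fold_mean"]]
      .round(3).to_string(index=False))
# c_pooled is Harrell's cause-specific C on pooled out-of-fold predictions
# (0.5 = chance, 1 = perfect ranking). On this generator the hazards are
# log-linear, so the correctly specified Cox model and the forest land
# within a few hundredths of each other; the forest pulls clearly ahead
# only when the risk structure contains interactions the additive model
# cannot express (see tests/test_acceptance.py::TestModelComparison).
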