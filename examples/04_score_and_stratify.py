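"""Complexity scoring, five-group stratification and outcome prediction.

Generates a synthetic cohort whose 1-year outcomes follow the logistic
complexity score, recalibrates the coefficients by maximum likelihood,
stratifies patients into the five (AF type x score band) groups and
compares k-NN outcome prediction against the conventional paroxysmal/
persistent baseline.
"""

import afstrat as afs

cohort = afs.generate_cohort(afs.CohortSpec(n=2000, seed=42))
cohort["score"] = afs.complexity_score(cohort)

fit = afs.calibrate_coefficients(cohort)
print("recalibrated coefficients (truth -0.11, +0.40, -0.39, -0.04):")
print(f"  intercept {fit.intercept:+.3f}, HDF {fit.beta_hdf:+.3f}, "
      f"MedianDF {fit.beta_median_df:+.3f}, MRT {fit.beta_mean_rotor_time:+.3f}")

cohort["group"] = afs.assign_groups(cohort)
print("\npatients per stratification group:")
for g, n in cohort["group"].value_counts().sort_index().items():
    rate = cohort.loc[cohort["group"] == g, "outcome_1y"].mean()
    print(f"  {g} ({afs.GROUP_LABELS[g]:>6}): n = {n:4d}, "
          f"AF freedom at 1 y = {rate:.0%}")

split = afs.stratified_split(cohort, seed=0)
train, test = cohort.iloc[split.train_ids], cohort.iloc[split.test_ids]
model = afs.fit_knn(train, k=5)
pred, vote = afs.predict_outcome(model, test)
y = test["outcome_1y"].to_numpy()
print(f"\nheld-out k-NN accuracy (k = 5): {(pred == y).mean():.0%}")

# ROC comparison: complexity score vs the conventional temporal (3-P)
# classification used as a predictor, paired on the same test patients
three_p = (test["af_type"] == "persistent").astype(float).to_numpy()
a_score, a_3p, p = afs.delong_compare(test["score"].to_numpy(), three_p, y)
print(f"AUC: complexity score {a_score:.2f} vs 3-P classification {a_3p:.2f} "
      f"(paired DeLong p = {p:.3g})")
# The score discriminates 1-year outcome in this cohort; the temporal label
# alone carries no outcome information here (AUC ~ 0.5) because the
# generator draws AF type independently of the biomarkers.
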