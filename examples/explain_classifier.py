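"""Explain the classifier with within-CV Shapley attributions.

Path-dependent TreeSHAP attributions are computed on each fold's
held-out rows only and pooled; per class, features are ranked by mean
absolute attribution, and a sign-concordance score summarises the
direction of each feature's influence.
"""

from cmcpatterns import (
    CVConfig,
    compute_shap_cv,
    directionality_summary,
    generate_cohort,
    global_importance,
    run_nested_cv,
    stratum_config,
)

covariates, _, truth = generate_cohort(stratum_config("elsa", "male", n=900, seed=13))
predictors = covariates.drop(columns=["participant_id", "sex", "follow_up_years"])

_, folds = run_nested_cv(predictors, truth, CVConfig.quick(seed=2))
shap_result = compute_shap_cv(folds)

err = abs(shap_result.predicted_probability()
          - shap_result.base_values
          - shap_result.values.sum(axis=1)).max()

for cls in ("FirstDM", "Healthy"):
    top = global_importance(shap_result, cls, top_m=5)
    print(f"\ntop features for class {cls} (mean |SHAP| in probability units):")
    print(top.round(4).to_string(index=False))
    feature = top.iloc[0]["feature"]
    _, score = directionality_summary(shap_result, feature, cls)
    print(f"sign concordance of {feature}: {score:.2f} "
          "(>0.5 means higher values push toward the class)")
# every attribution satisfies base + sum(phi) == predicted probability,
# so importances are directly interpretable as probability shifts
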