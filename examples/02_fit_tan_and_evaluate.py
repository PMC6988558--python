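"""Fit a TAN habitat model and inspect its calibration and sensitivity.

Builds the patch-size variant of the binary RERA-presence model: capture
records only, covariates discretized into at most five well-supported
states, TAN structure induced by class-conditional mutual information,
CPTs learned by frequency counting with one pseudo-count.
"""

from marshbn import (ResponseSpec, SimConfig, complexity, discretize_cases,
                     evaluate, fit_schemes, kfold_cv, learn_cpts,
                     learn_tan_structure, sensitivity_report, simulate,
                     to_model_cases)

survey = simulate(SimConfig(seed=1))
resp = ResponseSpec.rera_presence()
captures = to_model_cases(survey, resp)
print(f"{len(captures)} capture cases of {len(survey)} trap nights")

covs = ["Patch_Size", "Patch_Size_Expanded"]
schemes = fit_schemes(captures, covariates=covs)
dcases = discretize_cases(captures, schemes, resp)
model = learn_cpts(learn_tan_structure(dcases, covs), dcases, alpha=1.0)

print("links:", model.links)
print("complexity (nodes, links, probabilities):", tuple(complexity(model)))

ev = evaluate(model, dcases)
print(f"overall error {100 * ev.overall_error:.1f}%, "
      f"Type I (false presence) {100 * ev.type1_error:.1f}%, "
      f"Type II (false nonpresence) {100 * ev.type2_error:.1f}%, "
      f"spherical payoff {ev.spherical_payoff:.3f}")

cv = kfold_cv(dcases, covs, k=4, seed=42)
print(f"4-fold CV: overall {100 * cv.overall_error:.1f}%, "
      f"payoff {cv.spherical_payoff:.3f}  (close to calibration = not overfit)")

print("entropy reduction (bits), most influential covariate first:")
for cov, bits in sensitivity_report(model).rows:
    print(f"  {cov}: {bits:.4f}")
# Patch_Size ranks first: it is the strongest planted driver of RERA
# presence in the default synthetic conditions.
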