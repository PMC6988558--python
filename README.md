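# marshbn

Tree-augmented naive Bayes (TAN) habitat-association modelling for
salt-marsh small-mammal trap surveys, built around the analysis problem of
the endangered salt marsh harvest mouse (*Reithrodontomys raviventris*,
code RERA) in the tidal marshes of North San Francisco Bay.

## The problem and the method

Multi-site live-trapping surveys record, per *trap night* (one trap set for
one night), a species outcome — a capture code or `TRAP` for an empty trap
— together with microsite and landscape covariates at the trap location:
elevation and tidal datums (MHW/MHHW), vegetation cover and height of the
dominant plants (chiefly pickleweed, *Salicornia pacifica*), distances to
levees, water, the bay, urban areas, agriculture and paved roads, and marsh
patch sizes. Captures are sparse (~73% of trap nights empty) and effort is
uneven across sites and years, which makes classical occupancy models a
poor fit; a discrete Bayesian-network classifier handles the missingness
and collinearity gracefully.

The pipeline is:

1. **Screen** the continuous covariates with all pairwise Pearson
   correlations; greedily eliminate covariates in significantly strong
   pairs (|r| > 0.75, p < 0.05) until no redundancy remains.
2. **Discretize** each covariate into at most 5 ordered states with at
   least ~20 training cases per state (equal-frequency seeding).
3. **Induce a TAN** over the capture records: the response C (RERA presence,
   or the nine-species outcome) is a parent of every covariate, and the
   covariates are joined by the maximum spanning tree under
   class-conditional mutual information
   I(Xi; Xj | C) = Σ P(xi, xj, c) · log₂[P(xi, xj | c) / (P(xi | c) P(xj | c))],
   so each covariate has ≤ 2 parents and a k-covariate model has exactly
   2k − 1 links. CPTs are learned by frequency counting with a
   configurable pseudo-count.
4. **Evaluate**: confusion tables with the predicted-class error
   convention — Type I (false presence) = false positives / all predicted
   presences, Type II (false nonpresence) = false negatives / all predicted
   nonpresences — plus multiclass overall error, spherical payoff
   (mean p(true state)/‖p‖₂), stratified 4-fold cross-validation, and
   entropy-reduction sensitivity I(C; Xi) under the model's joint.
5. **Rank a 38-model suite** (19 covariate-set combinations × 2 responses)
   on a Pareto frontier of accuracy versus complexity (nodes, links,
   probability values).

A synthetic survey generator reproduces the study conditions (12,405 trap
nights, 73% empty, RERA at 20% of captures, strongly correlated covariate
pairs via a latent-Gaussian copula, planted logistic drivers of RERA
presence), so the entire pipeline is testable without field data.

## Worked example

```python
from marshbn import (ResponseSpec, SimConfig, discretize_cases, evaluate,
                     fit_schemes, learn_cpts, learn_tan_structure,
                     sensitivity_report, simulate, to_model_cases)

survey = simulate(SimConfig(seed=1))                     # 12,405 trap nights
resp = ResponseSpec.rera_presence()
captures = to_model_cases(survey, resp)                  # 3,359 capture cases
covs = ["Patch_Size", "Patch_Size_Expanded"]
schemes = fit_schemes(captures, covariates=covs)
dcases = discretize_cases(captures, schemes, resp)
model = learn_cpts(learn_tan_structure(dcases, covs), dcases)
ev = evaluate(model, dcases)
```

Running `python examples/02_fit_tan_and_evaluate.py` (the same analysis)
prints:

```
overall error 20.0%, Type I (false presence) 0.0%, Type II (false nonpresence) 20.0%, spherical payoff 0.839
4-fold CV: overall 20.5%, payoff 0.837  (close to calibration = not overfit)
entropy reduction (bits), most influential covariate first:
  Patch_Size: 0.0580
  Patch_Size_Expanded: 0.0138
```

Read: the patch-size model never falsely predicts presence (Type I 0%) but
misses the 20% of capture cases that are RERA when it always leans to
nonpresence (Type II and overall 20% — the majority-class floor for a 20%
prevalence); cross-validation matching calibration says the model is not
overfit; and the planted driver `Patch_Size` carries most of the
information about the response. The other examples cover screening
(`01`), the 38-model suite with its Pareto frontier (`03`), and the
RERA-vs-vole habitat comparison with Welch t tests under Bonferroni
adjustment (`04`). A thin CLI mirrors the library
(`marshbn simulate|screen|discretize|fit|evaluate|suite|sensitivity|compare|run`).

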