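"""Compare habitat attributes of the two most-captured species.

Welch two-sample t tests (with variance-ratio F tests) on each covariate
over the trap nights where each species was captured, Bonferroni-adjusted
across the 16 comparison covariates.  'higher_mean' names the species with
the significantly larger mean, or 'nd' for no significant difference.
"""

from marshbn import (COMPARISON_COVARIATES, SimConfig, compare_species,
                     comparison_table, simulate)

survey = simulate(SimConfig(seed=1))
rows = compare_species(survey, "RERA", "MICA", list(COMPARISON_COVARIATES))
table = comparison_table(rows)
print(table[["variable", "t", "df", "p_adj", "higher_mean"]].round(3).to_string())
# In the default synthetic conditions only the planted RERA drivers
# (patch size, distance to road) separate the species; the remaining
# covariates are 'nd' because both species share the same microsite
# distributions by construction.
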