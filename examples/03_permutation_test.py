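"""Genotype-permutation empirical p-value for the block-4 sensitivity deficit.

The outcome distribution is non-normal, so instead of trusting the
parametric F-test we hold every phenotype fixed, reshuffle the observed
genotype labels B times, and ask how often a reshuffled cohort produces
an F at least as large as the observed one.  Both analysis variants of
the design are shown: asymptomatic participants only (BPRS < 27), and
the full sample with BPRS as covariate.
"""

from cogassoc import (CohortConfig, ModelSpec, PermutationPlan, carrier_class,
                      block_scores_from_matrix, generate_cohort,
                      generate_cpt_matrix, permute_pvalue)

config = CohortConfig(seed=7)
cohort = generate_cohort(config)
scores = block_scores_from_matrix(generate_cpt_matrix(cohort, config))
table = cohort.merge(scores, on="id")
table["carrier"] = carrier_class(table["genotype"]).map(
    {0: "noncarrier", 1: "carrier"})

spec = ModelSpec(outcome="sensitivity_b4", between=("carrier", "status"),
                 covariates=(), interactions=False)
for variant in ("asymptomatic_only", "bprs_covariate"):
    plan = PermutationPlan(n_permutations=100_000, seed=11,
                           variant=variant, term="carrier")
    res = permute_pvalue(table, spec, plan)
    print(f"{variant:18s}  F_obs = {res.observed_F:6.2f}   "
          f"empirical p = {res.empirical_p:.5f}   "
          f"({res.count_ge} of {res.n_permutations:,} permuted F >= observed, "
          f"n = {res.n_used})")

print("\nAn empirical p near 1/B means essentially no random genotype "
      "assignment reproduces the observed carrier deficit.")
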