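"""The whole decision flow on one synthetic cohort.

Generate -> score -> screen for normality (with a log-transform rescue)
-> parametric ANCOVA for normal outcomes, genotype-permutation empirical
p-values for the rest -> effect sizes and the power table they imply.
"""

from cogassoc import CohortConfig, RunConfig, run_pipeline

config = RunConfig(cohort=CohortConfig(seed=7), seed=7,
                   n_permutations=10_000)
report = run_pipeline(config)

print("filter log:", report.filter_log, "\n")

print(f"{'outcome':<28} {'path':<12} {'p (asympt.)':>12} {'p (covar.)':>12}")
for rec in report.results:
    if rec.get("path") != "permutation":
        continue
    ps = {t["variant"]: t["empirical_p"] for t in rec["tests"]
          if t["kind"] == "permutation"}
    print(f"{rec['outcome']:<28} {rec['path']:<12} "
          f"{ps['asymptomatic_only']:>12.4f} {ps['bprs_covariate']:>12.4f}")

print("\nEffect sizes (positive d = carrier deficit on the scored column):")
es = report.effect_sizes
print(es[["outcome", "column", "d"]].round(3).to_string(index=False))

print("\nPower table (from the observed d via the point-biserial r2):")
print(report.power_table.round(3).to_string(index=False))
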