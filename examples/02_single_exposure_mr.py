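"""Estimate one exposure's causal effect with all five MR estimators.

Simulates a causal trait (theta = 0.5), harmonizes exposure and outcome to a
common effect allele, and prints each estimator's odds ratio per unit
increase in (log-transformed) taxon abundance.  With valid instruments all
methods should agree and their intervals should cover exp(0.5) ~ 1.65.
"""

from mrscreen import (SimulationConfig, egger, harmonize_pair, ivw,
                      max_likelihood, simulate_summary_pair, weighted_median)

config = SimulationConfig(n_snps=30, theta=0.5, prop_palindromic=0.1, seed=7)
exposure, outcome, truth = simulate_summary_pair(config)

hset = harmonize_pair(exposure, outcome, exposure_name="genus.Example",
                      outcome_name="arterial embolism and thrombosis")
print(f"{hset.n_snp} of {len(exposure)} instruments survive harmonization "
      f"(palindromic variants dropped)\n")

slope, intercept = egger(hset)
estimates = [ivw(hset, model="auto"), slope,
             weighted_median(hset, n_boot=1000, seed=42), max_likelihood(hset)]

print(f"{'method':18s} {'OR':>6s} {'95% CI':>14s} {'p':>9s}")
for est in estimates:
    print(f"{est.method:18s} {est.or_value:6.2f} "
          f"{est.ci_low:6.2f}-{est.ci_high:<6.2f} {est.pvalue:9.2e}")

print(f"\ntrue OR = exp({truth.theta}) = {2.718281828 ** truth.theta:.2f}")
print(f"Egger intercept p = {intercept.pvalue:.3f} "
      "(> 0.05: no evidence of directional pleiotropy)")
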