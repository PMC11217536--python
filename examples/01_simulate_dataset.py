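"""Generate synthetic GWAS summary statistics with known ground truth.

Emulates a gut-microbiome abundance GWAS (n=18,340) as the exposure and a
rare binary disease GWAS (1,076 cases / 381,977 controls) as the outcome,
with a true causal effect theta = 0.5 and 10% palindromic variants.
"""

from mrscreen import SimulationConfig, simulate_summary_pair, simulate_taxa_catalog

config = SimulationConfig(n_snps=30, theta=0.5, prop_palindromic=0.1, seed=7)
exposure, outcome, truth = simulate_summary_pair(config)

print("first three exposure records (variant, alleles, beta, se, p):")
for r in exposure[:3]:
    print(f"  {r.variant_id:4s} {r.effect_allele}/{r.other_allele} "
          f"beta={r.beta:+.4f} se={r.se:.4f} p={r.pvalue:.2e}")

print(f"\ntrue causal effect theta = {truth.theta}")
print(f"planted palindromic SNPs: {sorted(truth.palindromic_indices)}")
print("(these A/T and C/G variants are strand-ambiguous and will be dropped "
      "at harmonization)")

catalog = simulate_taxa_catalog(n_total=211, n_unnamed=15, seed=7)
unnamed = [t for t in catalog if not t.is_named]
print(f"\ntaxon catalog: {len(catalog)} traits, {len(unnamed)} without a "
      f"specific name, e.g. {unnamed[0].trait_name!r}")
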