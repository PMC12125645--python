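"""Generate a synthetic cohort of US children and inspect its structure.

Draws 20,000 children with the national fluoride-exposure pattern (12.4%
below detection, 45.7% suboptimal, 40.4% optimal, 1.5% excessive) and
prints the realized marginals. Survey weights scale the sample to 80
million children, so weighted tabulations read as national counts.
"""

import fluorosim as fs

config = fs.PopulationConfig(n=20_000, seed=42)
pop = fs.generate_population(config)

print(pop.head(5).to_string(index=False))
print()
print("fluoride stratum shares (target 12.4/45.7/40.4/1.5%):")
print((100 * pop["fluoride_stratum"].value_counts(normalize=True)).round(1).to_string())
print()
print(f"total survey weight: {pop['weight'].sum():,.0f} "
      f"(national child population: {config.national_population:,.0f})")
print("Each row is one child; the weighted stratum shares determine who "
      "gains or loses protection when fluoride policy changes.")
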