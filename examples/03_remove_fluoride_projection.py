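"""Project the consequences of removing fluoride from public water systems.

Compares remove-fluoride against the status quo over 5- and 10-year
horizons with common random numbers, reporting national-scale changes in
caries prevalence, decayed teeth, fluorosis, QALYs and discounted cost
(2024 USD, 3%/yr discounting), plus the breakdown by insurance type.
"""

import fluorosim as fs

pop = fs.generate_population(fs.PopulationConfig(n=10_000, seed=1))
targets = [fs.CalibrationTarget(g, p)
           for g, p in [("2-5", 0.213), ("6-12", 0.516), ("13-19", 0.572)]]
params = fs.calibrate(pop, fs.default_parameters(), targets)
pop = fs.assign_baseline_caries(pop, params, seed=2)

for horizon in (5, 10):
    inc = fs.run_incremental(
        pop, params,
        fs.ScenarioSpec("remove_fluoride", "all_residents", horizon),
        fs.ScenarioSpec("status_quo", "all_residents", horizon),
        seed=3,
    )
    print(f"--- removing fluoride vs status quo, {horizon}-year horizon ---")
    print(f"  caries prevalence : {inc.d_prevalence_pp:+.2f} pp")
    print(f"  decayed teeth     : {inc.d_decayed_teeth/1e6:+.2f} million")
    print(f"  fluorosis cases   : {inc.d_fluorosis/1e6:+.3f} million")
    print(f"  QALYs             : {inc.d_qalys/1e6:+.3f} million")
    print(f"  cost              : {inc.d_cost_usd/1e9:+.3f} $B")
    print("  by insurance (Δ decayed teeth, millions):",
          {k: round(v['d_decayed_teeth']/1e6, 2) for k, v in inc.by_insurance.items()})
    print()
print("Positive prevalence/teeth/cost and negative QALYs mean removal "
      "worsens oral health and raises spending; fluorosis falls because "
      "excessive exposure disappears. Publicly insured children, who are "
      "likelier to live in fluoridated areas and carry higher baseline "
      "risk, absorb the largest share.")
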