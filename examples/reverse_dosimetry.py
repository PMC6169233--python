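"""Back-calculate PAH intake from synthetic urinary biomarkers and rank strata."""

from pahrisk import (
    SynthesisSpec,
    default_constants,
    default_kinetics,
    estimate_population,
    generate_biomarkers,
    rank_strata,
)

kinetics, constants = default_kinetics(), default_constants()
spec = SynthesisSpec(seed=7, noise_cv=0.2)
records, truth = generate_biomarkers(spec, kinetics, constants, n_replicates=50)
intakes = estimate_population(records, kinetics, constants)

overall = intakes[
    (intakes.gender == "all") & (intakes.race_ethnicity == "all")
    & (intakes.smoking_status == "all")
]
print("estimated overall intake (ug/kg-day):")
for _, row in overall.iterrows():
    print(f"  {row['parent']:<13s} {row['intake_ug_kg_day']:.4f}")

for axis in ("smoking_status", "race_ethnicity", "gender"):
    ranked = rank_strata(intakes, axis)
    print(f"ranking by {axis}: " + " > ".join(name for name, _ in ranked))

# The biomarker table was simulated forward from known intakes (naphthalene
# dominating; smokers at 3x nonsmokers, non-Hispanic black strata elevated),
# then inverted; the rankings recover that built-in exposure structure even
# with 20% lognormal measurement noise.
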