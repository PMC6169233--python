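# Methods

## Scope and model

`pahrisk` implements a screening-level probabilistic cancer-risk assessment
for complex PAH mixtures in contaminated sediment, plus two population-scale
companions: reverse-dosimetry intake estimation from urinary biomarkers and
life-cycle-style impact characterization from intake-fraction/effect-factor
tables. It deliberately models **direct** oral and dermal sediment contact
only; indirect dietary pathways (e.g. ingestion of contaminated seafood),
inhalation, worker scenarios and non-cancer endpoints are out of scope, as is
any re-implementation of structure-activity carcinogenicity prediction or
multimedia fate modeling — concern levels and characterization factors enter
as data.

## Mixture annotation

A mixture profile is an ordered, name-unique list of compounds with
concentration (ng/mL), concentration SD, an EPA priority-list flag, and a
carcinogenic-concern level on the closed ordered scale

    none < marginal < low < low-moderate < moderate < moderate-high < high.

Blank concern cells map to `none` (marginal/negligible rankings are reported
separately and never promoted); blank priority cells map to `false`. The
default screening threshold is `low-moderate`: the packaged 35-compound
sediment fixture then yields 16 priority PAHs and 11 compounds of concern.
Zero-concentration rows are retained — presence in the mixture record, not
abundance, drives annotation. `count_concern` is monotone non-increasing in
the threshold by construction.

## Deterministic risk equations

Standard chronic-exposure algebra (see README for the formulas). Notable
choices:

* **Shared-concentration convention (default).** The packaged configuration
  carries a single sediment concentration CS = 0.283 mg/kg for the seven-PAH
  contaminant-of-concern mixture alongside seven per-compound slope factors.
  The default mode applies that single CS in the exposure term and sums the
  per-compound hazards over it, `risk = exposure · ADAF · ΣCSF`. A
  per-compound mode (`concentrations=` mapping) evaluates exposure
  compound-wise for general use; the two coincide when all concentrations
  equal CS.
* **FI and EV.** Fraction ingested and dermal events/day are not part of the
  packaged uncertain-factor set; both default to the conservative value 1 and
  are configurable.
* **AT fixed.** The cancer averaging time is pinned at 25 550 days and never
  randomized.
* **Validation.** Strict-positive by default; `strict=False` permits zero
  factors so the analytic edge cases (risk linear through zero) are testable.
  Negative factors are always rejected.

Slope factors: oral 0.73/7.3/0.73/0.073/0.0073/7.3/0.73 and dermal
2.5/25/2.5/0.25/0.025/25/2.5 (mg/kg-day)⁻¹ for benz[a]anthracene,
benzo[a]pyrene, benzo[b]fluoranthene, benzo[k]fluoranthene, chrysene,
dibenz[a,h]anthracene and indeno[1,2,3-c,d]pyrene respectively.

## Monte Carlo propagation

Each uncertain factor has a symmetric half-width equal to 25% of its mean.
Given only a minimum and maximum, the uniform distribution on
[mean − hw, mean + hw] is the natural (maximum-entropy) choice and is the
default; a truncated normal (sd = hw/2, truncated at the range) is available
behind `kind="truncnorm"` but off by default. Factors are sampled
independently — no correlation structure is asserted. The randomized sets are
IR_S, EF, ED, BW (oral) and EF, ED, AF, SA, BW (dermal); CS, CF, AT, ADAF,
FI, EV and ABSd stay fixed.

Each of the 10,000 default iterations evaluates the full deterministic
equation on one sampled scenario, so the all-fixed configuration collapses
*exactly* (bit-for-bit) to the point estimate. Sampling uses
`numpy.random.default_rng(seed)`; identical configurations give identical
risk vectors, and every simulation output record carries its seed.

Summaries report mean, sample SD, min/max, median, 2.5/97.5 percentiles
(linear interpolation), adjusted Fisher–Pearson sample skewness
(defined as 0 for constant input), and a normal-approximation 95% CI of the
mean (mean ± 1.96·sd/√n). Values are sorted before summarizing so the
statistics are exactly permutation-invariant. The adult-trespasser oral run
at n = 10,000 yields a CI width ≈4.5 × 10⁻¹⁰, comfortably below the
0.03 × 10⁻⁷ reliability bound asserted in the acceptance suite. The measured
skewness of the simulated distributions is positive (right tail), as expected
for a product of symmetric factors with a reciprocal body-weight term; the
package reports the signed value without adjustment.

## Reverse dosimetry

A back-of-the-envelope steady-state mass balance converts a urinary
metabolite concentration (unadjusted geometric mean, µg/L) into parent-
compound intake (µg/kg-day); no creatinine adjustment and no PBPK modeling.
The packaged configuration tracks naphthalene, fluorene, phenanthrene and
pyrene with one metabolite each (2-naphthol, 2-hydroxyfluorene,
1-hydroxyphenanthrene, 1-hydroxypyrene); molecular weights are formula
weights and the excretion fractions (0.10/0.25/0.05/0.20) and population
constants (1.6 L/day urine, 80 kg body weight) are **illustrative
configuration inputs**, not measurements — absolute intake levels inherit
their uncertainty wholesale, which is why the package emphasizes stratum
*rankings* (invariant to any global rescaling) over absolute values.
Replicate records in a (parent, stratum) cell are pooled by geometric mean,
consistent with the geometric-mean convention of the emulated survey
summaries; a cell containing a zero concentration falls back to the
arithmetic mean. Rank ties break alphabetically.

## Impact characterization

Characterization records are (compound, compartment, route) rows with an
intake fraction (kg intake / kg emitted) and cancer-case and DALY effect
factors (per kg emitted). Pooling a mixture is a per-cell sum — intake and
effects are additive over co-emitted components. Route apportionment
normalizes route intake within a compartment (shares sum to 1 to 1e-12);
zero-intake compartments raise an explicit error rather than emit 0/0
shares. Compartment and route vocabularies are open; the packaged defaults
are household indoor air, fresh water, sea water, natural and agricultural
soil × inhalation, drinking water, produce, meat/dairy, fish.

## Synthetic data

The generators produce every input with known ground truth:

* **Mixtures** — log-uniform concentrations over two decades below the
  requested scale, priority flags at 45% frequency, concern levels from a
  fixed frequency table; the `"paper"` preset returns the packaged sediment
  fixture verbatim.
* **Biomarkers** — the reverse-dosimetry equation run *forward* from true
  intakes (defaults: naphthalene 0.50, phenanthrene 0.08, fluorene 0.05,
  pyrene 0.03 µg/kg-day, naphthalene dominant), per marginal stratum after
  multiplicative effects (smokers 3×, secondhand 1.5×, non-Hispanic black
  1.5×, no gender effect). Measurement noise is multiplicative lognormal
  with **median 1** (σ² = ln(1 + cv²)), so stratum geometric means remain
  centred on the noise-free values and geometric-mean recovery is unbiased;
  at cv = 0 the round trip is an identity to machine precision, and at
  cv = 0.2 with 500 replicates recovery is within 5%.
* **Characterization tables** — per-compartment totals decreasing by a
  factor 0.4 along the requested ordering (default fresh water > sea water >
  agricultural soil > natural soil), split across compounds by random
  positive weights and across routes by a fish-dominated share profile
  (fish 60%), so route normalization and effect ordering hold by
  construction.

Passing tests on these fixtures demonstrates algebraic correctness,
invertibility and determinism of the pipeline — not that real survey or fate
data satisfy the generators' independence, lognormality or marginal-stratum
structure (real data have survey weights, correlated strata and seasonal
variation the generators do not emulate).

## Pipeline and provenance

`run_full_pipeline` chains all five stages from one YAML/JSON/dict config
merged over documented defaults. Per-stage Monte Carlo seeds are derived
deterministically from the top-level seed (base + 10·group + route), the
report digest hashes all stage outputs (excluding the wall-clock manifest),
and the manifest records seed, config snapshot, package version and SHA-256
digests of any file inputs. Stage failures abort with the stage name and a
nonzero CLI exit status.

## Problem sizes

Default simulations run 10,000 iterations per group × route (a fraction of a
second each); the test suite uses 200–5,000 iterations for distributional
checks and 10,000 where a CI-width claim is asserted, and the acceptance
script runs 20 × 10,000 iterations. Biomarker recovery checks use 500
replicates per stratum.

## Known limitations

* Absolute intake levels from reverse dosimetry are only as good as the
  excretion fractions supplied; defaults are illustrative.
* No numeric characterization factors are bundled; only structural
  properties (additivity, normalization, ordering) are guaranteed.
* The uniform ±25% uncertainty model understates tails relative to
  heavy-tailed exposure-factor data, and independence ignores plausible
  correlations (e.g. EF with ED).
* One metabolite per parent: records from several metabolites of the same
  parent would be pooled like replicates (geometric mean), not summed, so a
  multi-metabolite kinetics table should be collapsed to one entry per
  parent before use.
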