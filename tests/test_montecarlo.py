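"""Monte Carlo sampling, distribution summaries, and histogram exports."""

import math

import numpy as np
import pytest

from pahrisk import (
    Group,
    ParameterDistribution,
    Route,
    SimulationConfig,
    compute_risk,
    export_histogram,
    sample_scenario,
    scenario,
    simulate_risk,
    simulation_config,
    slope_set,
    summarize_distribution,
)
from pahrisk.errors import ConfigError, ValidationError


class TestSampling:
    def test_uniform_draws_stay_within_printed_range(self):
        # body weight 80 +/- 20 -> every draw in [60, 100]
        cfg = simulation_config("adult_trespasser", "oral", seed=7)
        base = scenario("adult_trespasser", "oral")
        rng = np.random.default_rng(7)
        draws = [sample_scenario(cfg, base, rng).BW for _ in range(500)]
        assert min(draws) >= 60.0 and max(draws) <= 100.0
        assert max(draws) - min(draws) > 20  # actually spread over the range

    def test_all_fixed_returns_base_unchanged(self):
        cfg = simulation_config("adult_trespasser", "oral", seed=0, all_fixed=True)
        base = scenario("adult_trespasser", "oral")
        assert sample_scenario(cfg, base) == base

    def test_same_seed_gives_identical_draw_sequences(self):
        cfg = simulation_config("child_recreational", "dermal", seed=11)
        base = scenario("child_recreational", "dermal")
        seq1 = [sample_scenario(cfg, base, np.random.default_rng(11)) for _ in range(1)]
        seq2 = [sample_scenario(cfg, base, np.random.default_rng(11)) for _ in range(1)]
        assert seq1 == seq2

    def test_fixed_symbols_never_perturbed(self):
        cfg = simulation_config("adult_trespasser", "dermal", seed=3)
        base = scenario("adult_trespasser", "dermal")
        s = sample_scenario(cfg, base)
        assert (s.CS, s.CF, s.AT, s.ADAF, s.ABSd) == (base.CS, base.CF, base.AT, base.ADAF, base.ABSd)


class TestConfigValidation:
    def test_unknown_symbol_rejected(self):
        with pytest.raises(ConfigError, match="XX"):
            ParameterDistribution(symbol="XX", mean=1.0)

    def test_duplicate_symbols_rejected(self):
        d = ParameterDistribution(symbol="BW", mean=80, half_width=20)
        e = ParameterDistribution(symbol="EF", mean=40, half_width=10)
        f = ParameterDistribution(symbol="ED", mean=20, half_width=5)
        g = ParameterDistribution(symbol="IR_S", mean=20, half_width=5)
        with pytest.raises(ConfigError, match="duplicate"):
            SimulationConfig(
                group=Group.ADULT_TRESPASSER,
                route=Route.ORAL,
                distributions=(d, d, e, f, g),
            )

    def test_missing_route_symbol_rejected(self):
        bw = ParameterDistribution(symbol="BW", mean=80, half_width=20)
        with pytest.raises(ConfigError, match="IR_S"):
            SimulationConfig(
                group=Group.ADULT_TRESPASSER, route=Route.ORAL, distributions=(bw,)
            )

    def test_half_width_must_leave_support_positive(self):
        with pytest.raises(ValidationError):
            ParameterDistribution(symbol="BW", mean=80, half_width=80)


class TestSimulation:
    def test_all_fixed_collapses_to_point_estimate(self):
        base = scenario("adult_trespasser", "oral")
        slopes = slope_set("oral")
        cfg = simulation_config("adult_trespasser", "oral", n_iterations=50, seed=0, all_fixed=True)
        risks = simulate_risk(cfg, base, slopes)
        point = compute_risk(base, slopes)
        assert np.all(risks == point)

    def test_single_iteration_returns_one_value(self):
        cfg = simulation_config("adult_trespasser", "oral", n_iterations=1, seed=5)
        risks = simulate_risk(cfg, scenario("adult_trespasser", "oral"), slope_set("oral"))
        assert risks.shape == (1,) and risks[0] > 0

    def test_seeded_determinism_bit_identical(self):
        cfg = simulation_config("child_trespasser", "dermal", n_iterations=200, seed=42)
        base = scenario("child_trespasser", "dermal")
        slopes = slope_set("dermal")
        assert np.array_equal(simulate_risk(cfg, base, slopes), simulate_risk(cfg, base, slopes))

    def test_mean_agrees_with_closed_form_expectation(self):
        # independent oracle: E[risk] factorizes over independent draws;
        # E[U(a,b)] = (a+b)/2 and E[1/BW] = ln(b/a)/(b-a) in closed form.
        base = scenario("adult_trespasser", "oral")
        slopes = slope_set("oral")
        e_inv_bw = math.log(100 / 60) / 40
        expected = (
            base.CS * base.FI * base.CF / base.AT * slopes.total * base.ADAF
            * 20 * 40 * 20 * e_inv_bw
        )
        cfg = simulation_config("adult_trespasser", "oral", n_iterations=10000, seed=123)
        risks = simulate_risk(cfg, base, slopes)
        se = risks.std(ddof=1) / math.sqrt(len(risks))
        assert abs(risks.mean() - expected) < 4 * se

    def test_all_risks_positive(self):
        cfg = simulation_config("adult_recreational", "dermal", n_iterations=2000, seed=9)
        risks = simulate_risk(cfg, scenario("adult_recreational", "dermal"), slope_set("dermal"))
        assert np.all(risks > 0)

    def test_raising_cs_scales_every_risk_proportionally(self):
        base = scenario("adult_trespasser", "oral")
        slopes = slope_set("oral")
        cfg = simulation_config("adult_trespasser", "oral", n_iterations=300, seed=2)
        r1 = simulate_risk(cfg, base, slopes)
        r2 = simulate_risk(cfg, base.replace(CS=2 * base.CS), slopes)
        assert np.allclose(r2, 2 * r1, rtol=1e-12)

    @pytest.mark.parametrize("route", list(Route))
    def test_child_groups_dominate_adults_in_mean_risk(self, route):
        means = {}
        for group in Group:
            cfg = simulation_config(group, route, n_iterations=3000, seed=17)
            risks = simulate_risk(cfg, scenario(group, route), slope_set(route))
            means[group] = risks.mean()
        assert means[Group.CHILD_TRESPASSER] > means[Group.ADULT_TRESPASSER]
        assert means[Group.CHILD_RECREATIONAL] > means[Group.ADULT_RECREATIONAL]


class TestSummaries:
    def test_constant_collection_degenerates_cleanly(self):
        s = summarize_distribution(np.full(1000, 3.0e-8))
        assert s.sd == 0.0 and s.ci95_width == 0.0 and s.skewness == 0.0
        assert s.minimum == s.median == s.maximum == s.percentile_2_5 == 3.0e-8

    def test_summary_invariants(self):
        cfg = simulation_config("adult_trespasser", "oral", n_iterations=5000, seed=21)
        risks = simulate_risk(cfg, scenario("adult_trespasser", "oral"), slope_set("oral"))
        s = summarize_distribution(risks)
        assert s.minimum <= s.percentile_2_5 <= s.median <= s.percentile_97_5 <= s.maximum
        assert s.ci95_lower_of_mean <= s.mean <= s.ci95_upper_of_mean
        assert s.n == 5000

    def test_adult_trespasser_oral_ci_width_below_bound(self):
        # 95% CI of the mean narrower than 0.03e-7 at 10,000 iterations
        cfg = simulation_config("adult_trespasser", "oral", n_iterations=10000, seed=33)
        risks = simulate_risk(cfg, scenario("adult_trespasser", "oral"), slope_set("oral"))
        assert summarize_distribution(risks).ci95_width < 0.03e-7

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(1e-9, 1e-7, 400)
        assert summarize_distribution(values) == summarize_distribution(values[::-1])

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            summarize_distribution([])


class TestHistogram:
    def test_counts_conserved_and_edges_cover_range(self, tmp_path):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 1, 10000)
        table = export_histogram(values, bins=20, path=tmp_path / "h.csv")
        assert table["count"].sum() == 10000
        assert table["bin_left"].iloc[0] == pytest.approx(values.min())
        assert table["bin_right"].iloc[-1] == pytest.approx(values.max())
        assert (tmp_path / "h.csv").exists()

    def test_constant_collection_occupies_single_bin(self):
        table = export_histogram(np.full(50, 2.0), bins=10)
        assert (table["count"] > 0).sum() == 1

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValidationError):
            export_histogram([1.0], bins=0)

    def test_seeded_histogram_reproducible(self):
        cfg = simulation_config("adult_trespasser", "oral", n_iterations=500, seed=8)
        base = scenario("adult_trespasser", "oral")
        slopes = slope_set("oral")
        t1 = export_histogram(simulate_risk(cfg, base, slopes), bins=15)
        t2 = export_histogram(simulate_risk(cfg, base, slopes), bins=15)
        assert t1.equals(t2)
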