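"""Monte Carlo propagation of exposure-factor uncertainty through the risk equations.

Each uncertain exposure factor is given a symmetric range (mean +/- half
width, the half width being 25% of the mean in the packaged configuration)
and sampled independently from a uniform distribution over that range; the
sediment concentration, slope factors, averaging time, conversion factor and
age adjustment are held fixed.  Each iteration evaluates the deterministic
risk equation on one sampled scenario, yielding an excess-lifetime-cancer-risk
distribution per population group and route, summarized by moments,
percentiles and a normal-approximation 95% confidence interval of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .risk import CancerSlopeSet, ExposureScenario, Group, Route, compute_risk

__all__ = [
    "ParameterDistribution",
    "SimulationConfig",
    "RiskDistributionSummary",
    "RANDOMIZED_SYMBOLS",
    "sample_scenario",
    "simulate_risk",
    "summarize_distribution",
    "export_histogram",
]

#: Exposure factors randomized per route; everything else is held fixed.
RANDOMIZED_SYMBOLS = {
    Route.ORAL: ("IR_S", "EF", "ED", "BW"),
    Route.DERMAL: ("EF", "ED", "AF", "SA", "BW"),
}

_SCENARIO_FIELDS = frozenset(f.name for f in dc_fields(ExposureScenario))


@dataclass(frozen=True)
class ParameterDistribution:
    """Uniform (or degenerate) sampling range for one scenario field.

    ``half_width`` is the printed "+/-" value; uniform draws cover
    [mean - half_width, mean + half_width].  ``kind='fixed'`` pins the
    factor at its mean.  A truncated-normal alternative
    (``kind='truncnorm'``, sd = half_width / 2, truncated at the range
    bounds) is available but off by default.
    """

    symbol: str
    mean: float
    half_width: float = 0.0
    kind: str = "uniform"

    def __post_init__(self) -> None:
        if self.symbol not in _SCENARIO_FIELDS:
            raise ConfigError(f"unknown scenario symbol: {self.symbol!r}")
        if self.kind not in ("fixed", "uniform", "truncnorm"):
            raise ConfigError(f"unknown distribution kind: {self.kind!r}")
        if self.half_width < 0:
            raise ValidationError(f"{self.symbol}: half_width must be >= 0")
        if self.kind != "fixed" and self.half_width >= self.mean:
            raise ValidationError(
                f"{self.symbol}: half_width {self.half_width} must be smaller than "
                f"mean {self.mean} to keep the support positive"
            )
        if self.kind == "fixed" and self.half_width != 0:
            raise ValidationError(f"{self.symbol}: fixed distribution needs half_width 0")

    def draw(self, rng: np.random.Generator, size: int | None = None):
        if self.kind == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        lo, hi = self.mean - self.half_width, self.mean + self.half_width
        if self.kind == "uniform":
            return rng.uniform(lo, hi, size=size)
        sd = self.half_width / 2.0
        a, b = (lo - self.mean) / sd, (hi - self.mean) / sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=sd, size=size, random_state=rng)


@dataclass(frozen=True)
class SimulationConfig:
    group: Group
    route: Route
    distributions: tuple[ParameterDistribution, ...]
    n_iterations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "route", Route(self.route))
        object.__setattr__(self, "distributions", tuple(self.distributions))
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        symbols = [d.symbol for d in self.distributions]
        if len(set(symbols)) != len(symbols):
            raise ConfigError(f"duplicate distribution symbols in config: {symbols}")
        missing = [s for s in RANDOMIZED_SYMBOLS[self.route] if s not in symbols]
        if missing:
            raise ConfigError(
                f"{self.route.value} config must supply distributions for {missing}"
            )


def sample_scenario(
    config: SimulationConfig,
    base: ExposureScenario,
    rng: np.random.Generator | None = None,
) -> ExposureScenario:
    """Draw one scenario: listed symbols sampled in order, the rest from ``base``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    changes = {d.symbol: float(d.draw(rng)) for d in config.distributions}
    return base.replace(**changes)


def simulate_risk(
    config: SimulationConfig,
    base: ExposureScenario,
    slopes: CancerSlopeSet,
) -> np.ndarray:
    """Run the Monte Carlo simulation; returns the n_iterations risk values."""
    if base.route is not config.route:
        raise ConfigError(
            f"base scenario route {base.route.value} != config route {config.route.value}"
        )
    rng = np.random.default_rng(config.seed)
    risks = np.empty(config.n_iterations)
    for i in range(config.n_iterations):
        risks[i] = compute_risk(sample_scenario(config, base, rng), slopes)
    return risks


@dataclass(frozen=True)
class RiskDistributionSummary:
    """Descriptive statistics of a simulated risk distribution."""

    mean: float
    sd: float
    minimum: float
    maximum: float
    median: float
    percentile_2_5: float
    percentile_97_5: float
    ci95_lower_of_mean: float
    ci95_upper_of_mean: float
    skewness: float
    n: int

    @property
    def ci95_width(self) -> float:
        return self.ci95_upper_of_mean - self.ci95_lower_of_mean

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        d["ci95_width"] = self.ci95_width
        return d


def summarize_distribution(risks) -> RiskDistributionSummary:
    """Moments, percentiles (linear interpolation) and the normal-approximation
    95% CI of the mean (mean +/- 1.96 sd / sqrt(n))."""
    values = np.sort(np.asarray(risks, dtype=float))  # order-invariant summary
    if values.size == 0:
        raise ValidationError("cannot summarize an empty risk collection")
    n = int(values.size)
    constant = values[0] == values[-1]
    mean = float(values.mean())
    sd = 0.0 if (n == 1 or constant) else float(values.std(ddof=1))
    half = 1.96 * sd / np.sqrt(n)
    # adjusted Fisher-Pearson sample skewness; defined as 0 for constant input
    skewness = 0.0 if sd == 0.0 else float(stats.skew(values, bias=False))
    return RiskDistributionSummary(
        mean=mean,
        sd=sd,
        minimum=float(values.min()),
        maximum=float(values.max()),
        median=float(np.median(values)),
        percentile_2_5=float(np.percentile(values, 2.5)),
        percentile_97_5=float(np.percentile(values, 97.5)),
        ci95_lower_of_mean=mean - half,
        ci95_upper_of_mean=mean + half,
        skewness=skewness,
        n=n,
    )


def export_histogram(
    risks,
    bins: int = 20,
    path: str | Path | None = None,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Bin the risk values; optionally write a CSV table and a histogram plot.

    Bin edges cover [min, max]; counts sum to the number of values.
    """
    if bins < 1:
        raise ValidationError("bins must be >= 1")
    values = np.asarray(risks, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot histogram an empty risk collection")
    counts, edges = np.histogram(values, bins=bins)
    table = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    if path is not None:
        table.to_csv(path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(values, bins=bins, color="steelblue", edgecolor="white")
        ax.set_xlabel("excess lifetime cancer risk")
        ax.set_ylabel("iterations")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return table
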