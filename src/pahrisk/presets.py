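"""Packaged exposure-factor configuration for the Superfund sediment assessment.

Four receptor groups (adult/child trespassers and recreational users) are
parameterized for oral and dermal sediment contact.  Each uncertain factor
carries a symmetric +/- range equal to 25% of its mean; the mixture sediment
concentration of the seven contaminants of concern (0.283 mg/kg), the cancer
averaging time (25550 days), the unit conversion factor (1e-6 kg/mg), the
dermal absorption fraction (0.13) and the age adjustment (ADAF 10 for
children, 1 for adults) are fixed.  Slope factors are route-specific values
for the seven PAH contaminants of concern.
"""

from __future__ import annotations

from .montecarlo import RANDOMIZED_SYMBOLS, ParameterDistribution, SimulationConfig
from .risk import CancerSlopeSet, ExposureScenario, Group, Route

__all__ = [
    "COC_NAMES",
    "SEDIMENT_CS_MG_KG",
    "slope_set",
    "scenario",
    "simulation_config",
]

#: Shared sediment concentration of the 7-PAH mixture, mg/kg.
SEDIMENT_CS_MG_KG = 0.283
AVERAGING_TIME_DAYS = 25550.0
CONVERSION_FACTOR = 1e-6
DERMAL_ABSORPTION_FRACTION = 0.13

#: The seven sediment PAH contaminants of concern.
COC_NAMES = (
    "Benz(a)anthracene",
    "Benzo(a)pyrene",
    "Benzo(b)fluoranthene",
    "Benzo(k)fluoranthene",
    "Chrysene",
    "Dibenz(a,h)anthracene",
    "Indeno(1,2,3-c,d)pyrene",
)

ORAL_SLOPE_FACTORS = {
    "Benz(a)anthracene": 7.30e-01,
    "Benzo(a)pyrene": 7.30e00,
    "Benzo(b)fluoranthene": 7.30e-01,
    "Benzo(k)fluoranthene": 7.30e-02,
    "Chrysene": 7.30e-03,
    "Dibenz(a,h)anthracene": 7.30e00,
    "Indeno(1,2,3-c,d)pyrene": 7.30e-01,
}

DERMAL_SLOPE_FACTORS = {
    "Benz(a)anthracene": 2.50e00,
    "Benzo(a)pyrene": 2.50e01,
    "Benzo(b)fluoranthene": 2.50e00,
    "Benzo(k)fluoranthene": 2.50e-01,
    "Chrysene": 2.50e-02,
    "Dibenz(a,h)anthracene": 2.50e01,
    "Indeno(1,2,3-c,d)pyrene": 2.50e00,
}

#: (mean, half_width) per uncertain factor, plus the fixed ADAF, by group.
GROUP_PARAMETERS = {
    Group.ADULT_TRESPASSER: {
        "BW": (80.0, 20.0),
        "EF": (40.0, 10.0),
        "ED": (20.0, 5.0),
        "IR_S": (20.0, 5.0),
        "AF": (0.07, 0.0175),
        "SA": (6032.0, 1508.0),
        "ADAF": 1.0,
    },
    Group.CHILD_TRESPASSER: {
        "BW": (15.0, 3.75),
        "EF": (52.0, 13.0),
        "ED": (6.0, 1.5),
        "IR_S": (50.0, 12.5),
        "AF": (0.2, 0.05),
        "SA": (2373.0, 593.25),
        "ADAF": 10.0,
    },
    Group.ADULT_RECREATIONAL: {
        "BW": (80.0, 20.0),
        "EF": (32.0, 8.0),
        "ED": (20.0, 5.0),
        "IR_S": (20.0, 5.0),
        "AF": (0.2, 0.05),
        "SA": (6032.0, 1508.0),
        "ADAF": 1.0,
    },
    Group.CHILD_RECREATIONAL: {
        "BW": (15.0, 3.75),
        "EF": (48.0, 12.0),
        "ED": (6.0, 1.5),
        "IR_S": (50.0, 12.5),
        "AF": (0.07, 0.0175),
        "SA": (2373.0, 593.25),
        "ADAF": 10.0,
    },
}


def slope_set(route: Route | str) -> CancerSlopeSet:
    """The packaged seven-compound slope-factor set for a route."""
    route = Route(route)
    slopes = ORAL_SLOPE_FACTORS if route is Route.ORAL else DERMAL_SLOPE_FACTORS
    return CancerSlopeSet(route=route, slopes=slopes)


def scenario(group: Group | str, route: Route | str) -> ExposureScenario:
    """Mean-value exposure scenario for a group and route."""
    group, route = Group(group), Route(route)
    p = GROUP_PARAMETERS[group]
    return ExposureScenario(
        group=group,
        route=route,
        CS=SEDIMENT_CS_MG_KG,
        AT=AVERAGING_TIME_DAYS,
        CF=CONVERSION_FACTOR,
        ADAF=p["ADAF"],
        BW=p["BW"][0],
        EF=p["EF"][0],
        ED=p["ED"][0],
        IR_S=p["IR_S"][0],
        AF=p["AF"][0],
        SA=p["SA"][0],
        ABSd=DERMAL_ABSORPTION_FRACTION,
    )


def simulation_config(
    group: Group | str,
    route: Route | str,
    n_iterations: int = 10000,
    seed: int = 0,
    all_fixed: bool = False,
) -> SimulationConfig:
    """Monte Carlo configuration with the packaged +/-25% uniform ranges.

    ``all_fixed=True`` pins every factor at its mean (degenerate simulation
    that collapses to the deterministic point estimate).
    """
    group, route = Group(group), Route(route)
    p = GROUP_PARAMETERS[group]
    dists = tuple(
        ParameterDistribution(
            symbol=symbol,
            mean=p[symbol][0],
            half_width=0.0 if all_fixed else p[symbol][1],
            kind="fixed" if all_fixed else "uniform",
        )
        for symbol in RANDOMIZED_SYMBOLS[route]
    )
    return SimulationConfig(
        group=group,
        route=route,
        distributions=dists,
        n_iterations=n_iterations,
        seed=seed,
    )
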