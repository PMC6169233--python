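"""End-to-end orchestration: run every analysis stage and bundle a report.

The pipeline chains the five stages — mixture annotation, deterministic
point risks, Monte Carlo risk distributions for the four receptor groups and
two routes, reverse-dosimetry intake estimation, and impact
characterization — from a single configuration document, and attaches a run
manifest (seed, config snapshot, package version, input digests) so every
stochastic output carries its provenance.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .dosimetry import (
    STRATUM_AXES,
    default_constants,
    default_kinetics,
    estimate_population,
    load_biomarkers,
    load_kinetics,
    rank_strata,
)
from .characterization import (
    effects_by_compartment,
    load_characterization,
    route_apportionment,
)
from .errors import PahriskError
from .mixture import count_concern, count_priority, load_mixture, summarize_mixture
from .montecarlo import simulate_risk, summarize_distribution
from .presets import COC_NAMES, scenario, simulation_config, slope_set
from .risk import Group, Route, compute_exposure, compute_risk
from .synthetic import (
    SynthesisSpec,
    generate_biomarkers,
    generate_characterization,
    generate_mixture,
)

__all__ = ["RunManifest", "StageError", "run_full_pipeline", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "preset": "synthetic",  # "paper" uses the packaged sediment fixture
    "seed": 0,
    "mixture": {"path": None, "concern_threshold": "low-moderate"},
    "monte_carlo": {"n_iterations": 10000},
    "dosimetry": {
        "enabled": True,
        "biomarkers_path": None,
        "kinetics_path": None,
        "n_replicates": 1,
        "noise_cv": 0.0,
    },
    "characterization": {"enabled": True, "path": None},
}


class StageError(PahriskError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass(frozen=True)
class RunManifest:
    timestamp: str
    seed: int
    package_version: str
    config: dict
    input_digests: dict
    output_paths: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON pipeline configuration and merge over defaults."""
    text = Path(path).read_text()
    loaded = yaml.safe_load(text) or {}
    return _merge(DEFAULT_CONFIG, loaded)


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for key, value in base.items():
        if isinstance(value, dict):
            out[key] = {**value, **override.get(key, {})}
        else:
            out[key] = override.get(key, value)
    for key in override:
        if key not in out:
            out[key] = override[key]
    return out


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc

        return wrapped

    return decorator


@_stage("annotation")
def _run_annotation(config, digests):
    mix_cfg = config["mixture"]
    if mix_cfg.get("path"):
        path = Path(mix_cfg["path"])
        if not path.exists():
            raise FileNotFoundError(f"mixture file not found: {path}")
        digests[str(path)] = _digest_file(path)
        profile = load_mixture(path)
    elif config["preset"] == "paper":
        profile = generate_mixture(SynthesisSpec(seed=config["seed"]), preset="paper")
    else:
        profile = generate_mixture(SynthesisSpec(seed=config["seed"]))
    threshold = mix_cfg.get("concern_threshold", "low-moderate")
    return {
        "n_priority": count_priority(profile),
        "n_concern": count_concern(profile, threshold),
        "concern_threshold": threshold,
        "summary": summarize_mixture(profile),
    }


@_stage("point_risk")
def _run_point_risks():
    out = {}
    for group in Group:
        for route in Route:
            s = scenario(group, route)
            slopes = slope_set(route)
            out[f"{group.value}/{route.value}"] = {
                "exposure_mg_kg_day": compute_exposure(s),
                "risk": compute_risk(s, slopes),
                "n_slope_compounds": len(slopes),
            }
    return out


@_stage("monte_carlo")
def _run_monte_carlo(config):
    n = int(config["monte_carlo"].get("n_iterations", 10000))
    base_seed = int(config["seed"])
    out = {}
    for i, group in enumerate(Group):
        for j, route in enumerate(Route):
            seed = base_seed + 10 * i + j  # distinct stream per group x route
            cfg = simulation_config(group, route, n_iterations=n, seed=seed)
            risks = simulate_risk(cfg, scenario(group, route), slope_set(route))
            summary = summarize_distribution(risks).to_dict()
            summary["seed"] = seed
            out[f"{group.value}/{route.value}"] = summary
    return out


@_stage("dosimetry")
def _run_dosimetry(config, digests):
    cfg = config["dosimetry"]
    kinetics = (
        load_kinetics(cfg["kinetics_path"]) if cfg.get("kinetics_path") else default_kinetics()
    )
    constants = default_constants()
    if cfg.get("biomarkers_path"):
        path = Path(cfg["biomarkers_path"])
        if not path.exists():
            raise FileNotFoundError(f"biomarker file not found: {path}")
        digests[str(path)] = _digest_file(path)
        records = load_biomarkers(path)
    else:
        spec = SynthesisSpec(seed=config["seed"], noise_cv=float(cfg.get("noise_cv", 0.0)))
        records, _ = generate_biomarkers(
            spec, kinetics, constants, n_replicates=int(cfg.get("n_replicates", 1))
        )
    intakes = estimate_population(records, kinetics, constants)
    return {
        "intake_table": intakes.to_dict(orient="records"),
        "rankings": {axis: rank_strata(intakes, axis) for axis in STRATUM_AXES},
    }


@_stage("characterization")
def _run_characterization(config, digests):
    cfg = config["characterization"]
    if cfg.get("path"):
        path = Path(cfg["path"])
        if not path.exists():
            raise FileNotFoundError(f"characterization file not found: {path}")
        digests[str(path)] = _digest_file(path)
        table = load_characterization(path)
        compounds = list(table.compounds)
    else:
        table = generate_characterization(SynthesisSpec(seed=config["seed"]), compounds=COC_NAMES)
        compounds = list(COC_NAMES)
    effects = effects_by_compartment(table, compounds)
    return {
        "compounds": compounds,
        "effects_by_compartment": effects.to_dict(orient="records"),
        "route_apportionment": {
            compartment: route_apportionment(table, compartment, compounds)
            for compartment in table.compartments
        },
    }


def run_full_pipeline(config: dict | str | Path | None = None, out_dir: str | Path | None = None) -> dict:
    """Run all five stages; returns the report bundle (and writes it if asked).

    The bundle is deterministic for a given configuration: ``bundle["digest"]``
    hashes all stage outputs (manifest excluded, since it carries a wall-clock
    timestamp).
    """
    if config is None:
        config = DEFAULT_CONFIG
    elif isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = _merge(DEFAULT_CONFIG, config)

    digests: dict[str, str] = {}
    bundle = {
        "annotation": _run_annotation(config, digests),
        "point_risk": _run_point_risks(),
        "monte_carlo": _run_monte_carlo(config),
    }
    if config["dosimetry"].get("enabled", True):
        bundle["dosimetry"] = _run_dosimetry(config, digests)
    if config["characterization"].get("enabled", True):
        bundle["characterization"] = _run_characterization(config, digests)

    bundle["digest"] = hashlib.sha256(
        json.dumps(bundle, sort_keys=True, default=str).encode()
    ).hexdigest()

    output_paths: list[str] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(bundle, indent=2, default=str) + "\n")
        output_paths.append(str(report_path))

    manifest = RunManifest(
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        seed=int(config["seed"]),
        package_version=__version__,
        config=config,
        input_digests=digests,
        output_paths=tuple(output_paths),
    )
    bundle["manifest"] = manifest.to_dict()
    if out_dir is not None:
        (out_dir / "manifest.json").write_text(
            json.dumps(bundle["manifest"], indent=2, default=str) + "\n"
        )
    return bundle
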