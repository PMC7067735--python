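"""Pipeline configuration: shipped defaults overlaid by a user YAML.

All published constants (species parameters, economics) live in
``data/defaults.yaml``, not in code; a user config overrides any subset
by deep merge. Validation errors name the offending field.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
from pathlib import Path

import yaml

from .economics import EconomicParams, SpeciesEconomics
from .productivity import ProductivityFunction, SpeciesParams
from .scenarios import validate_levels
from .synthetic import HabitatGenConfig


class ConfigError(ValueError):
    """Configuration failed validation; message names the field."""


def _deep_merge(base: dict, overlay: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in overlay.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_defaults() -> dict:
    text = (
        importlib.resources.files("habfish.data").joinpath("defaults.yaml").read_text()
    )
    return yaml.safe_load(text)


class PipelineConfig:
    """Validated view over the merged config mapping."""

    def __init__(self, raw: dict | None = None):
        self.raw = _deep_merge(load_defaults(), raw or {})
        self._validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def _validate(self) -> None:
        r = self.raw
        try:
            self.scenarios = validate_levels(r["scenarios"])
        except (KeyError, ValueError) as e:
            raise ConfigError(f"scenarios: {e}") from e
        if r.get("target_scenario") not in self.scenarios:
            raise ConfigError(
                f"target_scenario {r.get('target_scenario')!r} not among scenarios"
            )
        if not r.get("species"):
            raise ConfigError("species: at least one species block is required")
        self.seed = int(r["seed"])
        self.output_dir = Path(r["output_dir"])
        self.target_scenario = r["target_scenario"]

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def habitat_gen_config(self) -> HabitatGenConfig:
        s = self.raw["synthetic"]
        try:
            return HabitatGenConfig(
                grid_size=int(s["grid_size"]),
                cell_size=float(s["cell_size"]),
                autocorrelation_range=float(s["autocorrelation_range"]),
                base_prevalence=dict(s["base_prevalence"]),
                secchi_response=dict(s["secchi_response"]),
                technique_noise=float(s["technique_noise"]),
                seed=self.seed,
                scenario_levels=self.scenarios,
            )
        except (KeyError, ValueError) as e:
            raise ConfigError(f"synthetic: {e}") from e

    def species_params(self) -> dict[str, SpeciesParams]:
        out = {}
        for name, blk in self.raw["species"].items():
            try:
                h = blk["hpf"]
                hpf = ProductivityFunction(
                    slope=float(h["slope"]),
                    intercept=float(h["intercept"]),
                    offset=float(h.get("offset", 0.0)),
                    slope_se=h.get("slope_se"),
                    intercept_se=h.get("intercept_se"),
                    n=h.get("n"),
                    p=h.get("p"),
                    r2=h.get("r2"),
                )
                out[name] = SpeciesParams(
                    name=name,
                    migration_distance=float(blk["migration_distance"]),
                    length_cutoff_cm=float(blk["length_cutoff_cm"]),
                    mean_weight_kg=float(blk["mean_weight_kg"]),
                    hpf=hpf,
                    biomass_factor=float(blk["biomass_factor"]),
                    depth_limit=(
                        None if blk.get("depth_limit") is None else float(blk["depth_limit"])
                    ),
                    length_proportion=blk.get("length_proportion"),
                )
            except (KeyError, ValueError) as e:
                raise ConfigError(f"species.{name}: {e}") from e
        return out

    def economic_params(self) -> EconomicParams:
        e = self.raw["economics"]
        try:
            species = {
                name: SpeciesEconomics(
                    wtp_sek_2002=float(blk["wtp_sek_2002"]),
                    wtp_eur=float(blk["wtp_eur"]),
                    wpue_baseline=float(blk["wpue_baseline"]),
                )
                for name, blk in e["species"].items()
            }
            return EconomicParams(
                species=species,
                deflator=float(e["deflator"]),
                fx_sek_per_eur=float(e["fx_sek_per_eur"]),
                effort_perch=float(e["effort_perch"]),
                effort_perch_ci=float(e["effort_perch_ci"]),
                effort_pike=float(e["effort_pike"]),
                effort_pike_ci=float(e["effort_pike_ci"]),
                published_rounding=bool(e.get("published_rounding", True)),
            )
        except (KeyError, ValueError) as ex:
            raise ConfigError(f"economics: {ex}") from ex

    def monitoring_settings(self) -> dict:
        m = self.raw["monitoring"]
        if int(m["n_sites"]) < 3:
            raise ConfigError(f"monitoring.n_sites must be >= 3, got {m['n_sites']}")
        return {
            "n_sites": int(m["n_sites"]),
            "noise_sd": dict(m["noise_sd"]),
            "exclude_sites": list(m.get("exclude_sites") or []),
        }
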