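"""Parameter bundle, placeholder defaults and the YAML config loader.

Every physical parameter in a config file is a mapping with ``value``,
``unit`` and optional ``source`` keys.  The loader checks each unit against
the schema (a water content declared in mL/kg is rejected, not converted),
refuses unknown keys, and attaches a provenance tag per parameter so runs can
report which values are site measurements, literature values or placeholders.

The shipped defaults are an explicitly NON-AUTHORITATIVE placeholder set:
the geometry, partition and transport coefficients are order-of-magnitude
choices calibrated once so the simulated tissue concentrations reproduce the
qualitative part ordering observed in field wheat (root highest, leaf above
stem, root above grain) — they are not fitted to any survey.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import yaml

from .accumulation import SimulationConfig, SimulationResult, simulate, steady_state
from .growth import GrowthParams, TABLE_GROWTH_DEFAULTS, WheatPart
from .uptake import (
    AtmosphereParams,
    MetalEnvironment,
    PartGeometry,
    RootTransportParams,
)

__all__ = ["ModelSetup", "default_setup", "load_config", "save_config", "ConfigError"]

METALS = ("Cu", "Cd", "Pb", "Ni")


class ConfigError(ValueError):
    """Invalid or incomplete parameter configuration."""


@dataclass
class ModelSetup:
    """Everything needed to run the simulator for one or more metals."""

    growth: dict[WheatPart, GrowthParams]
    geometry: dict[WheatPart, PartGeometry]
    root_transport: RootTransportParams
    atmosphere: AtmosphereParams
    environments: dict[str, MetalEnvironment]
    q_up_coeff: dict[WheatPart, float]
    phloem_fraction: float
    sim: SimulationConfig
    provenance: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def run(self, metal: str, env: MetalEnvironment | None = None, **kwargs) -> SimulationResult:
        """Simulate one metal; ``env`` overrides the configured environment."""
        if env is None:
            if metal not in self.environments:
                raise KeyError(f"no environment configured for metal {metal!r}")
            env = self.environments[metal]
        return simulate(
            env,
            self.geometry,
            self.root_transport,
            self.atmosphere,
            self.growth,
            kwargs.pop("cfg", self.sim),
            q_up_coeff=self.q_up_coeff,
            phloem_fraction=self.phloem_fraction,
            **kwargs,
        )

    def plateau(self, metal: str, env: MetalEnvironment | None = None) -> dict[WheatPart, float]:
        env = env or self.environments[metal]
        return steady_state(
            env,
            self.geometry,
            self.root_transport,
            self.atmosphere,
            self.growth,
            self.sim,
            q_up_coeff=self.q_up_coeff,
            phloem_fraction=self.phloem_fraction,
        )

    def with_sim(self, **changes) -> "ModelSetup":
        return replace(self, sim=replace(self.sim, **changes))

    def config_hash(self) -> str:
        """Stable digest of the full parameter set, for run manifests."""
        payload = json.dumps(_setup_to_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_setup() -> ModelSetup:
    """The shipped placeholder parameterisation (see module docstring)."""
    geometry = {
        WheatPart.ROOT: PartGeometry(WheatPart.ROOT, area=2.0, water_content=0.8, k_iw=30.0),
        WheatPart.STEM: PartGeometry(WheatPart.STEM, area=0.05, water_content=0.6, k_iw=15.0),
        WheatPart.LEAF: PartGeometry(
            WheatPart.LEAF, area=0.2, water_content=0.75, k_iw=20.0, permeability=1e-4
        ),
        WheatPart.GRAIN: PartGeometry(
            WheatPart.GRAIN, area=1e-3, water_content=0.12, k_iw=10.0, permeability=1e-5
        ),
    }
    # total soil burdens follow the study area's published per-metal means;
    # bioavailable pools assume ~0.2% soluble / 1% exchangeable at a 1 L/kg
    # soil-solution ratio; soil-water partition ranks Cd most mobile, Pb least
    soil_totals = {"Cu": 22.1, "Cd": 0.6, "Pb": 36.3, "Ni": 28.9}
    k_sw = {"Cu": 20.0, "Cd": 5.0, "Pb": 60.0, "Ni": 40.0}
    c_atm = {"Cu": 1e-6, "Cd": 5e-8, "Pb": 2e-6, "Ni": 5e-7}
    environments = {
        m: MetalEnvironment(
            metal=m,
            c_total_soil=soil_totals[m],
            c_soluble=0.002 * soil_totals[m],
            c_exchangeable=0.010 * soil_totals[m],
            c_atmosphere=c_atm[m],
            soil_mass=200.0,
            k_sw=k_sw[m],
        )
        for m in METALS
    }
    q_up = {
        WheatPart.ROOT: 2.0,
        WheatPart.STEM: 1.0,
        WheatPart.LEAF: 0.5,
        WheatPart.GRAIN: 0.05,
    }
    provenance = {"growth": "field-typical logistic parameters"}
    for key in ("geometry", "atmosphere", "root_transport", "flux", "metals"):
        provenance[key] = "placeholder"
    return ModelSetup(
        growth=dict(TABLE_GROWTH_DEFAULTS),
        geometry=geometry,
        root_transport=RootTransportParams(q=5.0, f_c=1000.0, d_r=1e-6),
        atmosphere=AtmosphereParams(f_p=0.5, v_dep=10.0),
        environments=environments,
        q_up_coeff=q_up,
        phloem_fraction=0.4,
        sim=SimulationConfig(),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# YAML schema

_PART_KEYS = ("root", "stem", "leaf", "grain")

#: expected unit per (section, parameter)
UNIT_SCHEMA: dict[str, dict[str, str]] = {
    "growth": {"m0": "kg", "mmax": "kg", "g": "1/d", "emergence_day": "d"},
    "geometry": {
        "area": "m^2",
        "water_content": "L/kg",
        "k_iw": "L/kg",
        "permeability": "m/d",
    },
    "atmosphere": {"f_p": "-", "v_dep": "m/d"},
    "root_transport": {"q": "L/d", "f_c": "L/m^3", "d_r": "m/d"},
    "flux": {"q_up_coeff": "L/(kg d)", "phloem_fraction": "-"},
    "metals": {
        "c_total_soil": "mg/kg",
        "c_soluble": "mg/L",
        "c_exchangeable": "mg/L",
        "c_atmosphere": "mg/m^3",
        "soil_mass": "kg",
        "k_sw": "L/kg",
    },
    "simulation": {"t_end": "d", "dt": "d", "tau": "d", "grain_emergence": "d"},
}

_MANDATORY_METAL_KEYS = ("c_total_soil", "c_soluble", "c_exchangeable",
                         "c_atmosphere", "soil_mass", "k_sw")


def _read_entry(section: str, key: str, raw: Any, provenance: dict, path: str) -> float:
    expected = UNIT_SCHEMA[section].get(key)
    if expected is None:
        raise ConfigError(f"unknown key {path!r}")
    if isinstance(raw, Mapping):
        extra = set(raw) - {"value", "unit", "source"}
        if extra:
            raise ConfigError(f"unknown sub-keys {sorted(extra)} under {path!r}")
        if "value" not in raw:
            raise ConfigError(f"{path!r} has no 'value'")
        unit = raw.get("unit", expected)
        if unit != expected:
            raise ConfigError(
                f"{path!r}: unit {unit!r} does not match expected {expected!r}"
            )
        provenance[path] = str(raw.get("source", "unspecified"))
        return float(raw["value"])
    # bare numbers are accepted with the schema unit assumed
    provenance[path] = "unspecified"
    return float(raw)


def load_config(path: str) -> ModelSetup:
    """Parse and validate a YAML parameter file into a :class:`ModelSetup`.

    Parameters absent from the file fall back to the placeholder defaults and
    are recorded in ``setup.warnings``; unknown keys and unit mismatches are
    hard errors.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"config {path} is not a mapping")
    known_sections = set(UNIT_SCHEMA)
    unknown = set(doc) - known_sections
    if unknown:
        raise ConfigError(f"unknown config sections {sorted(unknown)}")

    base = default_setup()
    provenance: dict[str, str] = {}
    warnings: list[str] = []

    def section(name: str) -> Mapping:
        sec = doc.get(name)
        if sec is None:
            warnings.append(f"section '{name}' absent; placeholder defaults used")
            return {}
        if not isinstance(sec, Mapping):
            raise ConfigError(f"section '{name}' must be a mapping")
        return sec

    # growth / geometry: one block per part
    growth = dict(base.growth)
    for pname, block in section("growth").items():
        if pname not in _PART_KEYS:
            raise ConfigError(f"unknown part {pname!r} in growth section")
        part = WheatPart(pname)
        vals = {
            k: _read_entry("growth", k, v, provenance, f"growth.{pname}.{k}")
            for k, v in block.items()
        }
        cur = growth[part]
        growth[part] = GrowthParams(
            part,
            vals.get("m0", cur.m0),
            vals.get("mmax", cur.mmax),
            vals.get("g", cur.g),
            vals.get("emergence_day", cur.emergence_day),
        )

    geometry = dict(base.geometry)
    for pname, block in section("geometry").items():
        if pname not in _PART_KEYS:
            raise ConfigError(f"unknown part {pname!r} in geometry section")
        part = WheatPart(pname)
        vals = {
            k: _read_entry("geometry", k, v, provenance, f"geometry.{pname}.{k}")
            for k, v in block.items()
        }
        cur = geometry[part]
        geometry[part] = PartGeometry(
            part,
            vals.get("area", cur.area),
            vals.get("water_content", cur.water_content),
            vals.get("k_iw", cur.k_iw),
            vals.get("permeability", cur.permeability),
        )

    atm_block = section("atmosphere")
    atm_vals = {
        k: _read_entry("atmosphere", k, v, provenance, f"atmosphere.{k}")
        for k, v in atm_block.items()
    }
    atmosphere = AtmosphereParams(
        f_p=atm_vals.get("f_p", base.atmosphere.f_p),
        v_dep=atm_vals.get("v_dep", base.atmosphere.v_dep),
    )

    rt_block = section("root_transport")
    rt_vals = {
        k: _read_entry("root_transport", k, v, provenance, f"root_transport.{k}")
        for k, v in rt_block.items()
    }
    root_transport = RootTransportParams(
        q=rt_vals.get("q", base.root_transport.q),
        f_c=rt_vals.get("f_c", base.root_transport.f_c),
        d_r=rt_vals.get("d_r", base.root_transport.d_r),
    )

    flux_block = section("flux")
    q_up = dict(base.q_up_coeff)
    phloem = base.phloem_fraction
    for key, raw in flux_block.items():
        if key == "phloem_fraction":
            phloem = _read_entry("flux", key, raw, provenance, "flux.phloem_fraction")
        elif key == "q_up_coeff":
            if not isinstance(raw, Mapping):
                raise ConfigError("flux.q_up_coeff must map parts to entries")
            for pname, v in raw.items():
                if pname not in _PART_KEYS:
                    raise ConfigError(f"unknown part {pname!r} in flux.q_up_coeff")
                q_up[WheatPart(pname)] = _read_entry(
                    "flux", "q_up_coeff", v, provenance, f"flux.q_up_coeff.{pname}"
                )
        else:
            raise ConfigError(f"unknown key 'flux.{key}'")

    environments = dict(base.environments)
    metals_block = section("metals")
    for metal, block in metals_block.items():
        if not isinstance(block, Mapping):
            raise ConfigError(f"metals.{metal} must be a mapping")
        missing = set(_MANDATORY_METAL_KEYS) - set(block)
        if missing:
            raise ConfigError(
                f"metals.{metal}: missing mandatory parameter(s) {sorted(missing)} "
                f"(k_sw is the soil-water partition coefficient K_SW)"
            )
        vals = {
            k: _read_entry("metals", k, v, provenance, f"metals.{metal}.{k}")
            for k, v in block.items()
        }
        environments[metal] = MetalEnvironment(metal=metal, **vals)

    sim_block = section("simulation")
    sim_vals = {
        k: _read_entry("simulation", k, v, provenance, f"simulation.{k}")
        for k, v in sim_block.items()
    }
    sim = SimulationConfig(
        t_end=sim_vals.get("t_end", base.sim.t_end),
        dt=sim_vals.get("dt", base.sim.dt),
        grain_emergence=sim_vals.get("grain_emergence", base.sim.grain_emergence),
        tau=sim_vals.get("tau", base.sim.tau),
    )

    for path_key, tag in provenance.items():
        if tag == "placeholder":
            warnings.append(f"{path_key} uses a placeholder value")

    return ModelSetup(
        growth=growth,
        geometry=geometry,
        root_transport=root_transport,
        atmosphere=atmosphere,
        environments=environments,
        q_up_coeff=q_up,
        phloem_fraction=phloem,
        sim=sim,
        provenance=provenance,
        warnings=warnings,
    )


def _setup_to_dict(setup: ModelSetup) -> dict:
    def entry(value: float, section: str, key: str, source: str = "placeholder") -> dict:
        return {"value": value, "unit": UNIT_SCHEMA[section][key], "source": source}

    doc: dict = {"growth": {}, "geometry": {}}
    for part, gp in setup.growth.items():
        doc["growth"][part.value] = {
            "m0": entry(gp.m0, "growth", "m0"),
            "mmax": entry(gp.mmax, "growth", "mmax"),
            "g": entry(gp.g, "growth", "g"),
            "emergence_day": entry(gp.emergence_day, "growth", "emergence_day"),
        }
    for part, pg in setup.geometry.items():
        block = {
            "area": entry(pg.area, "geometry", "area"),
            "water_content": entry(pg.water_content, "geometry", "water_content"),
            "k_iw": entry(pg.k_iw, "geometry", "k_iw"),
        }
        if pg.permeability is not None:
            block["permeability"] = entry(pg.permeability, "geometry", "permeability")
        doc["geometry"][part.value] = block
    doc["atmosphere"] = {
        "f_p": entry(setup.atmosphere.f_p, "atmosphere", "f_p"),
        "v_dep": entry(setup.atmosphere.v_dep, "atmosphere", "v_dep"),
    }
    doc["root_transport"] = {
        "q": entry(setup.root_transport.q, "root_transport", "q"),
        "f_c": entry(setup.root_transport.f_c, "root_transport", "f_c"),
        "d_r": entry(setup.root_transport.d_r, "root_transport", "d_r"),
    }
    doc["flux"] = {
        "q_up_coeff": {
            part.value: entry(v, "flux", "q_up_coeff")
            for part, v in setup.q_up_coeff.items()
        },
        "phloem_fraction": entry(setup.phloem_fraction, "flux", "phloem_fraction"),
    }
    doc["metals"] = {
        metal: {
            k: entry(getattr(env, k), "metals", k)
            for k in _MANDATORY_METAL_KEYS
        }
        for metal, env in setup.environments.items()
    }
    doc["simulation"] = {
        "t_end": entry(setup.sim.t_end, "simulation", "t_end", "default"),
        "dt": entry(setup.sim.dt, "simulation", "dt", "default"),
        "tau": entry(setup.sim.tau, "simulation", "tau", "default"),
        "grain_emergence": entry(
            setup.sim.grain_emergence, "simulation", "grain_emergence", "default"
        ),
    }
    return doc


def save_config(setup: ModelSetup, path: str) -> None:
    """Write a setup back to YAML in the loader's schema."""
    with open(path, "w") as fh:
        yaml.safe_dump(_setup_to_dict(setup), fh, sort_keys=False)
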