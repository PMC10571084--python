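"""Config loading, serialization, and run manifests.

System configs are YAML with explicit unit tags on every physical
quantity; concentrations are converted to molar on load. The bundled
``"magzet1"`` preset name resolves to the packaged characterization
constants.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .equilibria import Component, EquilibriumSystem, Reaction
from .photophysics import Channel, ChannelSet, SpeciesSpectrum
from .units import to_molar

__all__ = ["SystemBundle", "load_system_config", "dump_system_config", "RunManifest"]


@dataclass(frozen=True)
class SystemBundle:
    """A validated system + spectra + channels triple from one config."""

    system: EquilibriumSystem
    spectra: dict[str, SpeciesSpectrum]
    channels: ChannelSet | None


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ValueError(f"config field {key!r} missing in {context}")
    return mapping[key]


def load_system_config(path: str | Path) -> SystemBundle:
    """Load a system config file (or the bundled ``"magzet1"`` preset).

    Schema errors raise ValueError naming the offending field; unknown
    units raise ValueError from the unit table.
    """
    if str(path) == "magzet1":
        text = (resources.files("ionsense") / "data/magzet1.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)

    components = []
    for c in raw.get("components", []):
        total = to_molar(float(c.get("total", 0.0)), _require(c, "unit", f"component {c.get('name')!r}")) \
            if c.get("role") != "proton" else 0.0
        components.append(
            Component(_require(c, "name", "components"), _require(c, "role", "components"), total)
        )
    reactions = []
    for r in raw.get("reactions", []):
        name = _require(r, "product", "reactions")
        kd = to_molar(float(_require(r, "kd", f"reaction {name!r}")),
                      _require(r, "unit", f"reaction {name!r}"))
        reactions.append(
            Reaction(
                name,
                {k: int(v) for k, v in _require(r, "stoichiometry", f"reaction {name!r}").items()},
                kd,
                temperature_label=r.get("temperature", ""),
                medium_label=r.get("medium", ""),
            )
        )
    system = EquilibriumSystem(components, reactions, ph=raw.get("ph"))

    spectra = {}
    for name, s in (raw.get("spectra") or {}).items():
        spectra[name] = SpeciesSpectrum(
            name,
            [tuple(float(v) for v in band) for band in s.get("bands", [])],
            brightness=float(s.get("brightness", 1.0)),
        )
    channels = None
    if "channels" in raw and raw["channels"]:
        ch = raw["channels"]
        channels = ChannelSet(
            excitation=float(ch.get("excitation", 390.0)),
            channels=[
                Channel(_require(c, "name", "channels"), float(c["center"]),
                        float(c.get("bandwidth", 1.0)))
                for c in _require(ch, "list", "channels")
            ],
        )
    return SystemBundle(system, spectra, channels)


def dump_system_config(bundle: SystemBundle, path: str | Path) -> None:
    """Write a SystemBundle back to YAML (molar units) for round-trips."""
    raw = {
        "components": [
            {"name": c.name, "role": c.role, "total": c.total_concentration, "unit": "M"}
            for c in bundle.system.components
        ],
        "reactions": [
            {
                "product": r.product_name,
                "stoichiometry": dict(r.stoichiometry),
                "kd": r.kd,
                "unit": "M",
                "temperature": r.temperature_label,
                "medium": r.medium_label,
            }
            for r in bundle.system.reactions
        ],
        "ph": bundle.system.ph,
        "spectra": {
            name: {"bands": [list(b) for b in s.emission_bands], "brightness": s.brightness}
            for name, s in bundle.spectra.items()
        },
    }
    if bundle.channels is not None:
        raw["channels"] = {
            "excitation": bundle.channels.excitation,
            "list": [
                {"name": c.name, "center": c.center, "bandwidth": c.bandwidth}
                for c in bundle.channels.channels
            ],
        }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class RunManifest:
    """One line of reproducibility metadata per CLI invocation."""

    command: str
    config_hash: str
    seed: int | None
    inputs: list[str]
    outputs: list[str]
    version: str = __version__
    timestamp: float = 0.0

    @classmethod
    def create(cls, command, config_text="", seed=None, inputs=(), outputs=()):
        return cls(
            command=command,
            config_hash=hashlib.sha256(config_text.encode()).hexdigest()[:16],
            seed=seed,
            inputs=list(inputs),
            outputs=list(outputs),
            timestamp=time.time(),
        )

    def append_to(self, path: str | Path) -> None:
        with open(path, "a") as fh:
            fh.write(json.dumps(self.__dict__) + "\n")
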