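"""Configuration loading, output serialization, and run manifests.

Config files are YAML (JSON is a YAML subset and accepted as-is).  All
quantity keys embed their unit (``temperature_C``, ``food_cells_per_mL``)
to prevent unit bugs.  A :class:`RunManifest` captures everything needed to
reproduce a run bit-for-bit: the config echo, the master seed, and the
package and coefficient-table versions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .food import Vessel
from .responses import load_coefficients
from .simulator import (FOOD_SETUP_CELLS, MEASURED_TEMPERATURE_C,
                        MonteCarloSummary, SimulationConfig, SimulationResult)

__all__ = ["RunManifest", "load_config", "preset_config", "write_outputs",
           "CONFIG_PRESETS"]

_CONFIG_KEYS = {
    "temperature_C", "food_cells_per_mL", "vessel", "n_initial_nauplii",
    "days", "reproduction_enabled", "mode", "temperature_variant",
    "feed_interval_days", "p_female", "replicates", "master_seed",
}

_VESSEL_KEYS = {"volume_mL", "bottom_area_cm2", "carbon_per_cell_ug"}


def _build_presets() -> dict:
    presets = {}
    for name, t in MEASURED_TEMPERATURE_C.items():
        presets[f"devtest-{name}"] = SimulationConfig(
            temperature_C=t, n_initial_nauplii=72, days=35,
            mode="direct_temperature", reproduction_enabled=False,
            replicates=1000)
    for name, cells in FOOD_SETUP_CELLS.items():
        presets[f"devtest-food-{name}"] = SimulationConfig(
            temperature_C=22.0, food_cells_per_mL=cells, n_initial_nauplii=35,
            days=45, mode="direct_food", reproduction_enabled=False,
            replicates=1000)
    return presets


CONFIG_PRESETS = _build_presets()


def preset_config(name: str) -> SimulationConfig:
    """A named treatment preset (e.g. ``devtest-20C``: 72 nauplii, 35 days,
    reproduction disabled, direct temperature mode)."""
    try:
        return replace(CONFIG_PRESETS[name])
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(CONFIG_PRESETS)}"
        ) from None


def load_config(source: Union[str, Path, dict]) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a YAML/JSON file or
    a mapping.

    Unknown keys are rejected by name.  ``temperature_C`` is required —
    no default temperature is assumed.  ``vessel`` may be a preset name or
    a mapping with ``volume_mL``/``bottom_area_cm2`` (and optionally
    ``carbon_per_cell_ug``).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a mapping, got {type(raw).__name__}")
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    if "temperature_C" not in raw:
        raise ValueError("config requires temperature_C (no default temperature)")
    # YAML 1.1 reads exponents like 2.5e5 (no sign) as strings; coerce
    for key in ("temperature_C", "food_cells_per_mL", "p_female"):
        if key in raw:
            raw[key] = float(raw[key])
    for key in ("n_initial_nauplii", "days", "feed_interval_days",
                "replicates", "master_seed"):
        if key in raw:
            raw[key] = int(raw[key])
    vessel = raw.get("vessel")
    if isinstance(vessel, dict):
        unknown_v = sorted(set(vessel) - _VESSEL_KEYS)
        if unknown_v:
            raise ValueError(f"unknown vessel keys: {', '.join(unknown_v)}")
        raw = dict(raw, vessel=Vessel(**vessel))
    return SimulationConfig(**raw)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's outputs bit-for-bit."""

    config: dict
    master_seed: int
    package_version: str
    coefficients_version: str
    created_utc: str

    @classmethod
    def for_run(cls, config: SimulationConfig) -> "RunManifest":
        from . import __version__
        cfg = asdict(config)
        if isinstance(config.vessel, Vessel):
            cfg["vessel"] = asdict(config.vessel)
        return cls(config=cfg, master_seed=config.master_seed,
                   package_version=__version__,
                   coefficients_version=str(load_coefficients()["version"]),
                   created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def write_outputs(result: Optional[SimulationResult],
                  summary: Optional[MonteCarloSummary],
                  manifest: RunManifest, outdir: Union[str, Path]) -> dict:
    """Write tidy CSVs and the manifest JSON to `outdir`.

    Column order is fixed, so re-running with the same manifest reproduces
    byte-identical CSVs (the manifest itself carries a timestamp).  Returns
    the mapping of logical name to written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    if result is not None:
        path = outdir / "abundance.csv"
        result.abundance.to_csv(path, index=False)
        written["abundance"] = path
        path = outdir / "events.csv"
        result.events.to_csv(path, index=False)
        written["events"] = path
    if summary is not None:
        path = outdir / "bands.csv"
        summary.to_frame().to_csv(path, index=False)
        written["bands"] = path
    path = outdir / "manifest.json"
    path.write_text(manifest.to_json() + "\n")
    written["manifest"] = path
    return written
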