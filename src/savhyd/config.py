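"""YAML configuration loading/validation and run manifests.

One YAML file with sections ``climate``, ``soil``, ``vegetation``,
``herbivory``, ``scenario``, ``analysis``; every free constant named in the
model modules is addressable here.  Unknown keys are rejected by name so
typos fail loudly.  A run manifest (config hash, master seed, package
version) accompanies every output directory; identical manifests reproduce
outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .climate import ClimateConfig
from .herbivory import FeedingSettings
from .runner import ScenarioConfig
from .terrain import SoilParams

_SECTIONS = {"climate", "soil", "vegetation", "herbivory", "scenario", "analysis"}

_VEG_KEYS = {"wue", "b0", "est_margin", "ld_rate", "p_est", "init_meta_cover", "stress_margin"}
_SCENARIO_KEYS = {
    "land_use", "stocking_rate", "years", "replicates", "rows", "cols",
    "cell_size", "seed",
}
_ANALYSIS_KEYS = {"window", "richness_threshold_pct"}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in config section '{section}': {sorted(unknown)}"
        )


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration.

    Returns a dict with instantiated ``climate_config``, ``soil``,
    ``scenario`` (ScenarioConfig) and an ``analysis`` dict; defaults are
    injected for everything omitted.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    _check_keys("(root)", raw, _SECTIONS)

    climate_kwargs = dict(raw.get("climate") or {})
    _check_keys("climate", climate_kwargs,
                {f.name for f in dataclasses.fields(ClimateConfig)})
    if "wet_season_months" in climate_kwargs:
        climate_kwargs["wet_season_months"] = frozenset(climate_kwargs["wet_season_months"])
    climate = ClimateConfig(**climate_kwargs)

    soil_kwargs = dict(raw.get("soil") or {})
    _check_keys("soil", soil_kwargs, {f.name for f in dataclasses.fields(SoilParams)})
    if "layer_depths" in soil_kwargs:
        soil_kwargs["layer_depths"] = tuple(soil_kwargs["layer_depths"])
    soil = SoilParams(**soil_kwargs)

    veg = dict(raw.get("vegetation") or {})
    _check_keys("vegetation", veg, _VEG_KEYS)

    herb = dict(raw.get("herbivory") or {})
    _check_keys("herbivory", herb, {"feeding"})
    feeding = FeedingSettings(herb["feeding"]) if "feeding" in herb else None

    scen = dict(raw.get("scenario") or {})
    _check_keys("scenario", scen, _SCENARIO_KEYS)
    scenario = ScenarioConfig(
        soil=soil, climate_config=climate, feeding=feeding, **veg, **scen
    )

    analysis = dict(raw.get("analysis") or {})
    _check_keys("analysis", analysis, _ANALYSIS_KEYS)
    analysis.setdefault("window", 20)
    analysis.setdefault("richness_threshold_pct", 2.5)

    return {
        "climate_config": climate,
        "soil": soil,
        "scenario": scenario,
        "analysis": analysis,
        "raw": raw,
    }


def save_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.get("raw", {}), sort_keys=True))


def config_hash(raw: dict) -> str:
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: str | Path, raw_config: dict, seed: int,
                   inputs: dict[str, str] | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(raw_config),
        "master_seed": seed,
        "savhyd_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "input_digests": inputs or {},
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return p


def write_outputs(summary, out_dir: str | Path, raw_config: dict | None = None,
                  seed: int | None = None) -> dict[str, Path]:
    """Write a RunSummary as tidy CSVs (stable column order) plus manifest."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create output directory {out_dir}: {err}") from err
    paths = {}
    for name, df in (
        ("cover", summary.cover),
        ("water", summary.water),
        ("herbivory", summary.herbivory),
    ):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.8g")
        paths[name] = p
    if raw_config is not None:
        paths["manifest"] = write_manifest(out_dir, raw_config, seed or 0)
    return paths
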