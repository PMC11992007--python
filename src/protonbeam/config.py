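"""Configuration loading and strict validation for CLI runs.

Configs are single human-editable YAML files (JSON is a YAML subset and is
accepted transparently).  Validation is strict: unknown keys are rejected
with a message naming the offending field, so typos fail fast instead of
silently taking defaults.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .beam import EnergyWindow
from .medium import MediumModel, get_medium
from .planning import RegionPartition, TreatmentPlan, select_basis_energies
from .radiobiology import get_cell_line

__all__ = ["ConfigError", "load_config", "plan_from_config"]


class ConfigError(ValueError):
    """Malformed configuration; the CLI maps this to exit code 2."""


PLAN_KEYS = {
    "medium", "window", "tumour", "oar", "weights", "objective", "cell",
    "n_beams", "sigma2", "range_interval", "upper_bound", "grid", "target",
    "dose_scale",
}
WEIGHT_KEYS = {"tumour", "oar", "healthy"}
GRID_KEYS = {"z_max", "n"}


def load_config(path: str | Path) -> dict:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping at top level")
    return data


def _reject_unknown(cfg: dict, allowed: set[str], where: str) -> None:
    unknown = set(cfg) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown field(s) {sorted(unknown)}")


def _resolve_medium(spec) -> MediumModel:
    if isinstance(spec, str):
        try:
            return get_medium(spec)
        except KeyError as exc:
            raise ConfigError(str(exc)) from exc
    if isinstance(spec, dict):
        try:
            return MediumModel(name=spec.get("name", "custom"),
                               alpha=spec["alpha"], p=spec["p"],
                               rho=spec.get("rho", 1.0))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"medium: {exc}") from exc
    raise ConfigError("medium: expected a registry name or a parameter mapping")


def plan_from_config(cfg: dict) -> TreatmentPlan:
    """Build a TreatmentPlan from a validated config mapping."""
    _reject_unknown(cfg, PLAN_KEYS, "plan config")
    for required in ("medium", "tumour", "n_beams", "sigma2", "range_interval"):
        if required not in cfg:
            raise ConfigError(f"plan config: missing required field {required!r}")
    medium = _resolve_medium(cfg["medium"])
    window = EnergyWindow(*cfg.get("window", [0.1, 150.0]))
    try:
        regions = RegionPartition(tumour=tuple(cfg["tumour"]),
                                  oar=tuple(cfg["oar"]) if cfg.get("oar") else None)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"regions: {exc}") from exc
    weights_cfg = cfg.get("weights", {"tumour": 1.0, "oar": 0.0, "healthy": 0.0})
    _reject_unknown(weights_cfg, WEIGHT_KEYS, "weights")
    weights = (float(weights_cfg.get("tumour", 1.0)),
               float(weights_cfg.get("oar", 0.0)),
               float(weights_cfg.get("healthy", 0.0)))
    grid_cfg = cfg.get("grid", {})
    _reject_unknown(grid_cfg, GRID_KEYS, "grid")
    z_max = float(grid_cfg.get("z_max", regions.tumour[1] + 2.0))
    n_z = int(grid_cfg.get("n", 1200))
    grid = np.linspace(0.0, z_max, n_z)
    objective = cfg.get("objective", "dose")
    cell = get_cell_line(cfg["cell"]) if cfg.get("cell") else None
    try:
        basis = select_basis_energies(int(cfg["n_beams"]),
                                      tuple(cfg["range_interval"]),
                                      float(cfg["sigma2"]), medium, window)
        return TreatmentPlan(
            basis, regions, medium, target=cfg.get("target", 1.0),
            weights=weights, objective=objective, cell=cell, grid=grid,
            window=window, upper_bound=cfg.get("upper_bound"),
            dose_scale=float(cfg.get("dose_scale", 1.0)),
        )
    except (TypeError, ValueError, KeyError) as exc:
        raise ConfigError(f"plan config: {exc}") from exc
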