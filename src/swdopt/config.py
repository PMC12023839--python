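"""YAML run-configuration loading and validation.

The config is a flat YAML document with four required sections (``design``,
``correlation``, ``costs``, ``power``) and an optional ``outputs`` section.
Cost keys use the conventional one-letter symbols (``c``, ``k``, ``kp``,
``p``, ``pp``, ``g``, ``gp``). Unknown keys anywhere are errors so that
typos never silently change a run. Defaults (``alpha: 0.05``,
``min_power: 0.80``, zero costs) are applied explicitly and echoed by the
CLI run log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .costs import CostSpec
from .design import Design, from_schematic, make_complete_stepped_wedge
from .grid import CorrelationGrid
from .variance import STRUCTURES, CorrelationSpec, PowerSpec

__all__ = ["ConfigError", "OutputOptions", "RunConfig", "load_config", "parse_config"]

_COST_KEYS = {
    "c": "cost_per_cluster",
    "k": "cluster_cost_intervention",
    "kp": "cluster_cost_control",
    "p": "participant_cost_intervention",
    "pp": "participant_cost_control",
    "g": "restart_cost_intervention",
    "gp": "restart_cost_control",
}


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass(frozen=True)
class OutputOptions:
    write_trace: bool = True
    write_schematics: bool = True
    filter_min_power: bool = False
    plots: bool = False


@dataclass(frozen=True)
class RunConfig:
    design: Design
    correlation: "CorrelationSpec | CorrelationGrid"
    costs: CostSpec
    power: PowerSpec
    outputs: OutputOptions = field(default_factory=OutputOptions)

    @property
    def is_grid(self) -> bool:
        return isinstance(self.correlation, CorrelationGrid)


def _require_mapping(node, path: str) -> dict:
    if not isinstance(node, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(node).__name__}")
    return node


def _check_keys(node: dict, allowed: set[str], path: str) -> None:
    unknown = set(node) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def _number(node, path: str) -> float:
    if isinstance(node, bool) or not isinstance(node, (int, float)):
        raise ConfigError(f"{path}: expected a number, got {node!r}")
    return float(node)


def _parse_design(node, path: str = "design") -> Design:
    node = _require_mapping(node, path)
    kind = node.get("type")
    if kind == "standard_sw":
        _check_keys(
            node,
            {"type", "n_sequences", "clusters_per_sequence", "cluster_period_size"},
            path,
        )
        try:
            return make_complete_stepped_wedge(
                node["n_sequences"],
                node["clusters_per_sequence"],
                node["cluster_period_size"],
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing key {exc.args[0]!r}") from None
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"{path}: {exc}") from None
    if kind == "schematic":
        _check_keys(
            node, {"type", "rows", "clusters_per_sequence", "cluster_period_size"}, path
        )
        try:
            return from_schematic(
                node["rows"],
                node["clusters_per_sequence"],
                node["cluster_period_size"],
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing key {exc.args[0]!r}") from None
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"{path}: {exc}") from None
    raise ConfigError(
        f"{path}.type: expected 'standard_sw' or 'schematic', got {kind!r}"
    )


def _parse_correlation(node, path: str = "correlation"):
    node = _require_mapping(node, path)
    _check_keys(node, {"structure", "icc", "cac"}, path)
    structure = node.get("structure", "discrete_time_decay")
    if structure not in STRUCTURES:
        raise ConfigError(
            f"{path}.structure: expected one of {STRUCTURES}, got {structure!r}"
        )
    if "icc" not in node:
        raise ConfigError(f"{path}: missing key 'icc'")
    icc, cac = node["icc"], node.get("cac", 1.0)
    as_list = isinstance(icc, list) or isinstance(cac, list)
    try:
        if as_list:
            icc_values = icc if isinstance(icc, list) else [icc]
            cac_values = cac if isinstance(cac, list) else [cac]
            return CorrelationGrid(
                tuple(_number(v, f"{path}.icc") for v in icc_values),
                tuple(_number(v, f"{path}.cac") for v in cac_values),
                structure,
            )
        return CorrelationSpec(
            icc=_number(icc, f"{path}.icc"),
            cac=_number(cac, f"{path}.cac"),
            structure=structure,
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def _parse_costs(node, path: str = "costs") -> CostSpec:
    node = _require_mapping(node, path)
    _check_keys(node, set(_COST_KEYS), path)
    kwargs = {}
    for key, fieldname in _COST_KEYS.items():
        if key in node:
            kwargs[fieldname] = _number(node[key], f"{path}.{key}")
    try:
        return CostSpec(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def _parse_power(node, path: str = "power") -> PowerSpec:
    node = _require_mapping(node, path)
    _check_keys(node, {"effect_size", "alpha", "min_power"}, path)
    if "effect_size" not in node:
        raise ConfigError(f"{path}: missing key 'effect_size'")
    try:
        return PowerSpec(
            effect_size=_number(node["effect_size"], f"{path}.effect_size"),
            alpha=_number(node.get("alpha", 0.05), f"{path}.alpha"),
            min_power=_number(node.get("min_power", 0.80), f"{path}.min_power"),
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def _parse_outputs(node, path: str = "outputs") -> OutputOptions:
    if node is None:
        return OutputOptions()
    node = _require_mapping(node, path)
    allowed = {"write_trace", "write_schematics", "filter_min_power", "plots"}
    _check_keys(node, allowed, path)
    kwargs = {}
    for key in allowed:
        if key in node:
            if not isinstance(node[key], bool):
                raise ConfigError(f"{path}.{key}: expected a boolean")
            kwargs[key] = node[key]
    return OutputOptions(**kwargs)


def parse_config(data: dict) -> RunConfig:
    """Validate an already-parsed YAML mapping into a :class:`RunConfig`."""
    data = _require_mapping(data, "<config>")
    _check_keys(data, {"design", "correlation", "costs", "power", "outputs"}, "<config>")
    for section in ("design", "correlation", "costs", "power"):
        if section not in data:
            raise ConfigError(f"<config>: missing section {section!r}")
    return RunConfig(
        design=_parse_design(data["design"]),
        correlation=_parse_correlation(data["correlation"]),
        costs=_parse_costs(data["costs"]),
        power=_parse_power(data["power"]),
        outputs=_parse_outputs(data.get("outputs")),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML config file."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse error: {exc}") from None
    if data is None:
        raise ConfigError(f"{path}: empty config file")
    return parse_config(data)
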