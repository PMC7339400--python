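"""Flat key-value (INI) configuration for the simulator.

Sections map onto the parameter dataclasses: [diagenesis] (rate constants
plus the layer thicknesses h1/h2), [routing] (channel/carbon parameters
plus reach length/width and watershed_area_ha), [forcing] (synthetic
forcing spec), [budget] and [sensitivity].  Unknown sections or keys are
rejected; every key has a valid default, so a zero-config run completes.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .diagenesis import DiagenesisParams, LayerGeometry
from .forcing import ForcingSpec
from .routing import ReachGeometry, RoutingParams

__all__ = ["BudgetConfig", "SensitivityConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class BudgetConfig:
    calendar_complete: bool = True


@dataclass(frozen=True)
class SensitivityConfig:
    """Latin-hypercube ensemble settings; ranges as 'name = low, high' keys."""

    k: int = 100
    alpha: float = 0.05
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "v_lpoc": (0.01, 0.5),
            "v_rpoc": (0.05, 1.0),
            "spcon": (0.0001, 0.01),
            "spexp": (1.0, 1.5),
            "prf": (0.005, 0.1),
        }
    )


@dataclass(frozen=True)
class RunConfig:
    diagenesis: DiagenesisParams = DiagenesisParams()
    layers: LayerGeometry = LayerGeometry()
    routing: RoutingParams = RoutingParams()
    reach: ReachGeometry = ReachGeometry()
    forcing: ForcingSpec = ForcingSpec()
    budget: BudgetConfig = BudgetConfig()
    sensitivity: SensitivityConfig = SensitivityConfig()
    watershed_area_ha: float = 22_070.0
    initial_bed_store: float = 0.0  # g m^-2
    output_dir: str = "sedcarb_out"
    log_level: str = "INFO"

    def manifest(self, seed: int | None = None) -> dict:
        """Run provenance: config hash, seed, package version."""
        from . import __version__

        blob = json.dumps(_as_plain_dict(self), sort_keys=True, default=str)
        return {
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": seed,
            "version": __version__,
        }


def _as_plain_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_plain_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    return obj


def _coerce(raw: str, annotation: type):
    if annotation is bool:
        low = raw.strip().lower()
        if low in ("true", "1", "yes", "on"):
            return True
        if low in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"not a boolean: {raw!r}")
    if annotation is int:
        return int(raw)
    if annotation is float:
        return float(raw)
    return raw


def _build_section(cls, items: dict[str, str], section: str):
    valid = {f.name: f.type for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, raw in items.items():
        if key not in valid:
            raise ValueError(f"unknown key {key!r} in section [{section}]")
        ftype = cls.__dataclass_fields__[key].type
        py_type = {"int": int, "float": float, "bool": bool, "str": str}.get(
            str(ftype), str
        )
        kwargs[key] = _coerce(raw, py_type)
    return cls(**kwargs)


# section -> (target RunConfig field(s)); diagenesis splits off h1/h2 and
# routing splits off length/width/watershed_area_ha/initial_bed_store.
_RUN_KEYS = {"output_dir": str, "log_level": str}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Parse an INI config into a RunConfig; None gives all defaults."""
    if path is None:
        return RunConfig()
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise FileNotFoundError(path)

    known = {"diagenesis", "routing", "forcing", "budget", "sensitivity", "run"}
    unknown = set(parser.sections()) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    kwargs: dict = {}

    diag_items = dict(parser.items("diagenesis")) if parser.has_section("diagenesis") else {}
    layer_items = {k: diag_items.pop(k) for k in ("h1", "h2") if k in diag_items}
    kwargs["diagenesis"] = _build_section(DiagenesisParams, diag_items, "diagenesis")
    kwargs["layers"] = _build_section(LayerGeometry, layer_items, "diagenesis")

    rout_items = dict(parser.items("routing")) if parser.has_section("routing") else {}
    reach_items = {k: rout_items.pop(k) for k in ("length", "width") if k in rout_items}
    if "watershed_area_ha" in rout_items:
        kwargs["watershed_area_ha"] = float(rout_items.pop("watershed_area_ha"))
    if "initial_bed_store" in rout_items:
        kwargs["initial_bed_store"] = float(rout_items.pop("initial_bed_store"))
    kwargs["routing"] = _build_section(RoutingParams, rout_items, "routing")
    kwargs["reach"] = _build_section(ReachGeometry, reach_items, "routing")

    if parser.has_section("forcing"):
        kwargs["forcing"] = _build_section(
            ForcingSpec, dict(parser.items("forcing")), "forcing"
        )

    if parser.has_section("budget"):
        kwargs["budget"] = _build_section(
            BudgetConfig, dict(parser.items("budget")), "budget"
        )

    if parser.has_section("sensitivity"):
        items = dict(parser.items("sensitivity"))
        k = int(items.pop("k", SensitivityConfig.k))
        alpha = float(items.pop("alpha", SensitivityConfig.alpha))
        if items:
            ranges = {}
            for name, raw in items.items():
                parts = [p.strip() for p in raw.split(",")]
                if len(parts) != 2:
                    raise ValueError(
                        f"sensitivity range {name!r} must be 'low, high'"
                    )
                ranges[name] = (float(parts[0]), float(parts[1]))
        else:
            ranges = SensitivityConfig().ranges
        kwargs["sensitivity"] = SensitivityConfig(k=k, alpha=alpha, ranges=ranges)

    if parser.has_section("run"):
        for key, raw in parser.items("run"):
            if key not in _RUN_KEYS:
                raise ValueError(f"unknown key {key!r} in section [run]")
            kwargs[key] = raw

    return RunConfig(**kwargs)
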