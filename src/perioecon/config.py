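"""YAML/JSON parameter configuration: loading and the shipped base case."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .params import (
    CostItem,
    ParameterSet,
    ProbabilityParam,
    RelativeRisk,
    UtilityParam,
    aggregate_cost,
)
from .sensitivity import DistributionSpec

__all__ = [
    "basecase_path",
    "load_config",
    "load_parameter_set",
    "parse_parameter_set",
    "parse_dsa_rows",
    "parse_psa_specs",
]


def basecase_path() -> Path:
    """Path of the shipped base-case configuration (printed model inputs)."""
    return Path(resources.files("perioecon") / "data" / "basecase_2021.yaml")


def load_config(path) -> dict:
    """Read a YAML or JSON configuration document."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def parse_parameter_set(doc: dict) -> ParameterSet:
    """Build a validated ParameterSet from a parsed config document."""
    currency = doc.get("currency", "BRL")
    probs = {
        name: ProbabilityParam(
            value=float(spec["value"]),
            horizon_years=float(spec.get("horizon_years", 1.0)),
            label=spec.get("label", name),
            source=spec.get("source", ""),
        )
        for name, spec in doc["probabilities"].items()
    }
    rrs = {
        name: RelativeRisk(
            point=float(spec["point"]),
            log_mean=spec.get("log_mean"),
            log_sd=spec.get("log_sd"),
            label=name,
        )
        for name, spec in doc["relative_risks"].items()
    }
    costs = {}
    for name, spec in doc["costs"].items():
        items = [
            CostItem(
                label=item.get("label", ""),
                amount=float(item["amount"]),
                currency=item.get("currency", currency),
            )
            for item in spec["items"]
        ]
        bundle = aggregate_cost(items)
        if "total" in spec and abs(bundle.total - float(spec["total"])) > 0.005:
            raise ValueError(
                f"costs.{name}: declared total {spec['total']} does not match "
                f"item sum {bundle.total:.2f}"
            )
        costs[name] = bundle
    utils = {
        name: UtilityParam(
            value=float(spec["value"]),
            low=spec.get("low"),
            high=spec.get("high"),
            state_label=name,
        )
        for name, spec in doc["utilities"].items()
    }
    return ParameterSet(
        probabilities=probs,
        relative_risks=rrs,
        costs=costs,
        utilities=utils,
        discount_rate=float(doc["discount_rate"]),
        horizon_cycles=int(doc["horizon_cycles"]),
        cycle_length_years=float(doc.get("cycle_length_years", 1.0)),
        ppp_rate=float(doc.get("ppp_rate", 2.46)),
        ohip_max=float(doc.get("ohip_max", 56.0)),
        time_rescale=doc.get("time_rescale", "hazard"),
        discount_effects=bool(doc.get("discount_effects", True)),
        half_cycle_correction=bool(doc.get("half_cycle_correction", False)),
    )


def parse_dsa_rows(doc: dict) -> list[dict]:
    """The one-way sensitivity rows (param, min, base, max, label)."""
    return [dict(row) for row in doc.get("dsa", {}).get("rows", [])]


def parse_psa_specs(doc: dict) -> dict[str, DistributionSpec]:
    """Per-parameter sampling distributions for the PSA."""
    specs = {}
    for name, spec in doc.get("psa", {}).get("distributions", {}).items():
        specs[name] = DistributionSpec(
            kind=spec["kind"],
            minimum=spec.get("min"),
            mode=spec.get("mode"),
            maximum=spec.get("max"),
            log_mean=spec.get("log_mean"),
            log_sd=spec.get("log_sd"),
            value=spec.get("value"),
        )
    return specs


def load_parameter_set(path=None) -> ParameterSet:
    """Load a ParameterSet from a config file (the shipped base case by default)."""
    doc = load_config(path if path is not None else basecase_path())
    return parse_parameter_set(doc)
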