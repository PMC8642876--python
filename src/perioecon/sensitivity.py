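"""Deterministic (one-way / tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs both arms with a single parameter at its minimum
and maximum while everything else stays at base, and orders parameters by
the spread they induce in incremental cost.  The probabilistic analysis
draws every uncertain parameter independently from its assigned
distribution — triangular for costs, quit probability and utilities,
uniform for the discount rate, lognormal for the tooth-loss risk ratios
(whose published moments are on the log scale) — evaluates both arms on the
same draw, and records per-iteration (cost, effect, QALY) pairs.  Draws
that imply an invalid derived probability (RR x p > 1) are rejected and
redrawn so the sampled distribution is never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .econ import PSASampleSet, incremental_analysis
from .markov import arm_expected_values
from .params import OVERRIDE_NAMES, ModelInputs, ParameterSet

__all__ = [
    "DistributionSpec",
    "OneWayResult",
    "sample_distribution",
    "run_one_way_dsa",
    "run_psa",
]

_KINDS = ("TRIANGULAR", "UNIFORM", "LOGNORMAL_RR", "FIXED")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one model parameter."""

    kind: str
    minimum: float | None = None
    mode: float | None = None
    maximum: float | None = None
    log_mean: float | None = None
    log_sd: float | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        kind = self.kind.upper()
        object.__setattr__(self, "kind", kind)
        if kind not in _KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if kind == "TRIANGULAR":
            if None in (self.minimum, self.mode, self.maximum):
                raise ValueError("triangular needs (minimum, mode, maximum)")
            if not self.minimum <= self.mode <= self.maximum:
                raise ValueError("triangular needs minimum <= mode <= maximum")
        elif kind == "UNIFORM":
            if None in (self.minimum, self.maximum):
                raise ValueError("uniform needs (minimum, maximum)")
            if not self.minimum < self.maximum:
                raise ValueError("uniform needs minimum < maximum")
        elif kind == "LOGNORMAL_RR":
            if None in (self.log_mean, self.log_sd):
                raise ValueError("lognormal needs (log_mean, log_sd)")
            if self.log_sd < 0:
                raise ValueError("log_sd must be >= 0")
        elif kind == "FIXED" and self.value is None:
            raise ValueError("fixed needs a value")

    @property
    def mean(self) -> float:
        """Analytic mean of the distribution (used in moment checks)."""
        if self.kind == "TRIANGULAR":
            return (self.minimum + self.mode + self.maximum) / 3.0
        if self.kind == "UNIFORM":
            return (self.minimum + self.maximum) / 2.0
        if self.kind == "LOGNORMAL_RR":
            return float(np.exp(self.log_mean + self.log_sd**2 / 2.0))
        return self.value


def sample_distribution(spec: DistributionSpec, rng: np.random.Generator, size=None):
    """Draw from a distribution spec with the supplied generator."""
    if spec.kind == "TRIANGULAR":
        if spec.minimum == spec.maximum:  # degenerate
            return spec.mode if size is None else np.full(size, spec.mode)
        return rng.triangular(spec.minimum, spec.mode, spec.maximum, size=size)
    if spec.kind == "UNIFORM":
        return rng.uniform(spec.minimum, spec.maximum, size=size)
    if spec.kind == "LOGNORMAL_RR":
        return np.exp(rng.normal(spec.log_mean, spec.log_sd, size=size))
    return spec.value if size is None else np.full(size, spec.value)


# ---------------------------------------------------------------------------
# one-way deterministic analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OneWayResult:
    """Both-arm outcomes with one parameter at its range endpoints."""

    parameter: str
    low: float
    base: float
    high: float
    outcomes: dict  # "low"/"base"/"high" -> dict of dC, dE_cea, dE_cua, classification
    spread: float  # |dC(high) - dC(low)|
    label: str = ""

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.parameter}: base {self.base} outside [{self.low}, {self.high}]"
            )


def _incrementals(inputs: ModelInputs) -> dict:
    sct = arm_expected_values(inputs, "SCT")
    nosct = arm_expected_values(inputs, "NO_SCT")
    cea = incremental_analysis(sct, nosct, "effect")
    cua = incremental_analysis(sct, nosct, "qaly")
    return {
        "delta_cost": cea.delta_cost,
        "delta_effect_cea": cea.delta_effect,
        "delta_effect_cua": cua.delta_effect,
        "classification_cea": cea.classification,
        "classification_cua": cua.classification,
    }


def run_one_way_dsa(
    ps: ParameterSet,
    dsa_rows,
    include_implant_scenario: bool = True,
) -> list[OneWayResult]:
    """One-way sweep over (parameter, min, base, max) rows, tornado-ordered.

    Each row re-runs both arms with that single parameter at its endpoints,
    all other inputs at the base case.  When requested, an implant-
    rehabilitation scenario row (rehabilitation cost and utility swapped to
    the implant bundle) is appended.  Results come back sorted by descending
    spread in incremental cost.
    """
    base_inputs = ps.to_model_inputs()
    results: list[OneWayResult] = []
    for row in dsa_rows:
        param = row["param"]
        if param not in OVERRIDE_NAMES:
            raise KeyError(f"unknown DSA parameter {param!r}")
        lo, base, hi = float(row["min"]), float(row["base"]), float(row["max"])
        outcomes = {
            "low": _incrementals(base_inputs.with_overrides({param: lo})),
            "base": _incrementals(base_inputs.with_overrides({param: base})),
            "high": _incrementals(base_inputs.with_overrides({param: hi})),
        }
        spread = abs(outcomes["high"]["delta_cost"] - outcomes["low"]["delta_cost"])
        results.append(
            OneWayResult(
                parameter=param, low=lo, base=base, high=hi,
                outcomes=outcomes, spread=spread, label=row.get("label", param),
            )
        )
    if include_implant_scenario:
        implant = ps.to_model_inputs(rehab_mode="implant")
        outcomes = {
            "low": _incrementals(base_inputs),
            "base": _incrementals(base_inputs),
            "high": _incrementals(implant),
        }
        spread = abs(outcomes["high"]["delta_cost"] - outcomes["low"]["delta_cost"])
        results.append(
            OneWayResult(
                parameter="rehab_mode",
                low=0.0, base=0.0, high=1.0,
                outcomes=outcomes, spread=spread,
                label="implant_rehabilitation_scenario",
            )
        )
    results.sort(key=lambda r: -r.spread)
    return results


def tornado_frame(results) -> "object":
    """Flatten one-way results into a tornado table (descending spread)."""
    import pandas as pd

    rows = []
    for r in results:
        rec = {"parameter": r.parameter, "label": r.label,
               "low": r.low, "base": r.base, "high": r.high, "spread": r.spread}
        for end in ("low", "base", "high"):
            for k, v in r.outcomes[end].items():
                rec[f"{end}_{k}"] = v
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

_MAX_CONSECUTIVE_REJECTIONS = 1000


def _draw_valid(specs: dict, base: ModelInputs, rng: np.random.Generator) -> ModelInputs:
    rejections = 0
    while True:
        draw = {name: float(sample_distribution(spec, rng)) for name, spec in specs.items()}
        candidate = base.with_overrides(draw)
        try:
            candidate.p_loss("FORMER")
            candidate.p_loss("CURRENT")
        except ValueError:
            rejections += 1
            if rejections > _MAX_CONSECUTIVE_REJECTIONS:
                raise RuntimeError(
                    "over 1000 consecutive invalid parameter draws; "
                    "the PSA distributions are mis-specified"
                )
            continue
        return candidate


def run_psa(
    ps: ParameterSet | ModelInputs,
    specs: dict,
    iterations: int,
    seed: int,
) -> PSASampleSet:
    """Monte-Carlo PSA: per iteration, draw all parameters, run both arms on
    the same draw, and record (cost, effect, qaly) per arm.

    Fully reproducible for a given seed; invalid draws (derived probability
    above 1) are rejected and redrawn.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    unknown = set(specs) - set(OVERRIDE_NAMES)
    if unknown:
        raise KeyError(f"unknown PSA parameters: {sorted(unknown)}")
    base = ps.to_model_inputs() if isinstance(ps, ParameterSet) else ps
    rng = np.random.default_rng(seed)
    costs = {a: np.empty(iterations) for a in ("SCT", "NO_SCT")}
    effects = {a: np.empty(iterations) for a in ("SCT", "NO_SCT")}
    qalys = {a: np.empty(iterations) for a in ("SCT", "NO_SCT")}
    for i in range(iterations):
        inputs = _draw_valid(specs, base, rng)
        for arm in ("SCT", "NO_SCT"):
            res = arm_expected_values(inputs, arm)
            costs[arm][i] = res.expected_cost
            effects[arm][i] = res.expected_effect
            qalys[arm][i] = res.expected_qaly
    return PSASampleSet(costs=costs, effects=effects, qalys=qalys, seed=seed)
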