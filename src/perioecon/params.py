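"""Model inputs as validated domain types, plus the parameter-derivation formulas.

The decision model compares implementing smoking-cessation therapy (SCT)
against not implementing it in periodontitis patients, so its inputs are
(i) transition probabilities (quit rates, annual tooth-loss probability in
non-smokers, probability of not rehabilitating a lost tooth), (ii) risk
ratios of tooth loss for former and current smokers relative to
non-smokers, (iii) itemised costs in Brazilian reais (converted to
purchasing-power-parity US$), and (iv) oral-health-state utilities obtained
by mapping OHIP (Oral Health Impact Profile) scores linearly onto [0, 1].

This module houses those types and the small derivation formulas:
time-rescaling of probabilities, risk-ratio application, OHIP-to-utility
mapping, cost aggregation and PPP currency conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ProbabilityParam",
    "RelativeRisk",
    "CostItem",
    "CostBundle",
    "UtilityParam",
    "ParameterSet",
    "ModelInputs",
    "ValidationIssue",
    "multi_year_to_annual_prob",
    "annual_to_multi_year_prob",
    "apply_relative_risk",
    "ohip_to_utility",
    "aggregate_cost",
    "convert_currency_ppp",
    "validate_parameter_set",
]


# ---------------------------------------------------------------------------
# scalar formulas
# ---------------------------------------------------------------------------

def multi_year_to_annual_prob(p_multi: float, years: float) -> float:
    """Rescale a probability observed over ``years`` to a 1-year probability.

    Assumes a constant hazard over the observation window, so the annual
    value is ``1 - (1 - p)**(1/years)``.  Compounding the result over
    ``years`` independent annual trials recovers ``p_multi`` exactly.

    Raises
    ------
    ValueError
        If ``p_multi`` is not in [0, 1) (a probability of 1 over a finite
        window implies an infinite hazard) or ``years`` is not positive.
    """
    if not 0.0 <= p_multi < 1.0:
        raise ValueError(f"p_multi must be in [0, 1), got {p_multi!r}")
    if years <= 0:
        raise ValueError(f"years must be positive, got {years!r}")
    return -math.expm1(math.log1p(-p_multi) / years)


def annual_to_multi_year_prob(p_annual: float, years: float) -> float:
    """Compound a 1-year probability over ``years``: ``1 - (1 - p)**years``."""
    if not 0.0 <= p_annual < 1.0:
        raise ValueError(f"p_annual must be in [0, 1), got {p_annual!r}")
    if years <= 0:
        raise ValueError(f"years must be positive, got {years!r}")
    return -math.expm1(years * math.log1p(-p_annual))


def proportional_to_annual_prob(p_multi: float, years: float) -> float:
    """Naive rescaling ``p / years``, kept as a sensitivity-check alternative
    to the constant-hazard formula."""
    if not 0.0 <= p_multi < 1.0:
        raise ValueError(f"p_multi must be in [0, 1), got {p_multi!r}")
    if years <= 0:
        raise ValueError(f"years must be positive, got {years!r}")
    return p_multi / years


def ohip_to_utility(ohip_score: float, ohip_max: float) -> float:
    """Map an OHIP score linearly to a utility in [0, 1].

    0 (no oral-health impact) maps to utility 1, the instrument maximum maps
    to 0.  The instrument length (``ohip_max``; 56 for OHIP-14, 196 for
    OHIP-49) is a parameter because published studies use both variants.
    """
    if ohip_max <= 0:
        raise ValueError(f"ohip_max must be positive, got {ohip_max!r}")
    if not 0.0 <= ohip_score <= ohip_max:
        raise ValueError(
            f"ohip_score must be in [0, {ohip_max}], got {ohip_score!r}"
        )
    return 1.0 - ohip_score / ohip_max


def convert_currency_ppp(amount: float, ppp_rate: float) -> float:
    """Convert an amount by a purchasing-power-parity factor (amount / rate).

    The returned value is unrounded; reporting layers round to 2 decimals.
    """
    if ppp_rate <= 0:
        raise ValueError(f"ppp_rate must be positive, got {ppp_rate!r}")
    return amount / ppp_rate


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityParam:
    """A probability together with the time frame it was measured over."""

    value: float
    horizon_years: float = 1.0
    label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"probability {self.label!r}: value {self.value} outside [0, 1]")
        if self.horizon_years <= 0:
            raise ValueError(f"probability {self.label!r}: horizon_years must be > 0")

    def annual(self, method: str = "hazard") -> float:
        """The 1-year probability, rescaled if the source window differs."""
        if self.horizon_years == 1.0:
            return self.value
        if method == "hazard":
            return multi_year_to_annual_prob(self.value, self.horizon_years)
        if method == "proportional":
            return proportional_to_annual_prob(self.value, self.horizon_years)
        raise ValueError(f"unknown rescaling method {method!r}")


@dataclass(frozen=True)
class RelativeRisk:
    """Risk ratio of tooth loss vs. non-smokers, with its log-scale moments.

    ``log_mean``/``log_sd`` parameterise the lognormal sampling distribution
    used in probabilistic sensitivity analysis.  When both the point value
    and log_mean are given, exp(log_mean) should agree with the point value
    to ~2% (a larger gap is reported by :func:`validate_parameter_set` as a
    warning-level issue, not an error, because published point estimates and
    pooled log-scale moments can legitimately differ).
    """

    point: float
    log_mean: float | None = None
    log_sd: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.point <= 0:
            raise ValueError(f"relative risk {self.label!r}: point must be > 0")
        if self.log_sd is not None and self.log_sd < 0:
            raise ValueError(f"relative risk {self.label!r}: log_sd must be >= 0")

    def log_consistency_gap(self) -> float | None:
        """Relative error between exp(log_mean) and the point value."""
        if self.log_mean is None:
            return None
        return abs(math.exp(self.log_mean) - self.point) / self.point


def apply_relative_risk(p_ref: float, rr: RelativeRisk | float) -> float:
    """Derive a stratum probability as RR x reference probability.

    Errors (never clamps) when the product exceeds 1, so that invalid
    sensitivity-analysis draws are rejected rather than silently distorted.
    """
    point = rr.point if isinstance(rr, RelativeRisk) else float(rr)
    if not 0.0 <= p_ref <= 1.0:
        raise ValueError(f"p_ref must be in [0, 1], got {p_ref!r}")
    if point <= 0:
        raise ValueError(f"risk ratio must be positive, got {point!r}")
    p = point * p_ref
    if p > 1.0:
        raise ValueError(
            f"RR x p = {point} x {p_ref} = {p} exceeds 1: not a probability"
        )
    return p


@dataclass(frozen=True)
class CostItem:
    label: str
    amount: float
    currency: str = "BRL"
    recurrence: str = "upfront"  # upfront | per_cycle | per_event

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"cost item {self.label!r}: negative amount")
        if not self.currency:
            raise ValueError(f"cost item {self.label!r}: empty currency")
        if self.recurrence not in ("upfront", "per_cycle", "per_event"):
            raise ValueError(f"cost item {self.label!r}: bad recurrence {self.recurrence!r}")


@dataclass(frozen=True)
class CostBundle:
    """An ordered list of cost items sharing one currency, with their total."""

    items: tuple[CostItem, ...]
    total: float
    currency: str

    def converted_total(self, ppp_rate: float) -> float:
        """Bundle total in PPP-US$ (identity if already expressed in USD)."""
        if self.currency in ("USD", "USD-PPP"):
            return self.total
        return convert_currency_ppp(self.total, ppp_rate)


def aggregate_cost(items) -> CostBundle:
    """Sum cost items into a bundle, preserving order.

    All items must share one currency; an empty collection yields a
    zero-total bundle in BRL.
    """
    items = tuple(items)
    if not items:
        return CostBundle(items=(), total=0.0, currency="BRL")
    currencies = {it.currency for it in items}
    if len(currencies) > 1:
        raise ValueError(f"mixed currencies in bundle: {sorted(currencies)}")
    total = math.fsum(it.amount for it in items)
    return CostBundle(items=items, total=total, currency=items[0].currency)


@dataclass(frozen=True)
class UtilityParam:
    """A health-state utility with its deterministic sensitivity range."""

    value: float
    low: float | None = None
    high: float | None = None
    state_label: str = ""

    def __post_init__(self) -> None:
        lo = self.value if self.low is None else self.low
        hi = self.value if self.high is None else self.high
        if not 0.0 <= lo <= self.value <= hi <= 1.0:
            raise ValueError(
                f"utility {self.state_label!r}: need 0 <= low <= value <= high <= 1, "
                f"got ({lo}, {self.value}, {hi})"
            )


# ---------------------------------------------------------------------------
# the full parameter set and the flat engine inputs derived from it
# ---------------------------------------------------------------------------

#: canonical keys for the cost bundles of the model
COST_BUNDLE_KEYS = (
    "sct",
    "periodontal_treatment",
    "maintenance_former",
    "maintenance_current",
    "extraction_no_rehab",
    "extraction_partial_prosthesis",
    "extraction_implant",
)

#: flat parameter names understood by sensitivity-analysis overrides
OVERRIDE_NAMES = (
    "cost_sct",
    "cost_periodontal",
    "cost_maintenance_former",
    "cost_maintenance_current",
    "cost_extraction_no_rehab",
    "cost_extraction_rehab",
    "discount_rate",
    "p_quit_sct",
    "p_quit_no_sct",
    "p_loss_nonsmoker",
    "p_no_rehab",
    "rr_former",
    "rr_current",
    "u_after_treatment",
    "u_maintenance",
    "u_lost_no_rehab",
    "u_lost_rehab",
    "u_periodontitis",
)


@dataclass(frozen=True)
class ModelInputs:
    """Flat, fully derived inputs consumed by the cohort/microsim engines.

    All costs are in PPP-US$ at full floating precision; probabilities are
    per annual cycle.  ``u_periodontitis`` is carried for completeness but
    does not enter the default trajectory (everyone is treated at t = 0).
    """

    p_quit_sct: float
    p_quit_no_sct: float
    p_loss_nonsmoker: float
    p_no_rehab: float
    rr_former: float
    rr_current: float
    cost_sct: float
    cost_periodontal: float
    cost_maintenance_former: float
    cost_maintenance_current: float
    cost_extraction_no_rehab: float
    cost_extraction_rehab: float
    u_after_treatment: float
    u_maintenance: float
    u_lost_no_rehab: float
    u_lost_rehab: float
    u_periodontitis: float
    discount_rate: float
    horizon_cycles: int
    discount_effects: bool = True
    half_cycle_correction: bool = False

    def p_loss(self, smoking_status: str) -> float:
        rr = self.rr_former if smoking_status == "FORMER" else self.rr_current
        return apply_relative_risk(self.p_loss_nonsmoker, rr)

    def with_overrides(self, overrides: dict[str, float]) -> "ModelInputs":
        unknown = set(overrides) - set(OVERRIDE_NAMES)
        if unknown:
            raise KeyError(f"unknown model parameters: {sorted(unknown)}")
        return replace(self, **overrides)


@dataclass(frozen=True)
class ParameterSet:
    """The complete base-case model input (Tables of probabilities, risk
    ratios, itemised costs and utilities, plus discounting and horizon)."""

    probabilities: dict[str, ProbabilityParam]
    relative_risks: dict[str, RelativeRisk]
    costs: dict[str, CostBundle]
    utilities: dict[str, UtilityParam]
    discount_rate: float
    horizon_cycles: int
    cycle_length_years: float = 1.0
    ppp_rate: float = 2.46
    ohip_max: float = 56.0
    time_rescale: str = "hazard"  # or "proportional"
    discount_effects: bool = True
    half_cycle_correction: bool = False

    REQUIRED_PROBABILITIES = (
        "quit_with_sct",
        "quit_without_sct",
        "toothloss_nonsmokers",
        "no_rehab",
    )
    REQUIRED_UTILITIES = (
        "after_periodontal_treatment",
        "maintenance",
        "lost_no_rehab",
        "lost_partial_prosthesis",
    )

    def cost_usd(self, bundle_key: str) -> float:
        """A bundle's total in PPP-US$, unrounded."""
        return self.costs[bundle_key].converted_total(self.ppp_rate)

    def to_model_inputs(
        self,
        rehab_mode: str = "partial_prosthesis",
        overrides: dict[str, float] | None = None,
    ) -> ModelInputs:
        """Derive the flat engine inputs.

        ``rehab_mode`` selects which rehabilitation bundle/utility applies
        after tooth loss ("partial_prosthesis" base case or "implant"
        scenario).  ``overrides`` patches individual flat parameters (used
        by the sensitivity analyses; values on the PPP-US$ scale).
        """
        if rehab_mode not in ("partial_prosthesis", "implant"):
            raise ValueError(f"unknown rehab_mode {rehab_mode!r}")
        probs = {
            k: self.probabilities[k].annual(self.time_rescale)
            for k in self.REQUIRED_PROBABILITIES
        }
        if rehab_mode == "implant":
            rehab_cost = self.cost_usd("extraction_implant")
            u_rehab = self.utilities.get(
                "lost_implant", self.utilities["lost_partial_prosthesis"]
            ).value
        else:
            rehab_cost = self.cost_usd("extraction_partial_prosthesis")
            u_rehab = self.utilities["lost_partial_prosthesis"].value
        u_perio = self.utilities.get("periodontitis")
        inputs = ModelInputs(
            p_quit_sct=probs["quit_with_sct"],
            p_quit_no_sct=probs["quit_without_sct"],
            p_loss_nonsmoker=probs["toothloss_nonsmokers"],
            p_no_rehab=probs["no_rehab"],
            rr_former=self.relative_risks["former"].point,
            rr_current=self.relative_risks["current"].point,
            cost_sct=self.cost_usd("sct"),
            cost_periodontal=self.cost_usd("periodontal_treatment"),
            cost_maintenance_former=self.cost_usd("maintenance_former"),
            cost_maintenance_current=self.cost_usd("maintenance_current"),
            cost_extraction_no_rehab=self.cost_usd("extraction_no_rehab"),
            cost_extraction_rehab=rehab_cost,
            u_after_treatment=self.utilities["after_periodontal_treatment"].value,
            u_maintenance=self.utilities["maintenance"].value,
            u_lost_no_rehab=self.utilities["lost_no_rehab"].value,
            u_lost_rehab=u_rehab,
            u_periodontitis=u_perio.value if u_perio is not None else 0.76,
            discount_rate=self.discount_rate,
            horizon_cycles=self.horizon_cycles,
            discount_effects=self.discount_effects,
            half_cycle_correction=self.half_cycle_correction,
        )
        if overrides:
            inputs = inputs.with_overrides(overrides)
        return inputs


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    path: str
    constraint: str
    observed: object
    severity: str = "error"  # error | warning

    def to_dict(self) -> dict:
        return {
            "path": self.path,
            "constraint": self.constraint,
            "observed": self.observed,
            "severity": self.severity,
        }


def validate_parameter_set(ps: ParameterSet) -> list[ValidationIssue]:
    """Report every violated invariant of a parameter set (empty on success).

    Member types enforce their own invariants at construction; this check
    covers the cross-cutting ones: presence of the required entries, the
    discount rate and horizon ranges, bundle totals matching their item
    sums, derived stratum probabilities RR x p staying within [0, 1], and
    the consistency of each risk ratio's point value with exp(log_mean)
    (warning-level).
    """
    issues: list[ValidationIssue] = []

    def err(path: str, constraint: str, observed, severity: str = "error") -> None:
        issues.append(ValidationIssue(path, constraint, observed, severity))

    for name in ps.REQUIRED_PROBABILITIES:
        if name not in ps.probabilities:
            err(f"probabilities.{name}", "required entry present", "missing")
    for name in ("former", "current"):
        if name not in ps.relative_risks:
            err(f"relative_risks.{name}", "required entry present", "missing")
    for name in COST_BUNDLE_KEYS:
        if name not in ps.costs:
            err(f"costs.{name}", "required entry present", "missing")
    for name in ps.REQUIRED_UTILITIES:
        if name not in ps.utilities:
            err(f"utilities.{name}", "required entry present", "missing")

    if not 0.0 <= ps.discount_rate <= 1.0:
        err("discount_rate", "0 <= rate <= 1", ps.discount_rate)
    if ps.horizon_cycles < 1:
        err("horizon_cycles", ">= 1", ps.horizon_cycles)
    if ps.cycle_length_years <= 0:
        err("cycle_length_years", "> 0", ps.cycle_length_years)
    if ps.ppp_rate <= 0:
        err("ppp_rate", "> 0", ps.ppp_rate)

    for key, bundle in ps.costs.items():
        item_sum = math.fsum(it.amount for it in bundle.items)
        if abs(item_sum - bundle.total) > 0.005:
            err(f"costs.{key}.total", "total == sum(items) +- 0.005", bundle.total)
        if bundle.items and any(it.currency != bundle.currency for it in bundle.items):
            err(f"costs.{key}.currency", "single currency per bundle", bundle.currency)

    p_ref = ps.probabilities.get("toothloss_nonsmokers")
    if p_ref is not None:
        p_annual = p_ref.annual(ps.time_rescale)
        for name, rr in ps.relative_risks.items():
            derived = rr.point * p_annual
            if derived > 1.0:
                err(
                    f"relative_risks.{name}",
                    "RR x p_toothloss_nonsmokers <= 1",
                    derived,
                )
            gap = rr.log_consistency_gap()
            if gap is not None and gap > 0.02:
                err(
                    f"relative_risks.{name}",
                    "|exp(log_mean) - point| / point <= 0.02",
                    gap,
                    severity="warning",
                )
    return issues
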