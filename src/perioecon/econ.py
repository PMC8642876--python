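"""Incremental cost-effectiveness analysis and decision uncertainty summaries.

Given arm-level expected costs and effects, this module classifies the
intervention against its comparator (dominant / dominated / trade-off, with
the ICER where defined), and summarises probabilistic sensitivity analysis
output as cost-effectiveness-plane quadrant probabilities and
cost-effectiveness acceptability curves (CEAC) over a willingness-to-pay
grid, using the net-monetary-benefit decision rule NMB = lambda*E - C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import ArmResult

__all__ = [
    "IncrementalResult",
    "PSASampleSet",
    "QuadrantSummary",
    "CEACurve",
    "incremental_analysis",
    "net_monetary_benefit",
    "quadrant_probabilities",
    "compute_ceac",
    "default_wtp_grid",
]

#: tie-break tolerance for "effects are equal" in classification
_EFFECT_EPS = 1e-12


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental cost/effect of the intervention over the comparator."""

    delta_cost: float
    delta_effect: float
    classification: str  # DOMINANT | DOMINATED | TRADEOFF_NE | TRADEOFF_SW | INDIFFERENT
    icer: float | None
    effect_measure: str = "effect"

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "classification": self.classification,
            "icer": self.icer,
            "effect_measure": self.effect_measure,
        }


def incremental_analysis(
    intervention: ArmResult,
    comparator: ArmResult,
    effect_field: str = "effect",
) -> IncrementalResult:
    """Classify the intervention vs. the comparator on the CE plane.

    ``effect_field`` picks the effect measure: ``"effect"`` (tooth-loss
    avoided, CEA) or ``"qaly"`` (oral-health-related QALYs, CUA).  The ICER
    dC/dE is reported only for genuine trade-offs (NE: more costly, more
    effective; SW: cheaper, less effective); dominance makes a ratio
    meaningless and it is left undefined.
    """
    if effect_field not in ("effect", "qaly"):
        raise ValueError(f"effect_field must be 'effect' or 'qaly', got {effect_field!r}")
    attr = "expected_effect" if effect_field == "effect" else "expected_qaly"
    dc = intervention.expected_cost - comparator.expected_cost
    de = getattr(intervention, attr) - getattr(comparator, attr)

    if abs(de) < _EFFECT_EPS:
        if dc > 0:
            cls, icer = "DOMINATED", None
        elif dc < 0:
            cls, icer = "DOMINANT", None
        else:
            cls, icer = "INDIFFERENT", None
    elif de > 0:
        if dc < 0:
            cls, icer = "DOMINANT", None
        else:  # dc == 0 is a degenerate trade-off with ICER 0
            cls, icer = "TRADEOFF_NE", dc / de
    else:  # de < 0
        if dc > 0:
            cls, icer = "DOMINATED", None
        else:
            cls, icer = "TRADEOFF_SW", dc / de
    return IncrementalResult(
        delta_cost=dc,
        delta_effect=de,
        classification=cls,
        icer=icer,
        effect_measure=effect_field,
    )


def net_monetary_benefit(cost: float, effect: float, wtp: float) -> float:
    """NMB = wtp * effect - cost."""
    if wtp < 0:
        raise ValueError(f"wtp must be non-negative, got {wtp!r}")
    return wtp * effect - cost


@dataclass(frozen=True)
class PSASampleSet:
    """Per-iteration arm-level (cost, effect, qaly) triples from a PSA.

    Both arms are evaluated on the *same* parameter draw in each iteration,
    so per-iteration differences are meaningful.
    """

    costs: dict  # arm -> np.ndarray
    effects: dict
    qalys: dict
    seed: int

    def __post_init__(self) -> None:
        arms = set(self.costs)
        if arms != {"SCT", "NO_SCT"} or set(self.effects) != arms or set(self.qalys) != arms:
            raise ValueError("sample set must carry both arms")
        n = {len(v) for d in (self.costs, self.effects, self.qalys) for v in d.values()}
        if len(n) != 1:
            raise ValueError("all arms must have identical iteration counts")

    @property
    def iterations(self) -> int:
        return len(self.costs["SCT"])

    def deltas(self, effect_field: str = "effect") -> tuple[np.ndarray, np.ndarray]:
        """(delta_effect, delta_cost) arrays, intervention minus comparator."""
        if effect_field not in ("effect", "qaly"):
            raise ValueError(f"bad effect_field {effect_field!r}")
        eff = self.effects if effect_field == "effect" else self.qalys
        de = np.asarray(eff["SCT"]) - np.asarray(eff["NO_SCT"])
        dc = np.asarray(self.costs["SCT"]) - np.asarray(self.costs["NO_SCT"])
        return de, dc

    def to_frame(self):
        import pandas as pd

        rows = []
        for arm in ("SCT", "NO_SCT"):
            rows.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.iterations),
                        "arm": arm,
                        "cost": self.costs[arm],
                        "effect": self.effects[arm],
                        "qaly": self.qalys[arm],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class QuadrantSummary:
    """CE-plane quadrant probabilities (x = delta effect, y = delta cost)."""

    p_NE: float
    p_NW: float
    p_SE: float
    p_SW: float

    def to_dict(self) -> dict:
        return {"p_NE": self.p_NE, "p_NW": self.p_NW, "p_SE": self.p_SE, "p_SW": self.p_SW}


def quadrant_probabilities(samples: PSASampleSet, effect_field: str = "effect") -> QuadrantSummary:
    """Fraction of PSA iterations falling in each CE-plane quadrant.

    Boundary points (a zero delta) are measure-zero under continuous
    sampling; for determinism they are assigned to the quadrant that follows
    clockwise, starting from NE: the +dC axis counts as NE, the +dE axis as
    SE, the -dC axis as SW, the -dE axis as NW, and the origin as NE.
    """
    if samples.iterations < 1:
        raise ValueError("need at least one PSA iteration")
    de, dc = samples.deltas(effect_field)
    ne = (de > 0) & (dc > 0) | (de == 0) & (dc > 0) | (de == 0) & (dc == 0)
    se = (de > 0) & (dc < 0) | (de > 0) & (dc == 0)
    sw = (de < 0) & (dc < 0) | (de == 0) & (dc < 0)
    nw = (de < 0) & (dc > 0) | (de < 0) & (dc == 0)
    n = samples.iterations
    return QuadrantSummary(
        p_NE=float(ne.sum()) / n,
        p_NW=float(nw.sum()) / n,
        p_SE=float(se.sum()) / n,
        p_SW=float(sw.sum()) / n,
    )


@dataclass(frozen=True)
class CEACurve:
    """Probability that the intervention is cost-effective per WTP value."""

    wtp_grid: np.ndarray
    probability_cost_effective: np.ndarray
    effect_measure: str = "effect"

    def __post_init__(self) -> None:
        grid = np.asarray(self.wtp_grid, dtype=float)
        prob = np.asarray(self.probability_cost_effective, dtype=float)
        if grid.ndim != 1 or len(grid) == 0:
            raise ValueError("wtp grid must be a non-empty 1-d array")
        if (np.diff(grid) <= 0).any():
            raise ValueError("wtp grid must be strictly increasing")
        if (grid < 0).any():
            raise ValueError("wtp values must be non-negative")
        if prob.shape != grid.shape or (prob < 0).any() or (prob > 1).any():
            raise ValueError("probabilities must align with the grid and lie in [0, 1]")
        object.__setattr__(self, "wtp_grid", grid)
        object.__setattr__(self, "probability_cost_effective", prob)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"wtp": self.wtp_grid, "probability_cost_effective": self.probability_cost_effective}
        )


def default_wtp_grid(maximum: float = 1000.0, step: float = 10.0) -> np.ndarray:
    """WTP grid 0..maximum in the given step (US$ per health effect)."""
    n = int(math.floor(maximum / step)) + 1
    return np.arange(n) * step


def compute_ceac(
    samples: PSASampleSet,
    wtp_grid,
    effect_field: str = "effect",
) -> CEACurve:
    """CEAC: at each WTP value, the fraction of iterations where the
    intervention's net monetary benefit strictly exceeds the comparator's
    (ties count against the intervention).

    At lambda = 0 this reduces to the probability of being cost-saving.
    """
    if samples.iterations < 1:
        raise ValueError("need at least one PSA iteration")
    de, dc = samples.deltas(effect_field)
    grid = np.asarray(wtp_grid, dtype=float)
    # NMB(int) > NMB(comp)  <=>  lambda * dE - dC > 0
    prob = np.array([(lam * de - dc > 0).mean() for lam in grid])
    return CEACurve(wtp_grid=grid, probability_cost_effective=prob, effect_measure=effect_field)
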