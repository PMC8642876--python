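"""Decision tree + three-state Markov cohort engine.

Structure: a chance node (quit smoking or not — SCT raises the quit
probability) feeds one of two smoking strata (FORMER / CURRENT), each a
Markov cohort over three tooth states evaluated in annual cycles:

* ``MAINTENANCE``   — tooth retained, patient in periodontal maintenance;
* ``LOST_NO_REHAB`` — tooth lost, no prosthetic rehabilitation;
* ``LOST_REHAB``    — tooth lost, rehabilitated (partial prosthesis, or
  implant in the scenario analysis).

One tooth per patient is modelled, so the LOST states are absorbing and
there is no smoking relapse (the quit draw happens once, up front).

Reward conventions (end-of-cycle accrual): per-cycle costs, utilities and
the tooth-retained effect indicator are earned on end-of-cycle occupancy and
discounted by ``(1+r)^-t`` with t the 1-based cycle index; one-off
extraction/rehabilitation costs are earned on the transition flux into the
LOST states in the cycle the loss occurs; upfront treatment costs fall at
t = 0 undiscounted.  An optional half-cycle correction instead credits
state rewards on the average of begin- and end-of-cycle occupancy at
discount exponent t - 1/2 (transition-flux event costs are unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelInputs, apply_relative_risk

__all__ = [
    "STATES",
    "MAINTENANCE",
    "LOST_NO_REHAB",
    "LOST_REHAB",
    "Stratum",
    "TransitionMatrix",
    "RewardSpec",
    "CohortTrace",
    "ArmResult",
    "build_transition_matrix",
    "discount_factor",
    "run_cohort_trace",
    "build_rewards",
    "arm_expected_values",
]

#: ordered state labels; the order is part of the contract
STATES = ("MAINTENANCE", "LOST_NO_REHAB", "LOST_REHAB")
MAINTENANCE, LOST_NO_REHAB, LOST_REHAB = range(3)

ARMS = ("SCT", "NO_SCT")
SMOKING_STATUSES = ("FORMER", "CURRENT")


@dataclass(frozen=True)
class Stratum:
    smoking_status: str  # FORMER | CURRENT
    arm: str  # SCT | NO_SCT

    def __post_init__(self) -> None:
        if self.smoking_status not in SMOKING_STATUSES:
            raise ValueError(f"bad smoking_status {self.smoking_status!r}")
        if self.arm not in ARMS:
            raise ValueError(f"bad arm {self.arm!r}")


@dataclass(frozen=True)
class TransitionMatrix:
    """3x3 annual transition probabilities, rows indexed by source state."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"transition matrix must be 3x3, got {m.shape}")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsums = m.sum(axis=1)
        if not np.allclose(rowsums, 1.0, rtol=0.0, atol=1e-12):
            raise ValueError(f"rows must sum to 1, got {rowsums}")
        # one tooth per patient: lost states are absorbing
        if not (m[LOST_NO_REHAB] == np.eye(3)[LOST_NO_REHAB]).all():
            raise ValueError("LOST_NO_REHAB row must be absorbing")
        if not (m[LOST_REHAB] == np.eye(3)[LOST_REHAB]).all():
            raise ValueError("LOST_REHAB row must be absorbing")
        object.__setattr__(self, "entries", m)


def build_transition_matrix(p_loss: float, p_no_rehab: float) -> TransitionMatrix:
    """Annual transitions out of MAINTENANCE.

    A tooth is lost with probability ``p_loss``; a lost tooth goes
    unrehabilitated with probability ``p_no_rehab``, otherwise it is
    rehabilitated.  The two LOST states are absorbing.
    """
    for name, p in (("p_loss", p_loss), ("p_no_rehab", p_no_rehab)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p!r}")
    m = np.eye(3)
    m[MAINTENANCE] = [
        1.0 - p_loss,
        p_loss * p_no_rehab,
        p_loss * (1.0 - p_no_rehab),
    ]
    return TransitionMatrix(m)


def discount_factor(rate: float, cycle_index: float) -> float:
    """``1 / (1 + rate)**t``; cycle 0 is undiscounted."""
    if rate <= -1.0:
        raise ValueError(f"rate must exceed -1, got {rate!r}")
    return float((1.0 + rate) ** -cycle_index)


@dataclass(frozen=True)
class RewardSpec:
    """Rewards attached to states, transitions and model entry for one stratum."""

    upfront_cost: float
    per_cycle_cost: np.ndarray  # by state
    per_event_cost: np.ndarray  # by destination state (index 0 unused)
    per_cycle_utility: np.ndarray  # by state; MAINTENANCE entry used from cycle 2 on
    first_cycle_maintenance_utility: float  # post-treatment utility, cycle 1 only
    per_cycle_effect: np.ndarray  # by state (tooth-retained indicator)

    def __post_init__(self) -> None:
        for name in ("per_cycle_cost", "per_event_cost", "per_cycle_utility", "per_cycle_effect"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if (self.per_cycle_utility < 0).any() or (self.per_cycle_utility > 1).any():
            raise ValueError("utilities must lie in [0, 1]")
        if not 0.0 <= self.first_cycle_maintenance_utility <= 1.0:
            raise ValueError("first-cycle utility must lie in [0, 1]")
        if self.upfront_cost < 0 or (self.per_cycle_cost < 0).any() or (self.per_event_cost < 0).any():
            raise ValueError("costs must be non-negative")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and discounted accruals for one stratum cohort."""

    occupancy: np.ndarray  # (horizon+1, 3), row 0 = initial distribution
    cycle_costs: np.ndarray  # (horizon+1,), index 0 holds the upfront cost
    cycle_effects: np.ndarray
    cycle_qalys: np.ndarray
    expected_cost: float
    expected_effect: float
    expected_qaly: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cycle": np.arange(self.occupancy.shape[0]),
                **{f"occ_{s}": self.occupancy[:, i] for i, s in enumerate(STATES)},
                "disc_cost": self.cycle_costs,
                "disc_effect": self.cycle_effects,
                "disc_qaly": self.cycle_qalys,
            }
        )


@dataclass(frozen=True)
class ArmResult:
    arm: str
    expected_cost: float
    expected_effect: float
    expected_qaly: float

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "expected_cost": self.expected_cost,
            "expected_effect": self.expected_effect,
            "expected_qaly": self.expected_qaly,
        }


def run_cohort_trace(
    matrix: TransitionMatrix,
    rewards: RewardSpec,
    horizon_cycles: int,
    rate: float,
    discount_effects: bool = True,
    half_cycle_correction: bool = False,
) -> CohortTrace:
    """Propagate a cohort starting fully in MAINTENANCE and accrue rewards.

    Costs are always discounted; effects and QALYs are discounted unless
    ``discount_effects`` is False.  See the module docstring for the accrual
    conventions.
    """
    if horizon_cycles < 0:
        raise ValueError("horizon_cycles must be >= 0")
    T = int(horizon_cycles)
    m = matrix.entries
    occ = np.zeros((T + 1, 3))
    occ[0, MAINTENANCE] = 1.0
    costs = np.zeros(T + 1)
    effects = np.zeros(T + 1)
    qalys = np.zeros(T + 1)
    costs[0] = rewards.upfront_cost

    for t in range(1, T + 1):
        prev = occ[t - 1]
        occ[t] = prev @ m
        # flux into the absorbing states this cycle (from MAINTENANCE only)
        flux = prev[MAINTENANCE] * m[MAINTENANCE]
        event_cost = (
            flux[LOST_NO_REHAB] * rewards.per_event_cost[LOST_NO_REHAB]
            + flux[LOST_REHAB] * rewards.per_event_cost[LOST_REHAB]
        )
        util = rewards.per_cycle_utility.copy()
        if t == 1:
            util[MAINTENANCE] = rewards.first_cycle_maintenance_utility
        if half_cycle_correction:
            occ_reward = 0.5 * (prev + occ[t])
            df_state = discount_factor(rate, t - 0.5)
        else:
            occ_reward = occ[t]
            df_state = discount_factor(rate, t)
        df_event = discount_factor(rate, t)
        df_eff = df_state if discount_effects else 1.0
        costs[t] = df_event * event_cost + df_state * occ_reward @ rewards.per_cycle_cost
        effects[t] = df_eff * occ_reward @ rewards.per_cycle_effect
        qalys[t] = df_eff * occ_reward @ util

    return CohortTrace(
        occupancy=occ,
        cycle_costs=costs,
        cycle_effects=effects,
        cycle_qalys=qalys,
        expected_cost=float(costs.sum()),
        expected_effect=float(effects.sum()),
        expected_qaly=float(qalys.sum()),
    )


def build_rewards(inputs: ModelInputs, smoking_status: str, upfront_cost: float = 0.0) -> RewardSpec:
    """Stratum rewards: maintenance cost by smoking status in every state
    (remaining teeth stay in maintenance after a loss), one-off
    extraction/rehabilitation costs on entry to the LOST states."""
    maint_cost = (
        inputs.cost_maintenance_former
        if smoking_status == "FORMER"
        else inputs.cost_maintenance_current
    )
    return RewardSpec(
        upfront_cost=upfront_cost,
        per_cycle_cost=np.full(3, maint_cost),
        per_event_cost=np.array(
            [0.0, inputs.cost_extraction_no_rehab, inputs.cost_extraction_rehab]
        ),
        per_cycle_utility=np.array(
            [inputs.u_maintenance, inputs.u_lost_no_rehab, inputs.u_lost_rehab]
        ),
        first_cycle_maintenance_utility=inputs.u_after_treatment,
        per_cycle_effect=np.array([1.0, 0.0, 0.0]),
    )


def run_stratum(inputs: ModelInputs, smoking_status: str) -> CohortTrace:
    """Cohort trace for one smoking stratum, without arm-level upfront costs."""
    p_loss = apply_relative_risk(
        inputs.p_loss_nonsmoker,
        inputs.rr_former if smoking_status == "FORMER" else inputs.rr_current,
    )
    matrix = build_transition_matrix(p_loss, inputs.p_no_rehab)
    rewards = build_rewards(inputs, smoking_status)
    return run_cohort_trace(
        matrix,
        rewards,
        inputs.horizon_cycles,
        inputs.discount_rate,
        discount_effects=inputs.discount_effects,
        half_cycle_correction=inputs.half_cycle_correction,
    )


def arm_expected_values(inputs: ModelInputs, arm: str) -> ArmResult:
    """Roll back the decision tree for one arm.

    The arm's quit probability mixes the FORMER and CURRENT stratum cohorts;
    both arms pay the periodontal-treatment upfront cost and the SCT arm
    additionally pays the smoking-cessation-therapy cost at t = 0.
    """
    if arm not in ARMS:
        raise ValueError(f"bad arm {arm!r}")
    if not isinstance(inputs, ModelInputs):  # accept a full ParameterSet too
        inputs = inputs.to_model_inputs()
    p_quit = inputs.p_quit_sct if arm == "SCT" else inputs.p_quit_no_sct
    former = run_stratum(inputs, "FORMER")
    current = run_stratum(inputs, "CURRENT")
    upfront = inputs.cost_periodontal + (inputs.cost_sct if arm == "SCT" else 0.0)
    cost = upfront + p_quit * former.expected_cost + (1 - p_quit) * current.expected_cost
    effect = p_quit * former.expected_effect + (1 - p_quit) * current.expected_effect
    qaly = p_quit * former.expected_qaly + (1 - p_quit) * current.expected_qaly
    return ArmResult(arm=arm, expected_cost=cost, expected_effect=effect, expected_qaly=qaly)
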