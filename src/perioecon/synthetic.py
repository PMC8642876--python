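"""Random parameter sets and individual-level patient trajectories.

The microsimulation re-expresses the cohort model at the individual level:
each simulated patient draws quit-or-not once at entry (no smoking relapse),
then walks the three tooth states cycle by cycle with Bernoulli transitions,
accruing exactly the same upfront / per-cycle / per-event rewards and
discounting conventions as the cohort engine.  By the law of large numbers
its sample means converge to the cohort expectations, which makes it an
independent oracle for the deterministic engine.

Random-stream contract: patient ``i``'s draws depend only on ``(seed, i)``
(one row of uniforms per patient, laid out row-major), so enlarging ``n``
extends the population without reshuffling earlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import ARMS, LOST_NO_REHAB, LOST_REHAB, MAINTENANCE, STATES
from .params import ModelInputs, ParameterSet, ProbabilityParam, RelativeRisk, \
    CostItem, UtilityParam, aggregate_cost, validate_parameter_set

__all__ = [
    "MicrosimResult",
    "microsimulate_arm",
    "generate_parameter_set",
    "generate_model_inputs",
]


@dataclass(frozen=True)
class MicrosimResult:
    """Sample means (with standard errors) of accrued cost/effect/QALY."""

    arm: str
    n_patients: int
    seed: int
    mean_cost: float
    mean_effect: float
    mean_qaly: float
    se_cost: float
    se_effect: float
    se_qaly: float
    quit_fraction: float
    records: "object"  # capped pandas DataFrame of individual trajectories

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "n_patients": self.n_patients,
            "seed": self.seed,
            "mean_cost": self.mean_cost,
            "mean_effect": self.mean_effect,
            "mean_qaly": self.mean_qaly,
            "se_cost": self.se_cost,
            "se_effect": self.se_effect,
            "se_qaly": self.se_qaly,
            "quit_fraction": self.quit_fraction,
        }


def microsimulate_arm(
    inputs: ModelInputs | ParameterSet,
    arm: str,
    n_patients: int,
    seed: int,
    max_records: int = 10_000,
) -> MicrosimResult:
    """Simulate ``n_patients`` individual trajectories through one arm.

    Uniform draws are laid out one row per patient (columns: quit draw,
    one transition draw per cycle, rehabilitation draw), so results for
    patient ``i`` depend only on ``(seed, i)`` and the horizon.  Summaries
    are over all ``n_patients``; at most ``max_records`` full trajectories
    are materialised in the returned record table.
    """
    import pandas as pd

    if arm not in ARMS:
        raise ValueError(f"bad arm {arm!r}")
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if isinstance(inputs, ParameterSet):
        inputs = inputs.to_model_inputs()
    T = inputs.horizon_cycles
    rng = np.random.default_rng(seed)
    u = rng.random((n_patients, T + 2))

    p_quit = inputs.p_quit_sct if arm == "SCT" else inputs.p_quit_no_sct
    quit = u[:, 0] < p_quit
    p_loss = np.where(quit, inputs.p_loss("FORMER"), inputs.p_loss("CURRENT"))
    maint_cost = np.where(
        quit, inputs.cost_maintenance_former, inputs.cost_maintenance_current
    )
    # rehabilitation decision is latent until a loss occurs
    lost_dest = np.where(u[:, T + 1] < inputs.p_no_rehab, LOST_NO_REHAB, LOST_REHAB)
    event_cost_by_dest = np.array(
        [0.0, inputs.cost_extraction_no_rehab, inputs.cost_extraction_rehab]
    )
    util_by_state = np.array(
        [inputs.u_maintenance, inputs.u_lost_no_rehab, inputs.u_lost_rehab]
    )
    effect_by_state = np.array([1.0, 0.0, 0.0])

    upfront = inputs.cost_periodontal + (inputs.cost_sct if arm == "SCT" else 0.0)
    cost = np.full(n_patients, upfront)
    effect = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    state = np.zeros(n_patients, dtype=np.int8)
    loss_cycle = np.zeros(n_patients, dtype=np.int32)  # 0 = never lost

    rate = inputs.discount_rate
    hcc = inputs.half_cycle_correction
    for t in range(1, T + 1):
        in_maint = state == MAINTENANCE
        lose = in_maint & (u[:, t] < p_loss)
        new_state = np.where(lose, lost_dest, state).astype(np.int8)
        loss_cycle[lose] = t

        util_t = util_by_state.copy()
        if t == 1:
            util_t[MAINTENANCE] = inputs.u_after_treatment
        df_event = (1.0 + rate) ** -t
        df_state = (1.0 + rate) ** -(t - 0.5) if hcc else df_event
        df_eff = df_state if inputs.discount_effects else 1.0

        cost += df_event * event_cost_by_dest[lost_dest] * lose
        if hcc:
            eff_t = 0.5 * (effect_by_state[state] + effect_by_state[new_state])
            q_t = 0.5 * (util_t[state] + util_t[new_state])
        else:
            eff_t = effect_by_state[new_state]
            q_t = util_t[new_state]
        cost += df_state * maint_cost  # same in every state: maintenance continues
        effect += df_eff * eff_t
        qaly += df_eff * q_t
        state = new_state

    def sem(x):
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    k = min(max_records, n_patients)
    records = pd.DataFrame(
        {
            "patient_id": np.arange(k),
            "arm": arm,
            "quit": quit[:k],
            "final_state": [STATES[s] for s in state[:k]],
            "loss_cycle": loss_cycle[:k],
            "accrued_cost": cost[:k],
            "accrued_effect": effect[:k],
            "accrued_qaly": qaly[:k],
        }
    )
    return MicrosimResult(
        arm=arm,
        n_patients=n_patients,
        seed=seed,
        mean_cost=float(cost.mean()),
        mean_effect=float(effect.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=sem(cost),
        se_effect=sem(effect),
        se_qaly=sem(qaly),
        quit_fraction=float(quit.mean()),
        records=records,
    )


# ---------------------------------------------------------------------------
# random valid parameter sets
# ---------------------------------------------------------------------------

#: default sampling bounds for random parameter sets (PPP-US$ / probability
#: scales), mirroring the deterministic sensitivity ranges of the base case
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "cost_sct": (185.86, 525.59),
    "cost_periodontal": (174.82, 213.68),
    "cost_maintenance_current": (94.80, 115.86),
    "cost_maintenance_former": (47.39, 57.93),
    "cost_extraction_no_rehab": (12.56, 15.35),
    "cost_extraction_rehab": (128.02, 156.46),
    "discount_rate": (0.03, 0.07),
    "p_quit_sct": (0.16, 0.38),
    "p_quit_no_sct": (0.05, 0.10),
    "p_loss_nonsmoker": (0.0003, 0.006),
    "p_no_rehab": (0.07, 0.41),
    "u_after_treatment": (0.76, 0.96),
    "u_maintenance": (0.85, 0.98),
    "u_lost_no_rehab": (0.55, 0.67),
    "u_lost_rehab": (0.62, 0.76),
    "rr_former": (0.98, 1.35),
    "rr_current": (2.29, 2.96),
}


def generate_model_inputs(
    seed: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    horizon_cycles: int = 30,
) -> ModelInputs:
    """Draw flat engine inputs uniformly within per-parameter bounds.

    Degenerate bounds (min == max) return the bound exactly.  Bounds that
    can never produce a valid probability (RR x p > 1 even at the lower
    corners) raise; otherwise invalid draws are rejected and redrawn.
    Unlisted parameters stay at the base case.
    """
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    rr_lo = ranges.get("rr_current", (1.0, 1.0))[0]
    p_lo = ranges.get("p_loss_nonsmoker", (0.0, 0.0))[0]
    if rr_lo * p_lo > 1.0:
        raise ValueError("infeasible bounds: RR x p exceeds 1 everywhere")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        flat = {k: float(rng.uniform(lo, hi)) if lo < hi else float(lo)
                for k, (lo, hi) in ranges.items()}
        base = dict(
            p_quit_sct=0.3, p_quit_no_sct=0.07, p_loss_nonsmoker=0.003,
            p_no_rehab=0.09, rr_former=1.15, rr_current=2.16,
            cost_sct=227.41, cost_periodontal=194.25,
            cost_maintenance_former=52.66, cost_maintenance_current=105.33,
            cost_extraction_no_rehab=13.95, cost_extraction_rehab=142.24,
            u_after_treatment=0.86, u_maintenance=0.93,
            u_lost_no_rehab=0.61, u_lost_rehab=0.69, u_periodontitis=0.76,
            discount_rate=0.05, horizon_cycles=horizon_cycles,
        )
        base.update(flat)
        candidate = ModelInputs(**base)
        try:
            candidate.p_loss("FORMER")
            candidate.p_loss("CURRENT")
        except ValueError:
            continue
        return candidate
    raise ValueError("infeasible bounds: no valid draw in 1000 attempts")


def generate_parameter_set(
    seed: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    horizon_cycles: int = 30,
) -> ParameterSet:
    """A full random :class:`ParameterSet` passing validation.

    Flat values are drawn via :func:`generate_model_inputs` and wrapped in
    single-item PPP-US$ cost bundles (the itemised R$ decomposition only
    exists for the printed base case).
    """
    mi = generate_model_inputs(seed, ranges, horizon_cycles)

    def bundle(label: str, usd: float):
        return aggregate_cost([CostItem(label=label, amount=usd, currency="USD-PPP")])

    ps = ParameterSet(
        probabilities={
            "quit_with_sct": ProbabilityParam(mi.p_quit_sct, label="quit with SCT"),
            "quit_without_sct": ProbabilityParam(mi.p_quit_no_sct, label="quit without SCT"),
            "toothloss_nonsmokers": ProbabilityParam(
                mi.p_loss_nonsmoker, label="annual tooth loss, non-smokers"
            ),
            "no_rehab": ProbabilityParam(mi.p_no_rehab, label="no rehabilitation"),
        },
        relative_risks={
            "former": RelativeRisk(mi.rr_former, label="former smokers"),
            "current": RelativeRisk(mi.rr_current, label="current smokers"),
        },
        costs={
            "sct": bundle("smoking cessation therapy", mi.cost_sct),
            "periodontal_treatment": bundle("periodontal treatment", mi.cost_periodontal),
            "maintenance_former": bundle("maintenance, former", mi.cost_maintenance_former),
            "maintenance_current": bundle("maintenance, current", mi.cost_maintenance_current),
            "extraction_no_rehab": bundle("extraction only", mi.cost_extraction_no_rehab),
            "extraction_partial_prosthesis": bundle(
                "extraction + partial prosthesis", mi.cost_extraction_rehab
            ),
            "extraction_implant": bundle("extraction + implant", mi.cost_extraction_rehab),
        },
        utilities={
            "periodontitis": UtilityParam(mi.u_periodontitis),
            "after_periodontal_treatment": UtilityParam(mi.u_after_treatment),
            "maintenance": UtilityParam(mi.u_maintenance),
            "lost_no_rehab": UtilityParam(mi.u_lost_no_rehab),
            "lost_partial_prosthesis": UtilityParam(mi.u_lost_rehab),
        },
        discount_rate=mi.discount_rate,
        horizon_cycles=horizon_cycles,
        ppp_rate=1.0,
    )
    issues = [i for i in validate_parameter_set(ps) if i.severity == "error"]
    if issues:  # pragma: no cover - construction should already have raised
        raise ValueError(f"generated parameter set failed validation: {issues}")
    return ps
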