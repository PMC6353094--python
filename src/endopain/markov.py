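"""Monthly Markov cohort engine with mortality overlay and accrual.

One arm of the model is a 5-state cohort simulation run in monthly cycles
from age 32 to 50: occupancy is propagated through a row-stochastic
transition matrix whose pain transitions come from the arm's elicited
probabilities and whose death probability comes from an annual life table
(converted to a monthly rate and applied uniformly from every alive state,
since the disease itself carries no excess mortality).  Costs and QALYs are
accrued per cycle on half-cycle-corrected occupancy and discounted at an
annual rate compounded monthly.  A patient-level microsimulation of the
same process serves as an independent cross-check of the cohort totals.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import CostSpec, LifeTable, ModelConfig, ParameterSet
from .states import ALIVE_STATES, N_ALIVE, N_STATES, STATES

_ROW_TOL = 1e-12


class EngineError(RuntimeError):
    """An invariant was violated while running the cohort."""


@dataclass(frozen=True)
class ArmParameters:
    """Everything the engine needs for one arm.

    Monthly cost vectors are per alive state; the alive transition matrix is
    4x4 and row-stochastic before the mortality overlay.
    """

    arm: str
    alive_matrix: np.ndarray
    utilities: np.ndarray          # annual QALY weight per alive state
    gp_visit_cost: float
    gp_interval: int               # months between GP visits
    drug_monthly: np.ndarray       # per alive state
    analgesic_monthly: np.ndarray  # per alive state
    gp_lumped: bool = False
    cost_mask: np.ndarray = field(default_factory=lambda: np.ones(N_ALIVE))

    def __post_init__(self) -> None:
        M = np.asarray(self.alive_matrix, dtype=float)
        if M.shape != (N_ALIVE, N_ALIVE):
            raise ValueError("alive transition matrix must be 4x4")
        if (M < -_ROW_TOL).any() or (M > 1 + _ROW_TOL).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("alive transition rows must sum to 1")
        if np.asarray(self.utilities).shape != (N_ALIVE,):
            raise ValueError("need one utility per alive state")

    def gp_monthly(self) -> np.ndarray:
        """Amortised GP cost per month and alive state."""
        return self.gp_visit_cost / self.gp_interval * self.cost_mask

    def state_monthly_cost(self) -> np.ndarray:
        """Total monthly cost per alive state under amortised GP visits."""
        return self.gp_monthly() + self.drug_monthly + self.analgesic_monthly


def make_arm_parameters(
    ps: ParameterSet,
    arm: str,
    *,
    utilities: np.ndarray | None = None,
    alive_matrix: np.ndarray | None = None,
    gp_visit_cost: float | None = None,
    oc_pack_cost: float | None = None,
    exclude_gp: bool = False,
) -> ArmParameters:
    """Assemble arm inputs from a parameter set, with optional overrides.

    Overrides exist so the probabilistic sensitivity analysis can inject
    sampled utilities, transition rows and unit costs, and so the one-way
    scenario can zero out GP consultations.
    """
    costs = ps.costs
    mask = np.array([0.0, 1.0, 1.0, 1.0]) if costs.pain_states_only else np.ones(N_ALIVE)
    gp_cost = costs.gp_visit_cost if gp_visit_cost is None else gp_visit_cost
    if exclude_gp:
        gp_cost = 0.0
    pack = costs.oc_pack_cost if oc_pack_cost is None else oc_pack_cost
    drug = np.zeros(N_ALIVE)
    if arm == "oc":
        drug = pack / costs.oc_pack_cycles * mask
    return ArmParameters(
        arm=arm,
        alive_matrix=(
            ps.transitions.matrix(arm) if alive_matrix is None else alive_matrix
        ),
        utilities=(
            ps.utilities.as_array() if utilities is None else np.asarray(utilities)
        ),
        gp_visit_cost=gp_cost,
        gp_interval=costs.gp_interval(arm),
        drug_monthly=drug,
        analgesic_monthly=costs.analgesic_monthly(),
        gp_lumped=costs.gp_lumped,
        cost_mask=mask,
    )


def discount_factor(cycle: int | np.ndarray, annual_rate: float) -> float | np.ndarray:
    """Discount factor (1 + r)^(-cycle/12) for a monthly cycle index."""
    if annual_rate < 0:
        raise ValueError("annual discount rate must be >= 0")
    if np.any(np.asarray(cycle) < 0):
        raise ValueError("cycle index must be >= 0")
    return (1.0 + annual_rate) ** (-np.asarray(cycle, dtype=float) / 12.0)


def build_matrix(params: ArmParameters, q_monthly: float) -> np.ndarray:
    """5x5 monthly matrix: pain transitions scaled by survival, dead absorbing.

    The monthly death probability applies identically from every alive state;
    the remaining (1 - q) mass follows the arm's pain transitions.
    """
    if not 0.0 <= q_monthly <= 1.0:
        raise ValueError("monthly death probability must lie in [0, 1]")
    M = np.zeros((N_STATES, N_STATES))
    M[:N_ALIVE, :N_ALIVE] = params.alive_matrix * (1.0 - q_monthly)
    M[:N_ALIVE, N_ALIVE] = q_monthly
    M[N_ALIVE, N_ALIVE] = 1.0
    rows = M.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-9):
        raise EngineError(f"matrix rows sum to {rows}, expected 1")
    return M


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and accrual for one arm."""

    arm: str
    ages: np.ndarray               # age at the start of each cycle (T,)
    occupancy: np.ndarray          # (T+1, 5) state fractions at cycle starts
    effective: np.ndarray          # (T, 5) accrual occupancy (half-cycle corrected)
    discount: np.ndarray           # (T,) discount factor per cycle
    cost_components: dict[str, np.ndarray]  # per-cycle discounted cost by component
    qaly_per_cycle: np.ndarray     # (T,) discounted QALY accrual

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per cycle and state."""
        T = len(self.ages)
        cost_cycle = sum(self.cost_components.values())
        rows = []
        for t in range(T):
            for j, s in enumerate(STATES):
                rows.append(
                    {
                        "cycle": t,
                        "age": self.ages[t],
                        "state": s,
                        "occupancy": self.occupancy[t, j],
                        "effective_occupancy": self.effective[t, j],
                        "discount_factor": self.discount[t],
                        "cost_accrued": cost_cycle[t] if j == 0 else 0.0,
                        "qaly_accrued": self.qaly_per_cycle[t] if j == 0 else 0.0,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ArmResult:
    """Discounted and undiscounted totals for one arm."""

    arm: str
    cost: float
    qalys: float
    cost_undiscounted: float
    qalys_undiscounted: float
    cost_breakdown: dict[str, float]
    fingerprint: str = ""

    def __str__(self) -> str:
        return f"{self.arm}: £{self.cost:,.0f}, {self.qalys:.2f} QALYs"


def run_cohort(
    config: ModelConfig, params: ArmParameters, life: LifeTable
) -> tuple[CohortTrace, ArmResult]:
    """Propagate the cohort and accrue discounted costs and QALYs.

    Occupancy advances as occ(t+1) = occ(t) @ M(age_t), with the transition
    matrix rebuilt once per model year from the life table.  With half-cycle
    correction on, accrual in cycle t uses the mean of the start- and
    end-of-cycle occupancies.  QALYs accrue at utility/12 per month; costs
    follow the arm's monthly vectors, with GP visits either amortised per
    month (default) or charged as a lump in visit months.
    """
    T = config.n_cycles
    if not life.covers(config.start_age, config.end_age):
        raise EngineError("life table does not cover the model age span")
    occ = np.zeros((T + 1, N_STATES))
    occ[0] = config.initial_occupancy()
    ages = config.start_age + np.arange(T) // 12

    matrices = {}
    for t in range(T):
        age = int(ages[t])
        if age not in matrices:
            matrices[age] = build_matrix(params, life.monthly_q(age))
        occ[t + 1] = occ[t] @ matrices[age]
        if abs(occ[t + 1].sum() - 1.0) > 1e-9:
            raise EngineError(f"occupancy does not sum to 1 at cycle {t + 1}")

    eff = (occ[:-1] + occ[1:]) / 2.0 if config.half_cycle_correction else occ[:-1]
    disc = discount_factor(np.arange(T), config.annual_discount_rate)

    alive_eff = eff[:, :N_ALIVE]
    qaly_cycle_undisc = alive_eff @ (params.utilities / 12.0)
    qaly_cycle = qaly_cycle_undisc * disc

    comp_undisc: dict[str, np.ndarray] = {
        "analgesic": alive_eff @ params.analgesic_monthly,
        "drug": alive_eff @ params.drug_monthly,
    }
    if params.gp_lumped:
        gp = np.zeros(T)
        visit_cycles = (np.arange(1, T + 1) % params.gp_interval) == 0
        eligible = eff[:, :N_ALIVE] @ params.cost_mask
        gp[visit_cycles] = params.gp_visit_cost * eligible[visit_cycles]
        comp_undisc["gp"] = gp
    else:
        comp_undisc["gp"] = alive_eff @ params.gp_monthly()

    components = {k: v * disc for k, v in comp_undisc.items()}

    trace = CohortTrace(
        arm=params.arm,
        ages=ages,
        occupancy=occ,
        effective=eff,
        discount=disc,
        cost_components=components,
        qaly_per_cycle=qaly_cycle,
    )
    result = ArmResult(
        arm=params.arm,
        cost=float(sum(v.sum() for v in components.values())),
        qalys=float(qaly_cycle.sum()),
        cost_undiscounted=float(sum(v.sum() for v in comp_undisc.values())),
        qalys_undiscounted=float(qaly_cycle_undisc.sum()),
        cost_breakdown={k: float(v.sum()) for k, v in components.items()},
    )
    return trace, result


@dataclass(frozen=True)
class MicrosimResult:
    """Mean discounted totals from patient-level simulation, with SEs."""

    arm: str
    cost: float
    qalys: float
    cost_se: float
    qalys_se: float
    n_patients: int


def microsim_oracle(
    config: ModelConfig,
    params: ArmParameters,
    life: LifeTable,
    n_patients: int,
    seed: int | np.random.Generator = 0,
) -> MicrosimResult:
    """Patient-level re-implementation of the cohort run.

    Each patient follows monthly categorical transitions through the same
    matrices; per-cycle accrual mirrors the cohort conventions (half-cycle
    correction averages the start- and end-of-cycle state values).  Sample
    means estimate the cohort totals; standard errors quantify Monte-Carlo
    noise.  Deliberately independent of :func:`run_cohort`'s linear algebra.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = config.n_cycles

    init = config.initial_occupancy()
    states = rng.choice(N_STATES, size=n_patients, p=init)

    util_month = np.append(params.utilities / 12.0, 0.0)
    cost_month = np.append(params.state_monthly_cost(), 0.0)
    if params.gp_lumped:
        cost_month = np.append(
            params.drug_monthly + params.analgesic_monthly, 0.0
        )
        gp_eligible = np.append(params.cost_mask, 0.0)

    cost_acc = np.zeros(n_patients)
    qaly_acc = np.zeros(n_patients)

    cum_by_age: dict[int, np.ndarray] = {}
    for t in range(T):
        age = int(config.start_age + t // 12)
        if age not in cum_by_age:
            cum_by_age[age] = np.cumsum(
                build_matrix(params, life.monthly_q(age)), axis=1
            )
        cum = cum_by_age[age]
        u = rng.random(n_patients)
        new_states = np.empty_like(states)
        for s in range(N_STATES):
            idx = states == s
            if idx.any():
                new_states[idx] = np.searchsorted(cum[s], u[idx], side="right")
        np.clip(new_states, 0, N_STATES - 1, out=new_states)

        d = float(discount_factor(t, config.annual_discount_rate))
        if config.half_cycle_correction:
            q_val = (util_month[states] + util_month[new_states]) / 2.0
            c_val = (cost_month[states] + cost_month[new_states]) / 2.0
        else:
            q_val = util_month[states]
            c_val = cost_month[states]
        qaly_acc += q_val * d
        cost_acc += c_val * d
        if params.gp_lumped and (t + 1) % params.gp_interval == 0:
            if config.half_cycle_correction:
                elig = (gp_eligible[states] + gp_eligible[new_states]) / 2.0
            else:
                elig = gp_eligible[states]
            cost_acc += params.gp_visit_cost * elig * d
        states = new_states

    return MicrosimResult(
        arm=params.arm,
        cost=float(cost_acc.mean()),
        qalys=float(qaly_acc.mean()),
        cost_se=float(cost_acc.std(ddof=1) / np.sqrt(n_patients)),
        qalys_se=float(qaly_acc.std(ddof=1) / np.sqrt(n_patients)),
        n_patients=n_patients,
    )
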