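"""Deterministic economics: incremental comparison, ICER, NMB, one-way SA.

The intervention is the oral-contraceptive arm and the comparator the
no-hormonal-treatment arm throughout.  When one strategy is both cheaper
and more effective the ICER is meaningless and a dominance verdict is
reported instead; negative ICERs are never printed.
"""
from __future__ import annotations

from dataclasses import dataclass

from .markov import ArmResult, make_arm_parameters, run_cohort
from .parameters import ParameterSet

#: Verdicts for the incremental comparison.
INTERVENTION_DOMINATES = "intervention_dominates"
COMPARATOR_DOMINATES = "comparator_dominates"
ICER_REPORTED = "icer_reported"
EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental cost and effect of the intervention over the comparator."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    verdict: str

    def __str__(self) -> str:
        icer = "n/a" if self.icer is None else f"£{self.icer:,.0f}/QALY"
        return (
            f"Δcost £{self.delta_cost:,.0f}, ΔQALY {self.delta_qalys:.2f}, "
            f"ICER {icer} ({self.verdict})"
        )


def compare(comparator: ArmResult, intervention: ArmResult) -> IncrementalResult:
    """Incremental comparison; intervention minus comparator.

    Verdict is a pure function of the signs of (ΔQALY, Δcost): cheaper and
    more effective is dominance; equal on both axes is equivalence; any
    other combination reports an ICER.
    """
    if comparator.fingerprint != intervention.fingerprint:
        raise ValueError(
            "arm results come from different model configurations "
            f"({comparator.fingerprint!r} vs {intervention.fingerprint!r})"
        )
    dc = intervention.cost - comparator.cost
    dq = intervention.qalys - comparator.qalys
    if dc == 0.0 and dq == 0.0:
        return IncrementalResult(0.0, 0.0, None, EQUIVALENT)
    if dq >= 0.0 and dc <= 0.0:
        return IncrementalResult(dc, dq, None, INTERVENTION_DOMINATES)
    if dq <= 0.0 and dc >= 0.0:
        return IncrementalResult(dc, dq, None, COMPARATOR_DOMINATES)
    return IncrementalResult(dc, dq, dc / dq, ICER_REPORTED)


def nmb(result: ArmResult, threshold: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold (GBP/QALY)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return threshold * result.qalys - result.cost


def run_base_case(ps: ParameterSet) -> tuple[ArmResult, ArmResult, IncrementalResult]:
    """Deterministic base case: both arms at the point estimates."""
    fp = ps.fingerprint()
    results = []
    for arm in ("nht", "oc"):
        _, res = run_cohort(ps.model, make_arm_parameters(ps, arm), ps.life_table)
        results.append(_stamp(res, fp))
    nht, oc = results
    return nht, oc, compare(nht, oc)


def one_way_sa_exclude_gp(
    ps: ParameterSet,
) -> tuple[ArmResult, ArmResult, IncrementalResult]:
    """Scenario with GP consultation costs removed from both arms.

    A cost-only perturbation: traces and hence QALY totals are identical to
    the base case.
    """
    fp = ps.fingerprint() + ":no_gp"
    results = []
    for arm in ("nht", "oc"):
        params = make_arm_parameters(ps, arm, exclude_gp=True)
        _, res = run_cohort(ps.model, params, ps.life_table)
        results.append(_stamp(res, fp))
    nht, oc = results
    return nht, oc, compare(nht, oc)


def _stamp(res: ArmResult, fingerprint: str) -> ArmResult:
    return ArmResult(
        arm=res.arm,
        cost=res.cost,
        qalys=res.qalys,
        cost_undiscounted=res.cost_undiscounted,
        qalys_undiscounted=res.qalys_undiscounted,
        cost_breakdown=res.cost_breakdown,
        fingerprint=fingerprint,
    )
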