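"""Probabilistic sensitivity analysis: joint sampling, CE plane, CEAC.

Each draw samples every uncertain input from its elicited distribution —
state utilities from Betas, transition rows from Betas (single destination)
or Dirichlets (two destinations, sampled jointly so the row still sums
to 1), and the GP and OC unit costs from Gammas with a fixed coefficient
of variation.  Utilities and the GP unit cost are state/service properties
rather than arm properties, so one value per draw is shared across both
arms.  Both arms are then evaluated through the cohort engine and the
incremental pair (ΔQALY, Δcost) is summarised on the cost-effectiveness
plane and as acceptability curves.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elicitation import (
    DistributionParams,
    TransitionCounts,
    fit_beta_from_counts,
    fit_dirichlet_from_counts,
    gamma_from_mean_cv,
)
from .markov import EngineError, make_arm_parameters, run_cohort
from .parameters import ARMS, ParameterSet
from .states import ALIVE_STATES, N_ALIVE

log = logging.getLogger(__name__)

#: Default willingness-to-pay grid (GBP/QALY): 0 to 50,000 in 1,000 steps,
#: plus a large sentinel standing in for "thresholds above £50,000".
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(range(0, 50_001, 1_000)) + (10.0**8,)


@dataclass(frozen=True)
class PSADistributions:
    """Sampling distributions for every uncertain input."""

    utilities: dict[str, DistributionParams]
    transition_rows: dict[tuple[str, str], tuple[DistributionParams, tuple[str, ...]]]
    gp_visit_cost: DistributionParams
    oc_pack_cost: DistributionParams


def build_distributions(ps: ParameterSet) -> PSADistributions:
    """Derive PSA distributions from the parameter set.

    Transition pseudo-counts are the elicited movers among ``pseudo_n``
    hypothetical patients; rows with one destination get a Beta, rows with
    several a Dirichlet over (stay, destinations...).  Unit costs with only
    a point estimate get Gammas with the configured CV; analgesic costs
    stay fixed.
    """
    utilities = {
        s: DistributionParams("Beta", tuple(ps.utilities.beta[s]))
        for s in ALIVE_STATES
    }
    rows: dict[tuple[str, str], tuple[DistributionParams, tuple[str, ...]]] = {}
    for arm in ARMS:
        for origin in ALIVE_STATES:
            stay, movers = ps.transitions.pseudo_counts(arm, origin)
            if not movers:
                continue
            dests = tuple(d for d, _ in movers)
            if len(movers) == 1:
                dist = fit_beta_from_counts(movers[0][1], ps.transitions.pseudo_n)
            else:
                dist = fit_dirichlet_from_counts(
                    TransitionCounts(
                        origin=origin,
                        n=ps.transitions.pseudo_n,
                        counts={d: k for d, k in movers},
                    )
                )
            rows[(arm, origin)] = (dist, dests)
    return PSADistributions(
        utilities=utilities,
        transition_rows=rows,
        gp_visit_cost=gamma_from_mean_cv(ps.costs.gp_visit_cost, ps.costs.cost_cv),
        oc_pack_cost=gamma_from_mean_cv(ps.costs.oc_pack_cost, ps.costs.cost_cv),
    )


@dataclass(frozen=True)
class ParameterDraw:
    """One joint sample of the uncertain inputs."""

    index: int
    utilities: np.ndarray                      # per alive state, shared by arms
    alive_matrices: dict[str, np.ndarray]      # 4x4 per arm
    gp_visit_cost: float
    oc_pack_cost: float


def sample_draw(
    dists: PSADistributions, rng: np.random.Generator, index: int = 0
) -> ParameterDraw:
    """Draw one parameter set; sampled rows always sum to 1."""
    utilities = np.array(
        [float(dists.utilities[s].sample(rng)) for s in ALIVE_STATES]
    )
    matrices: dict[str, np.ndarray] = {}
    for arm in ARMS:
        M = np.eye(N_ALIVE)
        for origin_i, origin in enumerate(ALIVE_STATES):
            key = (arm, origin)
            if key not in dists.transition_rows:
                continue
            dist, dests = dists.transition_rows[key]
            if dist.family == "Dirichlet":
                vec = dist.sample(rng)  # (stay, dest1, dest2, ...)
                M[origin_i, origin_i] = vec[0]
                for d, p in zip(dests, vec[1:]):
                    M[origin_i, ALIVE_STATES.index(d)] = p
            else:
                p = float(dist.sample(rng))
                M[origin_i, ALIVE_STATES.index(dests[0])] = p
                M[origin_i, origin_i] = 1.0 - p
        matrices[arm] = M
    return ParameterDraw(
        index=index,
        utilities=utilities,
        alive_matrices=matrices,
        gp_visit_cost=float(dists.gp_visit_cost.sample(rng)),
        oc_pack_cost=float(dists.oc_pack_cost.sample(rng)),
    )


@dataclass(frozen=True)
class PSAResult:
    """Draw-level incremental results plus plane and CEAC summaries."""

    draws: pd.DataFrame        # draw, cost_nht, qaly_nht, cost_oc, qaly_oc, delta_cost, delta_qaly, quadrant
    n_requested: int
    n_failed: int
    seed: int | None = None

    def quadrant_proportions(self) -> dict[str, float]:
        """Fractions of draws per CE-plane quadrant (ΔQALY on x, Δcost on y)."""
        n = len(self.draws)
        props = {
            q: float((self.draws["quadrant"] == q).sum()) / n
            for q in ("NE", "SE", "SW", "NW")
        }
        return props

    def ceac(self, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
        """P(each arm has maximal NMB) per threshold; ties split equally."""
        if len(self.draws) == 0:
            raise ValueError("PSA produced no successful draws")
        thresholds = np.asarray(thresholds, dtype=float)
        if (thresholds < 0).any():
            raise ValueError("thresholds must be >= 0")
        if (np.diff(thresholds) < 0).any():
            raise ValueError("thresholds must be sorted ascending")
        dq = self.draws["delta_qaly"].to_numpy()
        dc = self.draws["delta_cost"].to_numpy()
        rows = []
        for lam in thresholds:
            gain = lam * dq - dc  # NMB(OC) - NMB(NHT)
            p_oc = float((gain > 0).mean() + 0.5 * (gain == 0).mean())
            rows.append({"threshold": lam, "p_oc": p_oc, "p_nht": 1.0 - p_oc})
        return pd.DataFrame(rows)


def classify_quadrant(delta_qaly: float, delta_cost: float) -> str:
    """CE-plane quadrant; the SE quadrant is strictly more effective and cheaper."""
    if delta_qaly > 0:
        return "SE" if delta_cost < 0 else "NE"
    return "SW" if delta_cost < 0 else "NW"


def run_psa(
    ps: ParameterSet,
    n_draws: int | None = None,
    seed: int | None = None,
) -> PSAResult:
    """Sample, evaluate both arms per draw, and collect the CE plane.

    A draw whose cohort run violates an engine invariant is logged and
    excluded; the run continues.
    """
    n = ps.model.psa_draws if n_draws is None else n_draws
    if n < 1:
        raise ValueError("n_draws must be >= 1")
    used_seed = ps.model.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    dists = build_distributions(ps)

    records = []
    n_failed = 0
    for i in range(n):
        draw = sample_draw(dists, rng, index=i)
        try:
            rec: dict[str, float] = {"draw": i}
            for arm in ARMS:
                params = make_arm_parameters(
                    ps,
                    arm,
                    utilities=draw.utilities,
                    alive_matrix=draw.alive_matrices[arm],
                    gp_visit_cost=draw.gp_visit_cost,
                    oc_pack_cost=draw.oc_pack_cost,
                )
                _, res = run_cohort(ps.model, params, ps.life_table)
                rec[f"cost_{arm}"] = res.cost
                rec[f"qaly_{arm}"] = res.qalys
        except (EngineError, ValueError) as exc:
            n_failed += 1
            log.warning("PSA draw %d failed and was excluded: %s", i, exc)
            continue
        rec["delta_cost"] = rec["cost_oc"] - rec["cost_nht"]
        rec["delta_qaly"] = rec["qaly_oc"] - rec["qaly_nht"]
        rec["quadrant"] = classify_quadrant(rec["delta_qaly"], rec["delta_cost"])
        records.append(rec)
    if n_failed:
        log.warning("PSA: %d of %d draws failed and were excluded", n_failed, n)
    return PSAResult(
        draws=pd.DataFrame(records), n_requested=n, n_failed=n_failed, seed=used_seed
    )


def plot_ce_plane(result: PSAResult, path) -> None:
    """Scatter of the PSA draws: effect difference (x) vs cost difference (y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(
        result.draws["delta_qaly"], result.draws["delta_cost"], s=8, alpha=0.5
    )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs (OC − NHT)")
    ax.set_ylabel("Incremental cost, £ (OC − NHT)")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curves: pd.DataFrame, path) -> None:
    """Acceptability curves for both arms over the threshold grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = curves[curves["threshold"] < 10.0**7]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(finite["threshold"], finite["p_oc"], label="Oral contraceptives")
    ax.plot(finite["threshold"], finite["p_nht"], label="No hormonal treatment")
    ax.set_xlabel("Willingness-to-pay threshold, £/QALY")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    ax.set_title("Cost-effectiveness acceptability curves")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
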