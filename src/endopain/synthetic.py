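"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes that is not a
published parameter: a plausible female all-cause mortality life table
(Gompertz hazard, calibrated to the magnitude of UK national life tables
for women in their thirties and forties), elicited transition counts among
hypothetical patients, and roulette (chips-and-bins) histograms drawn from
a known Beta distribution.  Each generator's output feeds the same loaders
and fitting routines as real data, so parameter-recovery tests can compare
fitted values against the generating truth.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .elicitation import RouletteHistogram, TransitionCounts
from .parameters import LifeTable


@dataclass(frozen=True)
class GompertzSpec:
    """Gompertz mortality: hazard h0 * exp(slope * (age - reference_age)).

    Defaults give q_annual ~ 5e-4 at age 32 rising to ~2.3e-3 at age 50
    (cumulative mortality ~2% over ages 32-50), the order observed in UK
    female period life tables; illustrative, not an official table.
    """

    h0: float = 4.5e-4
    slope: float = 0.085
    reference_age: float = 30.0

    def __post_init__(self) -> None:
        if self.h0 <= 0:
            raise ValueError("baseline hazard h0 must be > 0")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")

    def q_annual(self, age: float) -> float:
        """Annual death probability from the integrated constant-in-year hazard."""
        h = self.h0 * np.exp(self.slope * (age - self.reference_age))
        return float(1.0 - np.exp(-h))


def make_life_table(spec: GompertzSpec, ages: Iterable[int]) -> LifeTable:
    """Evaluate a Gompertz spec on integer ages; q_annual increases with age."""
    ages = tuple(int(a) for a in ages)
    return LifeTable(ages=ages, q_annual=tuple(spec.q_annual(a) for a in ages))


def simulate_transition_counts(
    origin: str,
    true_probs: dict[str, float],
    n: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> TransitionCounts:
    """One month of transitions for ``n`` hypothetical patients.

    ``true_probs`` maps destination states to monthly probabilities; the
    remaining mass stays in ``origin``.  Destinations are drawn jointly
    (multinomially), mirroring how an elicited table partitions a cohort.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dests = list(true_probs)
    p = np.array([true_probs[d] for d in dests], dtype=float)
    if (p < 0).any() or p.sum() > 1.0:
        raise ValueError("true probabilities must be >= 0 and sum to <= 1")
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    counts = rng.multinomial(n, np.append(p, 1.0 - p.sum()))
    return TransitionCounts(
        origin=origin,
        n=n,
        counts={d: int(c) for d, c in zip(dests, counts[:-1])},
    )


def simulate_roulette(
    alpha: float,
    beta: float,
    bins: int = 20,
    chips: int = 50,
    seed: int | np.random.Generator | None = None,
    support: tuple[float, float] = (0.0, 1.0),
) -> RouletteHistogram:
    """Chips-and-bins histogram for an expert whose belief is Beta(alpha, beta).

    Chips are allocated multinomially with per-bin probabilities equal to the
    Beta probability mass in each bin, emulating an expert who places chips
    in proportion to their subjective density.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if chips < 1:
        raise ValueError("need at least 1 chip")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    edges = np.linspace(support[0], support[1], bins + 1)
    cdf = stats.beta.cdf(edges, alpha, beta)
    mass = np.diff(cdf)
    total = mass.sum()
    if total <= 0:
        raise ValueError("Beta distribution has no mass on the support")
    allocation = rng.multinomial(chips, mass / total)
    return RouletteHistogram(edges=tuple(edges), chips=tuple(int(c) for c in allocation))


def perturbed_transitions(
    base: dict[str, dict[str, float]],
    rel_sd: float,
    seed: int | np.random.Generator | None = None,
) -> dict[str, dict[str, float]]:
    """Multiplicatively jitter a transition table (lognormal, known truth)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: dict[str, dict[str, float]] = {}
    for origin, dests in base.items():
        out[origin] = {
            d: float(np.clip(p * rng.lognormal(0.0, rel_sd), 0.0, 0.99))
            for d, p in dests.items()
        }
    return out
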