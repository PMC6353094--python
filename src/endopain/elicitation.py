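"""Expert-elicitation fitting: counts to Beta/Dirichlet, chips to Beta.

The model's transition probabilities were elicited by asking an expert how
many of 1000 hypothetical patients would move between pain states in one
month; those counts become Beta pseudo-counts (single destination) or
Dirichlet concentrations (several destinations).  Utility weights were
elicited with the roulette ("chips and bins") format and fitted to a Beta
by the method of moments at bin midpoints.  Costs with only a published
point estimate get a Gamma with a chosen coefficient of variation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TransitionCounts:
    """Elicited one-month transition counts out of one origin state."""

    origin: str
    n: float
    counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size n must be > 0")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("transition counts must be >= 0")
        if sum(self.counts.values()) > self.n:
            raise ValueError("exit counts exceed cohort size")

    @property
    def stay(self) -> float:
        return self.n - sum(self.counts.values())


@dataclass(frozen=True)
class RouletteHistogram:
    """Chips placed over value bins on [0, 1] (the utility axis)."""

    edges: tuple[float, ...]
    chips: tuple[int, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if len(edges) < 3:
            raise ValueError("need at least 2 bins (3 edges)")
        if len(self.chips) != len(edges) - 1:
            raise ValueError("chips must have one entry per bin")
        if (np.diff(edges) <= 0).any():
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] < -1e-12 or edges[-1] > 1 + 1e-12:
            raise ValueError("bin edges must lie within [0, 1]")
        if any(c < 0 for c in self.chips):
            raise ValueError("chip counts must be >= 0")
        if sum(self.chips) < 1:
            raise ValueError("need at least one chip")

    @property
    def total_chips(self) -> int:
        return int(sum(self.chips))

    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    def moments(self) -> tuple[float, float]:
        """(mean, variance) of the chip distribution at bin midpoints."""
        w = np.asarray(self.chips, dtype=float)
        w = w / w.sum()
        m = self.midpoints()
        mean = float(w @ m)
        var = float(w @ (m - mean) ** 2)
        return mean, var


@dataclass(frozen=True)
class DistributionParams:
    """A fitted parametric distribution for one model input."""

    family: str  # Beta | Dirichlet | Gamma | Fixed
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family == "Beta":
            if len(self.params) != 2 or any(p <= 0 for p in self.params):
                raise ValueError("Beta needs two positive parameters")
        elif self.family == "Dirichlet":
            if len(self.params) < 2 or any(p <= 0 for p in self.params):
                raise ValueError("Dirichlet needs >= 2 positive concentrations")
        elif self.family == "Gamma":
            if len(self.params) != 2 or any(p <= 0 for p in self.params):
                raise ValueError("Gamma needs positive shape and scale")
        elif self.family == "Fixed":
            if len(self.params) != 1:
                raise ValueError("Fixed needs exactly one value")
        else:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def mean(self) -> float | np.ndarray:
        p = np.asarray(self.params)
        if self.family == "Beta":
            return float(p[0] / p.sum())
        if self.family == "Dirichlet":
            return p / p.sum()
        if self.family == "Gamma":
            return float(p[0] * p[1])
        return float(p[0])

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "Beta":
            return rng.beta(self.params[0], self.params[1], size=size)
        if self.family == "Dirichlet":
            return rng.dirichlet(self.params, size=size)
        if self.family == "Gamma":
            return rng.gamma(self.params[0], self.params[1], size=size)
        value = self.params[0]
        return value if size is None else np.full(size, value)


def fit_beta_from_counts(k: float, n: float) -> DistributionParams:
    """Beta(alpha=movers, beta=stayers) from k movers among n patients.

    Fractional pseudo-counts are accepted (elicited tables use values such
    as 0.1 movers).  A zero count has no proper Beta; it degrades to a
    Fixed(0) with a warning so downstream sampling still works.
    """
    if n <= 0:
        raise ValueError("cohort size n must be > 0")
    if not 0 <= k <= n:
        raise ValueError(f"count k={k} outside [0, n={n}]")
    if k == 0:
        warnings.warn(
            "zero transition count gives a degenerate Beta; using Fixed(0)",
            stacklevel=2,
        )
        return DistributionParams("Fixed", (0.0,))
    if k == n:
        warnings.warn(
            "all patients transition; degenerate Beta replaced by Fixed(1)",
            stacklevel=2,
        )
        return DistributionParams("Fixed", (1.0,))
    return DistributionParams("Beta", (float(k), float(n - k)))


def fit_dirichlet_from_counts(counts: TransitionCounts) -> DistributionParams:
    """Dirichlet over (stay, destinations...) from a multi-destination row."""
    if len(counts.counts) < 2:
        raise ValueError(
            "origin has a single destination; use fit_beta_from_counts"
        )
    conc = [counts.stay] + [counts.counts[d] for d in counts.counts]
    if any(c <= 0 for c in conc):
        raise ValueError("all Dirichlet concentrations must be > 0")
    return DistributionParams("Dirichlet", tuple(float(c) for c in conc))


def fit_beta_from_roulette(h: RouletteHistogram) -> DistributionParams:
    """Method-of-moments Beta fit to a chips-and-bins histogram.

    With histogram mean m and variance v (chips at bin midpoints), the
    moment match gives s = m(1-m)/v - 1, alpha = m*s, beta = (1-m)*s.
    A histogram with all chips in one bin has zero variance; the variance is
    floored at (bin width)^2 / 12 (the within-bin uniform variance), since a
    single-bin answer still expresses uncertainty within that bin.
    """
    mean, var = h.moments()
    widths = np.diff(np.asarray(h.edges))
    nonzero = np.asarray(h.chips) > 0
    floor = float((widths[nonzero] ** 2).max()) / 12.0
    var = max(var, floor)
    if not 0.0 < mean < 1.0:
        # all chips at an extreme midpoint; nudge inside the unit interval
        mean = min(max(mean, 1e-6), 1.0 - 1e-6)
    if var >= mean * (1.0 - mean):
        raise ValueError(
            "histogram variance is too large for a Beta on [0, 1]; "
            "use a wider support or more bins"
        )
    s = mean * (1.0 - mean) / var - 1.0
    return DistributionParams("Beta", (mean * s, (1.0 - mean) * s))


def gamma_from_mean_cv(mean: float, cv: float) -> DistributionParams:
    """Gamma with a given mean and coefficient of variation.

    shape = 1/cv^2, scale = mean*cv^2, so the distribution's mean is ``mean``
    and its standard deviation ``mean*cv``.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if cv <= 0:
        raise ValueError("cv must be > 0")
    return DistributionParams("Gamma", (1.0 / cv**2, mean * cv**2))


def read_transition_counts(path: str | Path) -> list[TransitionCounts]:
    """Read elicited counts from CSV ``origin,destination,count`` (+ optional n)."""
    df = pd.read_csv(path)
    need = {"origin", "destination", "count"}
    if not need <= set(df.columns):
        raise ValueError(f"transition counts CSV needs columns {sorted(need)}")
    out = []
    for origin, grp in df.groupby("origin", sort=False):
        n = float(grp["n"].iloc[0]) if "n" in grp.columns else 1000.0
        out.append(
            TransitionCounts(
                origin=str(origin),
                n=n,
                counts={str(r.destination): float(r.count) for r in grp.itertuples()},
            )
        )
    return out


def read_roulette(path: str | Path) -> RouletteHistogram:
    """Read a chips histogram from CSV ``bin_low,bin_high,chips``."""
    df = pd.read_csv(path).sort_values("bin_low")
    need = {"bin_low", "bin_high", "chips"}
    if not need <= set(df.columns):
        raise ValueError(f"roulette CSV needs columns {sorted(need)}")
    if not np.allclose(df["bin_high"].values[:-1], df["bin_low"].values[1:]):
        raise ValueError("roulette bins must be contiguous")
    edges = tuple(df["bin_low"].tolist() + [df["bin_high"].iloc[-1]])
    return RouletteHistogram(edges=edges, chips=tuple(int(c) for c in df["chips"]))
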