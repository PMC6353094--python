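"""Health-state space for the endometriosis pain model.

Five Markov states: four alive pain-severity states defined by ranges on
the 0-10 numerical rating scale (NRS), plus an absorbing death state.
"""
from __future__ import annotations

from dataclasses import dataclass

#: Alive states in severity order; indices are used throughout the engine.
ALIVE_STATES: tuple[str, ...] = ("no_pain", "mild", "moderate", "severe")
DEAD: str = "dead"
STATES: tuple[str, ...] = ALIVE_STATES + (DEAD,)

N_ALIVE = len(ALIVE_STATES)
N_STATES = len(STATES)

#: Inclusive NRS interval defining each alive state.
NRS_RANGES: dict[str, tuple[int, int]] = {
    "no_pain": (0, 0),
    "mild": (1, 3),
    "moderate": (4, 6),
    "severe": (7, 10),
}


@dataclass(frozen=True)
class HealthState:
    """A model health state and, for alive states, its NRS pain interval."""

    name: str
    nrs_range: tuple[int, int] | None

    def __post_init__(self) -> None:
        if self.name not in STATES:
            raise ValueError(f"unknown health state {self.name!r}")
        if self.name == DEAD:
            if self.nrs_range is not None:
                raise ValueError("dead state carries no NRS range")
        else:
            if self.nrs_range != NRS_RANGES[self.name]:
                raise ValueError(
                    f"state {self.name!r} must map to NRS {NRS_RANGES[self.name]}"
                )


def state_index(name: str) -> int:
    """Index of a state in the canonical ordering."""
    return STATES.index(name)


def severity_gap(a: str, b: str) -> int:
    """Absolute severity-level distance between two alive states."""
    return abs(ALIVE_STATES.index(a) - ALIVE_STATES.index(b))


def nrs_to_state(score: int) -> str:
    """Map an NRS pain score (0-10) to its health state."""
    if not 0 <= score <= 10:
        raise ValueError(f"NRS score must be in 0..10, got {score}")
    for name, (lo, hi) in NRS_RANGES.items():
        if lo <= score <= hi:
            return name
    raise AssertionError("unreachable: NRS ranges cover 0..10")
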