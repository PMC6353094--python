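"""Validated model inputs and the configuration loader.

All inputs to the cost-effectiveness model live here as pydantic types:
run settings (:class:`ModelConfig`), unit costs (:class:`CostSpec`),
QALY weights (:class:`UtilitySpec`), monthly transition probabilities
(:class:`TransitionSpec`) and all-cause mortality (:class:`LifeTable`).
:func:`load_config` reads one YAML file into a :class:`ParameterSet`; the
bundled default configuration carries the published parameterisation.
"""
from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .states import ALIVE_STATES, severity_gap

ARMS = ("nht", "oc")

_DIST_SUM_TOL = 1e-9


class ConfigError(ValueError):
    """A configuration file failed to parse or violated an invariant."""


class ModelConfig(BaseModel):
    """Run settings: cohort ages, cycle length, discounting, starting split."""

    model_config = ConfigDict(frozen=True)

    start_age: int = 32
    end_age: int = 50
    cycle_length_months: int = 1
    annual_discount_rate: float = 0.035
    half_cycle_correction: bool = True
    initial_distribution: dict[str, float] = Field(
        default_factory=lambda: {s: 0.25 for s in ALIVE_STATES}
    )
    psa_draws: int = 1000
    seed: int = 2016

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if self.end_age <= self.start_age:
            raise ValueError("end_age must exceed start_age")
        if self.cycle_length_months != 1:
            raise ValueError("only one-month cycles are supported")
        if self.annual_discount_rate < 0:
            raise ValueError("annual_discount_rate must be >= 0")
        if set(self.initial_distribution) != set(ALIVE_STATES):
            raise ValueError(
                "initial_distribution must cover exactly the four alive states"
            )
        vals = np.array([self.initial_distribution[s] for s in ALIVE_STATES])
        if (vals < 0).any():
            raise ValueError("initial_distribution entries must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"initial_distribution must sum to 1 (got {vals.sum():.6f})"
            )
        if self.psa_draws < 1:
            raise ValueError("psa_draws must be >= 1")
        return self

    @property
    def n_cycles(self) -> int:
        return (self.end_age - self.start_age) * 12 // self.cycle_length_months

    def initial_occupancy(self) -> np.ndarray:
        """Starting occupancy over the five states (dead mass is zero)."""
        out = np.zeros(len(ALIVE_STATES) + 1)
        out[: len(ALIVE_STATES)] = [
            self.initial_distribution[s] for s in ALIVE_STATES
        ]
        return out


class CostSpec(BaseModel):
    """Unit costs (GBP) and the rules mapping states to monthly spend.

    The analgesic ladder follows pain severity: the mild state uses half the
    maximum paracetamol dose (one unit of ``paracetamol_half_max_month``),
    moderate the full maximum dose (two units), and severe adds the maximum
    ibuprofen dose on top.  GP consultations occur every ``gp_interval_*``
    months and are amortised per month unless ``gp_lumped`` is set.  With
    ``pain_states_only`` (the default) treatment costs accrue only while the
    cohort is in a pain state: a pain-free month incurs no treatment cost.
    """

    model_config = ConfigDict(frozen=True)

    gp_visit_cost: float = 26.67
    gp_interval_nht: int = 3
    gp_interval_oc: int = 6
    oc_pack_cost: float = 2.82
    oc_pack_cycles: int = 3
    paracetamol_half_max_month: float = 2.31
    ibuprofen_max_month: float = 2.43
    paracetamol_units: dict[str, float] = Field(
        default_factory=lambda: {"no_pain": 0.0, "mild": 1.0, "moderate": 2.0, "severe": 2.0}
    )
    ibuprofen_units: dict[str, float] = Field(
        default_factory=lambda: {"no_pain": 0.0, "mild": 0.0, "moderate": 0.0, "severe": 1.0}
    )
    pain_states_only: bool = True
    gp_lumped: bool = False
    cost_cv: float = 0.2

    @model_validator(mode="after")
    def _check(self) -> "CostSpec":
        for name in (
            "gp_visit_cost",
            "oc_pack_cost",
            "paracetamol_half_max_month",
            "ibuprofen_max_month",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gp_interval_nht < 1 or self.gp_interval_oc < 1:
            raise ValueError("GP intervals must be >= 1 month")
        if self.oc_pack_cycles < 1:
            raise ValueError("oc_pack_cycles must be >= 1")
        for units in (self.paracetamol_units, self.ibuprofen_units):
            if set(units) != set(ALIVE_STATES):
                raise ValueError("analgesic units must cover the four alive states")
            if any(v < 0 for v in units.values()):
                raise ValueError("analgesic units must be >= 0")
        if self.cost_cv <= 0:
            raise ValueError("cost_cv must be > 0")
        return self

    def analgesic_monthly(self) -> np.ndarray:
        """Monthly analgesic cost per alive state."""
        return np.array(
            [
                self.paracetamol_units[s] * self.paracetamol_half_max_month
                + self.ibuprofen_units[s] * self.ibuprofen_max_month
                for s in ALIVE_STATES
            ]
        )

    def oc_monthly_drug_cost(self) -> float:
        """OC drug cost per monthly cycle (pack cost spread over its cycles)."""
        return self.oc_pack_cost / self.oc_pack_cycles

    def gp_interval(self, arm: str) -> int:
        return self.gp_interval_nht if arm == "nht" else self.gp_interval_oc


class UtilitySpec(BaseModel):
    """Annual QALY weight per alive state, with Beta PSA parameters."""

    model_config = ConfigDict(frozen=True)

    means: dict[str, float]
    beta: dict[str, tuple[float, float]]

    @model_validator(mode="after")
    def _check(self) -> "UtilitySpec":
        if set(self.means) != set(ALIVE_STATES):
            raise ValueError("utility means must cover the four alive states")
        if set(self.beta) != set(ALIVE_STATES):
            raise ValueError("utility Beta parameters must cover the four alive states")
        vals = [self.means[s] for s in ALIVE_STATES]
        if any(not 0.0 <= u <= 1.0 for u in vals):
            raise ValueError("utilities must lie in [0, 1]")
        if any(a <= b for a, b in zip(vals, vals[1:])):
            raise ValueError("utilities must strictly decrease with pain severity")
        for s, (a, b) in self.beta.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta parameters for {s} must be > 0")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.means[s] for s in ALIVE_STATES])


class TransitionSpec(BaseModel):
    """Monthly transition probabilities between alive states, per arm.

    Rows were elicited as monthly transition counts among ``pseudo_n``
    hypothetical patients, so probability p corresponds to p * pseudo_n
    movers; those pseudo-counts parameterise the Beta/Dirichlet PSA
    distributions.  Only adjacent-severity moves are permitted.
    """

    model_config = ConfigDict(frozen=True)

    pseudo_n: float = 1000.0
    nht: dict[str, dict[str, float]]
    oc: dict[str, dict[str, float]]

    @model_validator(mode="after")
    def _check(self) -> "TransitionSpec":
        if self.pseudo_n <= 0:
            raise ValueError("pseudo_n must be > 0")
        for arm in ARMS:
            rows: Mapping[str, Mapping[str, float]] = getattr(self, arm)
            for origin, dests in rows.items():
                if origin not in ALIVE_STATES:
                    raise ValueError(f"unknown origin state {origin!r}")
                total = 0.0
                for dest, p in dests.items():
                    if dest not in ALIVE_STATES:
                        raise ValueError(f"unknown destination state {dest!r}")
                    if dest == origin:
                        raise ValueError("self-transitions are implicit; omit them")
                    if severity_gap(origin, dest) > 1:
                        raise ValueError(
                            f"{arm}: {origin}->{dest} jumps more than one severity level"
                        )
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"{arm}: {origin}->{dest} outside [0, 1]")
                    total += p
                if total >= 1.0:
                    raise ValueError(
                        f"{arm}: exit probabilities from {origin} must sum to < 1"
                    )
        return self

    def matrix(self, arm: str) -> np.ndarray:
        """4x4 alive-state monthly transition matrix (rows sum to 1)."""
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}")
        rows: Mapping[str, Mapping[str, float]] = getattr(self, arm)
        n = len(ALIVE_STATES)
        M = np.eye(n)
        for origin, dests in rows.items():
            i = ALIVE_STATES.index(origin)
            for dest, p in dests.items():
                j = ALIVE_STATES.index(dest)
                M[i, j] = p
                M[i, i] -= p
        return M

    def pseudo_counts(self, arm: str, origin: str) -> tuple[float, list[tuple[str, float]]]:
        """(stay count, [(destination, mover count), ...]) for one row."""
        rows: Mapping[str, Mapping[str, float]] = getattr(self, arm)
        dests = rows.get(origin, {})
        movers = [(d, p * self.pseudo_n) for d, p in dests.items()]
        stay = self.pseudo_n - sum(k for _, k in movers)
        return stay, movers


class LifeTable(BaseModel):
    """All-cause mortality: annual probability of death per integer age."""

    model_config = ConfigDict(frozen=True)

    ages: tuple[int, ...]
    q_annual: tuple[float, ...]

    @model_validator(mode="after")
    def _check(self) -> "LifeTable":
        if len(self.ages) != len(self.q_annual):
            raise ValueError("ages and q_annual must have equal length")
        if len(self.ages) == 0:
            raise ValueError("life table is empty")
        if list(self.ages) != list(range(self.ages[0], self.ages[-1] + 1)):
            raise ValueError("ages must be consecutive integers")
        if any(not 0.0 <= q < 1.0 for q in self.q_annual):
            raise ValueError("q_annual values must lie in [0, 1)")
        return self

    def covers(self, start_age: int, end_age: int) -> bool:
        return self.ages[0] <= start_age and self.ages[-1] >= end_age - 1

    def q_at(self, age: int) -> float:
        if not self.ages[0] <= age <= self.ages[-1]:
            raise ValueError(f"age {age} outside life-table coverage")
        return self.q_annual[age - self.ages[0]]

    def monthly_q(self, age: int) -> float:
        """Monthly death probability: 1 - (1 - q_annual)^(1/12)."""
        return 1.0 - (1.0 - self.q_at(age)) ** (1.0 / 12.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q_annual": self.q_annual})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        if not {"age", "q_annual"} <= set(df.columns):
            raise ConfigError("life table needs columns age,q_annual")
        df = df.sort_values("age")
        return cls(ages=tuple(int(a) for a in df["age"]), q_annual=tuple(df["q_annual"]))

    @classmethod
    def read_csv(cls, path: str | Path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class ParameterSet(BaseModel):
    """Everything one run needs: settings, costs, utilities, transitions, mortality."""

    model_config = ConfigDict(frozen=True)

    model: ModelConfig
    costs: CostSpec
    utilities: UtilitySpec
    transitions: TransitionSpec
    life_table: LifeTable

    @model_validator(mode="after")
    def _check(self) -> "ParameterSet":
        if not self.life_table.covers(self.model.start_age, self.model.end_age):
            raise ValueError(
                f"life table does not cover ages {self.model.start_age}.."
                f"{self.model.end_age - 1}"
            )
        return self

    def fingerprint(self) -> str:
        """Stable hash of the model settings, for result compatibility checks."""
        import hashlib

        payload = self.model_dump_json().encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _utility_section(raw: dict) -> UtilitySpec:
    return UtilitySpec(
        means=raw["means"],
        beta={k: tuple(v) for k, v in raw["beta"].items()},
    )


def default_config_path() -> Path:
    """Path of the bundled default YAML configuration."""
    return Path(
        importlib.resources.files("endopain").joinpath("data/default_config.yaml")
    )


def load_config(path: str | Path | None = None, life_table_csv: str | Path | None = None) -> ParameterSet:
    """Load a YAML configuration into a validated :class:`ParameterSet`.

    With ``path=None`` the bundled default configuration is used.  The life
    table comes from ``life_table_csv`` when given, from a ``life_table``
    section or file reference inside the YAML otherwise, and falls back to
    the package's synthetic table covering the model's age span.
    """
    cfg_path = Path(path) if path is not None else default_config_path()
    try:
        text = cfg_path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read configuration {cfg_path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"configuration {cfg_path} is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration {cfg_path} must be a mapping at top level")

    try:
        model_raw = dict(raw.get("model", {}))
        psa_raw = dict(raw.get("psa", {}))
        if "draws" in psa_raw:
            model_raw.setdefault("psa_draws", psa_raw["draws"])
        if "seed" in psa_raw:
            model_raw.setdefault("seed", psa_raw["seed"])
        model = ModelConfig(**model_raw)
        costs_raw = dict(raw.get("costs", {}))
        if "cv" in psa_raw:
            costs_raw.setdefault("cost_cv", psa_raw["cv"])
        costs = CostSpec(**costs_raw)
        utilities = _utility_section(raw["utilities"])
        transitions = TransitionSpec(**raw["transitions"])
    except KeyError as exc:
        raise ConfigError(f"configuration section missing: {exc}") from exc
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc

    if life_table_csv is not None:
        life = LifeTable.read_csv(life_table_csv)
    elif "life_table" in raw:
        lt = raw["life_table"]
        if isinstance(lt, str):
            lt_path = Path(lt)
            if not lt_path.is_absolute():
                lt_path = cfg_path.parent / lt_path
            life = LifeTable.read_csv(lt_path)
        else:
            life = LifeTable(
                ages=tuple(int(r["age"]) for r in lt),
                q_annual=tuple(float(r["q_annual"]) for r in lt),
            )
    else:
        from .synthetic import GompertzSpec, make_life_table

        life = make_life_table(
            GompertzSpec(), range(model.start_age, model.end_age + 1)
        )

    try:
        return ParameterSet(
            model=model,
            costs=costs,
            utilities=utilities,
            transitions=transitions,
            life_table=life,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(ps: ParameterSet, path: str | Path) -> None:
    """Serialise a parameter set back to YAML (round-trips with load_config)."""
    raw = {
        "model": {
            "start_age": ps.model.start_age,
            "end_age": ps.model.end_age,
            "cycle_length_months": ps.model.cycle_length_months,
            "annual_discount_rate": ps.model.annual_discount_rate,
            "half_cycle_correction": ps.model.half_cycle_correction,
            "initial_distribution": dict(ps.model.initial_distribution),
        },
        "costs": ps.costs.model_dump(),
        "utilities": {
            "means": dict(ps.utilities.means),
            "beta": {k: list(v) for k, v in ps.utilities.beta.items()},
        },
        "transitions": {
            "pseudo_n": ps.transitions.pseudo_n,
            "nht": {o: dict(d) for o, d in ps.transitions.nht.items()},
            "oc": {o: dict(d) for o, d in ps.transitions.oc.items()},
        },
        "psa": {"draws": ps.model.psa_draws, "seed": ps.model.seed},
        "life_table": [
            {"age": int(a), "q_annual": float(q)}
            for a, q in zip(ps.life_table.ages, ps.life_table.q_annual)
        ],
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
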