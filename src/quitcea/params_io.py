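"""Parameter data model and I/O for the cessation cost-effectiveness model.

Defines the typed inputs of the lifetime Markov cohort model of
smoking-cessation support -- quit/relapse dynamics, health-state utilities,
annual disease costs, economic settings, the trial cohort mix -- together
with the age-by-gender epidemiological tables from which status-specific
transition probabilities are derived.  Readers validate aggressively: a
malformed table or configuration fails loudly at load time, never
mid-simulation.

The base-case parameter set is shipped as ``data/base_case.toml`` inside the
package; :func:`default_config_path` locates it.
"""

from __future__ import annotations

import importlib.resources
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

#: The five smoking-related diseases the model tracks, in canonical order.
DISEASES: tuple[str, ...] = ("lung_cancer", "stroke", "mi", "copd", "chd")
GENDERS: tuple[str, str] = ("male", "female")
AGE_MIN: int = 16
AGE_MAX: int = 100


class ConfigError(ValueError):
    """A configuration file is missing a key or holds an unusable value."""


class FormatError(ValueError):
    """A CSV table does not have the expected column layout."""


class ValidationError(ValueError):
    """A numeric invariant of the model inputs is violated."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


# ---------------------------------------------------------------------------
# scalar parameter blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuitParams:
    """Quit and relapse dynamics.

    ``control_quit_6m`` is the 6-month quit probability under current
    practice; the intervention multiplies it by ``rr_quit`` in the first
    cycle only.  ``relapse_6_12`` applies to quitters between 6 and 12
    months, ``relapse_lifetime`` once more among 12-month quitters, and
    ``background_quit_annual`` is the spontaneous annual quit probability
    applied to all remaining smokers in both arms.
    """

    control_quit_6m: float
    rr_quit: float
    rr_quit_ci_low: float
    rr_quit_ci_high: float
    relapse_6_12: float
    relapse_lifetime: float
    background_quit_annual: float

    def __post_init__(self) -> None:
        for name in (
            "control_quit_6m",
            "relapse_6_12",
            "relapse_lifetime",
            "background_quit_annual",
        ):
            _check_prob(name, getattr(self, name))
        if not (0.0 < self.rr_quit_ci_low <= self.rr_quit <= self.rr_quit_ci_high):
            raise ValidationError(
                "require 0 < rr_quit_ci_low <= rr_quit <= rr_quit_ci_high, got "
                f"({self.rr_quit_ci_low}, {self.rr_quit}, {self.rr_quit_ci_high})"
            )
        if self.rr_quit * self.control_quit_6m > 1.0 + 1e-12:
            raise ValidationError(
                "rr_quit * control_quit_6m exceeds 1: "
                f"{self.rr_quit} * {self.control_quit_6m}"
            )


@dataclass(frozen=True)
class UtilityTable:
    """Health-state values: one utility per disease, and utilities for
    disease-free smokers and former smokers."""

    disease_value: dict[str, float]
    smoker_value: float
    former_value: float

    def __post_init__(self) -> None:
        for d, v in self.disease_value.items():
            _check_prob(f"utility_{d}", v)
        _check_prob("utility_smoker", self.smoker_value)
        _check_prob("utility_former", self.former_value)
        if self.former_value < self.smoker_value:
            warnings.warn(
                "former-smoker utility below smoker utility "
                f"({self.former_value} < {self.smoker_value})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CostTable:
    """Annual disease treatment costs (GBP, 2009-10 prices) and one-off
    per-smoker intervention costs."""

    disease_annual_cost: dict[str, float]
    intervention_cost_per_smoker: float
    royalty_management_per_smoker: float = 0.0

    def __post_init__(self) -> None:
        for d, v in self.disease_annual_cost.items():
            if v < 0:
                raise ValidationError(f"cost_{d} must be >= 0, got {v!r}")
        if self.intervention_cost_per_smoker < 0:
            raise ValidationError("intervention_cost_per_smoker must be >= 0")
        if self.royalty_management_per_smoker < 0:
            raise ValidationError("royalty_management_per_smoker must be >= 0")


@dataclass(frozen=True)
class EconomicSettings:
    """Discounting, cycle structure and the willingness-to-pay grid."""

    discount_rate_cost: float = 0.035
    discount_rate_effect: float = 0.035
    cycle_length: float = 0.5
    horizon_age: float = 100.0
    wtp_grid_max: float = 4000.0
    wtp_grid_step: float = 50.0

    def __post_init__(self) -> None:
        for name in ("discount_rate_cost", "discount_rate_effect"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ValidationError(f"{name} must lie in [0, 1), got {r!r}")
        if self.cycle_length != 0.5:
            raise ValidationError(
                f"cycle_length is fixed at 0.5 years, got {self.cycle_length!r}"
            )
        if self.wtp_grid_max <= 0 or self.wtp_grid_step <= 0:
            raise ValidationError("willingness-to-pay grid must be positive")


@dataclass(frozen=True)
class Stratum:
    start_age: int
    age_weight: float
    gender: str
    gender_weight: float

    @property
    def weight(self) -> float:
        return self.age_weight * self.gender_weight


@dataclass(frozen=True)
class CohortMix:
    """The trial's age-by-gender mix: cohorts are simulated per stratum and
    combined as a weighted average."""

    strata: tuple[Stratum, ...]

    def __post_init__(self) -> None:
        age_w: dict[int, float] = {}
        gender_w: dict[str, float] = {}
        for s in self.strata:
            if s.gender not in GENDERS:
                raise ValidationError(f"unknown gender {s.gender!r}")
            age_w.setdefault(s.start_age, s.age_weight)
            gender_w.setdefault(s.gender, s.gender_weight)
            if age_w[s.start_age] != s.age_weight:
                raise ValidationError(f"inconsistent weight for age {s.start_age}")
            if gender_w[s.gender] != s.gender_weight:
                raise ValidationError(f"inconsistent weight for gender {s.gender}")
        if abs(sum(age_w.values()) - 1.0) > 1e-9:
            raise ValidationError(
                f"age weights must sum to 1, got {sum(age_w.values())!r}"
            )
        if abs(sum(gender_w.values()) - 1.0) > 1e-9:
            raise ValidationError(
                f"gender weights must sum to 1, got {sum(gender_w.values())!r}"
            )

    @classmethod
    def from_marginals(
        cls,
        start_ages: list[int],
        age_weights: list[float],
        gender_weights: Mapping[str, float],
    ) -> "CohortMix":
        if len(start_ages) != len(age_weights):
            raise ConfigError("start_ages and age_weights differ in length")
        strata = tuple(
            Stratum(int(a), float(aw), g, float(gw))
            for a, aw in zip(start_ages, age_weights)
            for g, gw in gender_weights.items()
        )
        return cls(strata)

    def __iter__(self) -> Iterator[Stratum]:
        return iter(self.strata)

    @property
    def start_ages(self) -> tuple[int, ...]:
        return tuple(dict.fromkeys(s.start_age for s in self.strata))


# ---------------------------------------------------------------------------
# epidemiological tables
# ---------------------------------------------------------------------------


def epi_columns(diseases: tuple[str, ...] = DISEASES) -> list[str]:
    """Canonical CSV column order for an epidemiological table."""
    cols = ["age", "gender", "m_gen", "p_smoker", "p_former", "p_never"]
    cols += [f"prev_{d}" for d in diseases]
    cols += ["rr_death_smoker", "rr_death_former"]
    for d in diseases:
        cols += [f"rr_{d}_smoker", f"rr_{d}_former"]
    return cols


@dataclass
class EpiTables:
    """Age-by-gender grid of general-population annual mortality, smoking
    prevalence, disease probabilities and relative risks by smoking status.

    ``table`` is indexed by (age, gender) and carries the value columns of
    :func:`epi_columns`.  Mortality and disease probabilities are annual;
    conversion to 6-month cycle probabilities happens downstream.
    """

    table: pd.DataFrame
    diseases: tuple[str, ...] = DISEASES

    def validate(self) -> None:
        t = self.table
        if t.index.names != ["age", "gender"]:
            raise FormatError("EpiTables must be indexed by (age, gender)")
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate row for (age, gender) = {dup}")
        ages = t.index.get_level_values("age")
        if not np.issubdtype(np.asarray(ages).dtype, np.integer):
            raise ValidationError("ages must be integers")
        if ages.min() < AGE_MIN or ages.max() > AGE_MAX:
            raise ValidationError(
                f"ages must lie in [{AGE_MIN}, {AGE_MAX}], got "
                f"[{ages.min()}, {ages.max()}]"
            )
        for age in sorted(set(ages)):
            present = set(t.xs(age, level="age").index)
            if present != set(GENDERS):
                raise ValidationError(f"age {age}: missing gender rows {set(GENDERS) - present}")
        value_cols = [c for c in epi_columns(self.diseases) if c not in ("age", "gender")]
        missing = [c for c in value_cols if c not in t.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        prob_cols = ["m_gen", "p_smoker", "p_former", "p_never"] + [
            f"prev_{d}" for d in self.diseases
        ]
        for col in prob_cols:
            bad = t.index[(t[col] < 0) | (t[col] > 1)]
            if len(bad):
                raise ValidationError(
                    f"{col} outside [0, 1] at (age, gender) = {bad[0]}"
                )
        rr_cols = [c for c in value_cols if c.startswith("rr_")]
        for col in rr_cols:
            bad = t.index[t[col] <= 0]
            if len(bad):
                raise ValidationError(f"{col} must be > 0, violated at {bad[0]}")
        sums = t["p_smoker"] + t["p_former"] + t["p_never"]
        bad = t.index[(sums - 1.0).abs() > 1e-6]
        if len(bad):
            raise ValidationError(
                "smoking-status prevalences must sum to 1; violated at "
                f"(age, gender) = {bad[0]} (sum {sums.loc[bad[0]]:.6f})"
            )

    def ages(self) -> np.ndarray:
        return np.asarray(sorted(set(self.table.index.get_level_values("age"))))

    def to_frame(self) -> pd.DataFrame:
        """Flat frame in canonical column order (for CSV output)."""
        out = self.table.reset_index()
        return out[epi_columns(self.diseases)]

    def equals(self, other: "EpiTables") -> bool:
        return (
            self.diseases == other.diseases
            and self.to_frame().equals(other.to_frame())
        )


def read_epi_tables(path: str | Path) -> EpiTables:
    """Read and validate an epidemiological table CSV.

    The file must carry exactly the columns of :func:`epi_columns`, one row
    per (age, gender).  Missing rows are an error, never interpolated.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    expected = epi_columns()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing column(s): {', '.join(missing)}"
        )
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise FormatError(f"{path}: unknown column(s): {', '.join(unknown)}")
    try:
        df["age"] = df["age"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-integer age values") from exc
    epi = EpiTables(df.set_index(["age", "gender"]).sort_index())
    epi.validate()
    return epi


def write_epi_tables(epi: EpiTables, path: str | Path) -> None:
    """Write an epidemiological table as CSV (inverse of
    :func:`read_epi_tables`; exact float round-trip)."""
    epi.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# assembled model inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelInputs:
    """One fully resolved parameter set for a model run."""

    quit: QuitParams
    utilities: UtilityTable
    costs: CostTable
    econ: EconomicSettings
    mix: CohortMix
    epi: EpiTables
    diseases: tuple[str, ...] = DISEASES
    relapse_mode: str = "one_off"

    def __post_init__(self) -> None:
        for label, keys in (
            ("utilities", set(self.utilities.disease_value)),
            ("costs", set(self.costs.disease_annual_cost)),
            ("epi", set(self.epi.diseases)),
        ):
            if keys != set(self.diseases):
                raise ValidationError(
                    f"disease keys in {label} ({sorted(keys)}) differ from "
                    f"model diseases {sorted(self.diseases)}"
                )
        if self.relapse_mode not in ("one_off", "spread"):
            raise ValidationError(
                f"lifetime_relapse_mode must be 'one_off' or 'spread', got "
                f"{self.relapse_mode!r}"
            )
        for s in self.mix:
            if s.start_age >= self.econ.horizon_age:
                raise ValidationError(
                    f"horizon_age {self.econ.horizon_age} must exceed cohort "
                    f"starting age {s.start_age}"
                )


_SCALAR_KEYS = (
    "control_quit_6m",
    "rr_quit",
    "rr_quit_ci_low",
    "rr_quit_ci_high",
    "relapse_6_12",
    "relapse_lifetime",
    "background_quit_annual",
    "utility_smoker",
    "utility_former",
    "intervention_cost_per_smoker",
    "royalty_management_per_smoker",
    "discount_rate_cost",
    "discount_rate_effect",
    "cycle_length",
    "horizon_age",
    "wtp_grid_max",
    "wtp_grid_step",
    "male_weight",
    "female_weight",
)


def required_config_keys(diseases: tuple[str, ...] = DISEASES) -> list[str]:
    keys = list(_SCALAR_KEYS)
    keys += [f"utility_{d}" for d in diseases]
    keys += [f"cost_{d}" for d in diseases]
    keys += ["start_ages", "age_weights"]
    return keys


def load_parameters(
    config: str | Path | Mapping[str, object], epi: EpiTables
) -> ModelInputs:
    """Assemble validated :class:`ModelInputs` from a flat TOML config (or an
    equivalent mapping) plus an epidemiological table.

    Raises :class:`ConfigError` naming any missing key, and
    :class:`ValidationError` on invariant violations.
    """
    if isinstance(config, (str, Path)):
        with open(config, "rb") as fh:
            raw: dict[str, object] = tomllib.load(fh)
    else:
        raw = dict(config)

    missing = [k for k in required_config_keys(epi.diseases) if k not in raw]
    if missing:
        raise ConfigError(f"missing key(s): {', '.join(missing)}")

    quit = QuitParams(
        control_quit_6m=float(raw["control_quit_6m"]),
        rr_quit=float(raw["rr_quit"]),
        rr_quit_ci_low=float(raw["rr_quit_ci_low"]),
        rr_quit_ci_high=float(raw["rr_quit_ci_high"]),
        relapse_6_12=float(raw["relapse_6_12"]),
        relapse_lifetime=float(raw["relapse_lifetime"]),
        background_quit_annual=float(raw["background_quit_annual"]),
    )
    utilities = UtilityTable(
        disease_value={d: float(raw[f"utility_{d}"]) for d in epi.diseases},
        smoker_value=float(raw["utility_smoker"]),
        former_value=float(raw["utility_former"]),
    )
    costs = CostTable(
        disease_annual_cost={d: float(raw[f"cost_{d}"]) for d in epi.diseases},
        intervention_cost_per_smoker=float(raw["intervention_cost_per_smoker"]),
        royalty_management_per_smoker=float(raw["royalty_management_per_smoker"]),
    )
    econ = EconomicSettings(
        discount_rate_cost=float(raw["discount_rate_cost"]),
        discount_rate_effect=float(raw["discount_rate_effect"]),
        cycle_length=float(raw["cycle_length"]),
        horizon_age=float(raw["horizon_age"]),
        wtp_grid_max=float(raw["wtp_grid_max"]),
        wtp_grid_step=float(raw["wtp_grid_step"]),
    )
    mix = CohortMix.from_marginals(
        list(raw["start_ages"]),  # type: ignore[arg-type]
        list(raw["age_weights"]),  # type: ignore[arg-type]
        {"male": float(raw["male_weight"]), "female": float(raw["female_weight"])},
    )
    inputs = ModelInputs(
        quit=quit,
        utilities=utilities,
        costs=costs,
        econ=econ,
        mix=mix,
        epi=epi,
        diseases=epi.diseases,
        relapse_mode=str(raw.get("lifetime_relapse_mode", "one_off")),
    )
    _check_epi_coverage(inputs)
    return inputs


def _check_epi_coverage(inputs: ModelInputs) -> None:
    """Every integer age a cohort can reach before the horizon must exist."""
    have = set(inputs.epi.ages().tolist())
    lo = min(inputs.mix.start_ages)
    hi = int(np.ceil(inputs.econ.horizon_age)) - 1
    needed = set(range(lo, hi + 1))
    gap = sorted(needed - have)
    if gap:
        raise ValidationError(
            f"epidemiological table misses ages {gap[0]}..{gap[-1]} needed "
            f"for the simulation"
        )


def default_config_path() -> Path:
    """Path of the packaged base-case configuration."""
    return Path(
        str(importlib.resources.files("quitcea").joinpath("data/base_case.toml"))
    )


def load_base_case(epi: EpiTables) -> ModelInputs:
    """Base-case :class:`ModelInputs` on the given epidemiological tables."""
    return load_parameters(default_config_path(), epi)
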