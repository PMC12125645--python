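"""Synthetic child population generation and CSV round-tripping.

The simulated cohort emulates the demographic structure of US children and
adolescents (ages 0-19): age, sex, race and ethnicity, family income
relative to the federal poverty level, health-insurance type, the fluoride
concentration stratum of the public water system serving the child's
community, tap-water drinking, a survey weight scaling the sample to the
national population, and prevalent dental caries at baseline.

The canonical in-memory container is a :class:`pandas.DataFrame` with one
row per child (columns fixed by :data:`POPULATION_COLUMNS`); a
:class:`ChildProfile` dataclass view is provided for single-child use.
By default fields are drawn independently from configured marginal tables;
an optional joint table over (age group x race/ethnicity x income) can be
supplied to induce realistic coupling between those three fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .parameters import (
    AGE_GROUPS,
    FLUORIDE_STRATA,
    INCOME_GROUPS,
    INSURANCE_TYPES,
    RACE_ETHNICITIES,
    SEXES,
)

__all__ = [
    "ChildProfile",
    "PopulationConfig",
    "ConfigError",
    "PopulationParseError",
    "generate_population",
    "read_population",
    "write_population",
    "age_group_of",
    "POPULATION_COLUMNS",
]

POPULATION_COLUMNS = (
    "id",
    "age",
    "age_group",
    "sex",
    "race_ethnicity",
    "income_group",
    "insurance",
    "fluoride_stratum",
    "drinks_tap_water",
    "weight",
    "baseline_caries",
)

#: age ranges (inclusive) for the joint-table age groups
_JOINT_AGE_RANGES = {"0-1": (0, 1), "2-5": (2, 5), "6-12": (6, 12), "13-19": (13, 19)}


class ConfigError(ValueError):
    """Invalid population configuration."""


class PopulationParseError(ValueError):
    """A population CSV violated the schema; names row and column."""


def age_group_of(age) -> np.ndarray | str:
    """Map age in years to its age group. Under-2s are grouped with 2-5
    (they carry zero risk until they age in); 20+ retain the 13-19 group."""
    scalar = np.isscalar(age)
    a = np.atleast_1d(np.asarray(age))
    out = np.where(a <= 5, "2-5", np.where(a <= 12, "6-12", "13-19"))
    return out[0] if scalar else out


@dataclass(frozen=True)
class ChildProfile:
    """Fixed covariates of one simulated child."""

    id: int
    age: int
    age_group: str
    sex: str
    race_ethnicity: str
    income_group: str
    insurance: str
    fluoride_stratum: str
    drinks_tap_water: bool
    weight: float
    baseline_caries: bool


def _uniform_ages() -> dict[int, float]:
    return {a: 1.0 / 20.0 for a in range(20)}


@dataclass
class PopulationConfig:
    """Sampling configuration for :func:`generate_population`.

    Marginal tables are dicts mapping category -> probability and must each
    sum to 1 (within 1e-9). ``joint_age_race_income`` optionally replaces
    the independent age-group/race/income draw with a joint table keyed
    ``"age_group|race|income"`` (age groups ``0-1``, ``2-5``, ``6-12``,
    ``13-19``); ages are then uniform within the group.
    """

    n: int = 10_000
    seed: int = 0
    age: dict[int, float] = field(default_factory=_uniform_ages)
    sex: dict[str, float] = field(
        default_factory=lambda: {"female": 0.49, "male": 0.51}
    )
    race_ethnicity: dict[str, float] = field(
        default_factory=lambda: {
            "hispanic": 0.243,
            "nh_black": 0.138,
            "nh_white": 0.516,
            "other": 0.103,
        }
    )
    income_group: dict[str, float] = field(
        default_factory=lambda: {"low": 0.30, "middle": 0.30, "high": 0.40}
    )
    insurance: dict[str, float] = field(
        default_factory=lambda: {"private": 0.48, "public": 0.45, "uninsured": 0.07}
    )
    fluoride_stratum: dict[str, float] = field(
        default_factory=lambda: {
            "below_detection": 0.124,
            "suboptimal": 0.457,
            "optimal": 0.404,
            "excessive": 0.015,
        }
    )
    p_tap_water: float = 0.70
    baseline_caries_prevalence: dict[str, float] = field(
        default_factory=lambda: {"2-5": 0.213, "6-12": 0.516, "13-19": 0.572}
    )
    national_population: float = 80_000_000.0
    #: optional per-stratum relative survey weights (fluoride_stratum -> w)
    stratum_weights: dict[str, float] | None = None
    joint_age_race_income: dict[str, float] | None = None

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError(f"n must be >= 1, got {self.n}")
        tables = {
            "age": (self.age, set(range(20))),
            "sex": (self.sex, set(SEXES)),
            "race_ethnicity": (self.race_ethnicity, set(RACE_ETHNICITIES)),
            "income_group": (self.income_group, set(INCOME_GROUPS)),
            "insurance": (self.insurance, set(INSURANCE_TYPES)),
            "fluoride_stratum": (self.fluoride_stratum, set(FLUORIDE_STRATA)),
        }
        for name, (table, allowed) in tables.items():
            if not set(table) <= allowed:
                raise ConfigError(
                    f"{name} table has unknown categories {set(table) - allowed}"
                )
            total = float(sum(table.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} table sums to {total!r}, not 1")
            if any(p < 0 for p in table.values()):
                raise ConfigError(f"{name} table has negative probabilities")
        if self.joint_age_race_income is not None:
            total = float(sum(self.joint_age_race_income.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"joint table sums to {total!r}, not 1")
            for key in self.joint_age_race_income:
                g, r, i = key.split("|")
                if g not in _JOINT_AGE_RANGES or r not in RACE_ETHNICITIES or i not in INCOME_GROUPS:
                    raise ConfigError(f"joint table has invalid cell {key!r}")
        if not 0.0 <= self.p_tap_water <= 1.0:
            raise ConfigError("p_tap_water must be in [0, 1]")
        for g, p in self.baseline_caries_prevalence.items():
            if g not in AGE_GROUPS or not 0.0 <= p <= 1.0:
                raise ConfigError(f"invalid baseline caries entry {g}={p}")
        if self.national_population <= 0:
            raise ConfigError("national_population must be > 0")

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.age = {int(k): v for k, v in cfg.age.items()}
        return cfg


def _draw_categorical(rng: np.random.Generator, table: Mapping, n: int) -> np.ndarray:
    cats = sorted(table)  # sorted for draw-order determinism
    p = np.array([table[c] for c in cats], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(cats), size=n, p=p)
    return np.asarray(cats, dtype=object)[idx]


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw a synthetic population of ``config.n`` children.

    Deterministic given ``config.seed``. Survey weights default to
    ``national_population / n`` (optionally modulated per fluoride stratum)
    and always sum to ``national_population``. Baseline caries is assigned
    from the configured age-group prevalences; children under 2 are
    caries-free. For model-consistent baseline assignment after calibration
    see :func:`fluorosim.risk.assign_baseline_caries`.
    """
    config.validate()
    n = config.n
    rng = np.random.default_rng(config.seed)

    if config.joint_age_race_income is not None:
        cells = sorted(config.joint_age_race_income)
        p = np.array([config.joint_age_race_income[c] for c in cells], dtype=float)
        idx = rng.choice(len(cells), size=n, p=p / p.sum())
        parts = [cells[i].split("|") for i in idx]
        groups = np.array([g for g, _, _ in parts], dtype=object)
        race = np.array([r for _, r, _ in parts], dtype=object)
        income = np.array([i for _, _, i in parts], dtype=object)
        lo = np.array([_JOINT_AGE_RANGES[g][0] for g in groups])
        hi = np.array([_JOINT_AGE_RANGES[g][1] for g in groups])
        ages = lo + (rng.random(n) * (hi - lo + 1)).astype(int)
    else:
        age_table = config.age
        ages = _draw_categorical(rng, age_table, n).astype(int)
        race = _draw_categorical(rng, config.race_ethnicity, n)
        income = _draw_categorical(rng, config.income_group, n)

    sex = _draw_categorical(rng, config.sex, n)
    insurance = _draw_categorical(rng, config.insurance, n)
    stratum = _draw_categorical(rng, config.fluoride_stratum, n)
    tap = rng.random(n) < config.p_tap_water

    groups = age_group_of(ages)
    base_p = np.array(
        [config.baseline_caries_prevalence.get(g, 0.0) for g in groups]
    )
    base_p = np.where(ages < 2, 0.0, base_p)
    baseline = rng.random(n) < base_p

    if config.stratum_weights:
        rel = np.array(
            [config.stratum_weights.get(s, 1.0) for s in stratum], dtype=float
        )
        weights = rel / rel.sum() * config.national_population
    else:
        weights = np.full(n, config.national_population / n)

    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "age": ages.astype(int),
            "age_group": groups.astype(str),
            "sex": sex.astype(str),
            "race_ethnicity": race.astype(str),
            "income_group": income.astype(str),
            "insurance": insurance.astype(str),
            "fluoride_stratum": stratum.astype(str),
            "drinks_tap_water": tap,
            "weight": weights,
            "baseline_caries": baseline,
        }
    )


# ---------------------------------------------------------------------------
# CSV round trip


def _check_enum(df: pd.DataFrame, column: str, allowed: Sequence[str]) -> None:
    bad = ~df[column].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise PopulationParseError(
            f"row {row}, column {column!r}: invalid value {df[column].iloc[row]!r}"
        )


def validate_population(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and invariants; returns the (typed) frame."""
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in POPULATION_COLUMNS]
    if missing or extra:
        raise PopulationParseError(
            f"bad columns: missing {missing}, unexpected {extra}"
        )
    df = df[list(POPULATION_COLUMNS)].copy()
    if len(df) == 0:
        return df
    df["id"] = df["id"].astype(int)
    df["age"] = df["age"].astype(int)
    df["weight"] = df["weight"].astype(float)
    for col in ("drinks_tap_water", "baseline_caries"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().map(
                {"true": True, "false": False}
            )
            if df[col].isna().any():
                row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
                raise PopulationParseError(
                    f"row {row}, column {col!r}: not a boolean"
                )
            df[col] = df[col].astype(bool)
    out_of_range = (df["age"] < 0) | (df["age"] > 19)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise PopulationParseError(
            f"row {row}, column 'age': {df['age'].iloc[row]} outside [0, 19]"
        )
    _check_enum(df, "age_group", AGE_GROUPS)
    _check_enum(df, "sex", SEXES)
    _check_enum(df, "race_ethnicity", RACE_ETHNICITIES)
    _check_enum(df, "income_group", INCOME_GROUPS)
    _check_enum(df, "insurance", INSURANCE_TYPES)
    _check_enum(df, "fluoride_stratum", FLUORIDE_STRATA)
    expected_group = pd.Series(age_group_of(df["age"].to_numpy()), index=df.index)
    mismatch = (df["age"] >= 2) & (df["age_group"] != expected_group)
    if mismatch.any():
        row = int(np.flatnonzero(mismatch.to_numpy())[0])
        raise PopulationParseError(
            f"row {row}, column 'age_group': inconsistent with age "
            f"{df['age'].iloc[row]}"
        )
    nonpos = df["weight"] <= 0
    if nonpos.any():
        row = int(np.flatnonzero(nonpos.to_numpy())[0])
        raise PopulationParseError(f"row {row}, column 'weight': must be > 0")
    return df


def write_population(profiles: pd.DataFrame | Iterable[ChildProfile], path) -> None:
    """Write a population to CSV (UTF-8, exact canonical column set)."""
    if not isinstance(profiles, pd.DataFrame):
        profiles = pd.DataFrame([p.__dict__ for p in profiles], columns=POPULATION_COLUMNS)
    validate_population(profiles).to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    """Read and validate a population CSV. A header-only file yields an
    empty population."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise PopulationParseError(f"{path}: empty file (no header)") from exc
    return validate_population(df)


def to_profiles(df: pd.DataFrame) -> list[ChildProfile]:
    """Dataclass view of a population frame."""
    return [ChildProfile(**rec) for rec in df.to_dict("records")]
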