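"""Caries risk, fluoride protection, fluorosis and mortality, and calibration.

The annual probability that a child develops a new decayed tooth is an
additive logistic function of age group, sex, race/ethnicity and income
(:class:`~fluorosim.parameters.CariesRiskModel`). Children protected by
community water fluoridation have that probability multiplied by
``1 - effectiveness`` (base case: a 25% relative reduction). Who is
protected depends on the policy scenario:

* ``status_quo`` - residents of optimally (0.6-1.5 mg/L) or excessively
  (>1.5 mg/L) fluoridated systems;
* ``remove_fluoride`` - nobody;
* ``optimize_fluoride`` - additionally residents of suboptimally
  (0.1-0.6 mg/L) fluoridated systems, with excessive systems brought down
  to optimal levels.

Under the ``tap_water_only`` protection model, protection further requires
that the child drinks tap water.

Residents of excessively fluoridated systems also face a risk of moderate
to severe dental fluorosis (cumulative probability over the simulated
horizon, converted to an annual hazard), eliminated by either policy change.

Because the baseline incidence is not directly observed, the age-group
intercepts are *calibrated* so that the model's status-quo cumulative
prevalence (the probability of having developed any caries by one's current
age) matches survey prevalence targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .parameters import (  # noqa: F401  (re-exported module surface)
    AGE_GROUPS,
    CariesRiskModel,
    DistributionSpec,
    ParameterSet,
    default_parameters,
)
from .population import age_group_of

__all__ = [
    "CalibrationTarget",
    "CalibrationError",
    "annual_caries_probability",
    "protection_status",
    "fluorosis_risk",
    "mortality_probability",
    "exposure_years",
    "cumulative_caries_probability",
    "predicted_prevalence",
    "calibrate",
    "assign_baseline_caries",
]


class CalibrationError(RuntimeError):
    """Calibration failed to reach its targets."""


@dataclass(frozen=True)
class CalibrationTarget:
    """Observed caries prevalence for one subgroup.

    ``race_ethnicity=None`` targets a whole age group; otherwise the
    (age group, race/ethnicity) cell.
    """

    age_group: str
    target_prevalence: float
    tolerance: float = 0.05
    race_ethnicity: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError(
                f"target_prevalence must be in (0, 1), got {self.target_prevalence}"
            )
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age_group {self.age_group!r}")


# ---------------------------------------------------------------------------
# per-child probabilities (vectorized over a population frame)


def _linear_predictor(population: pd.DataFrame, model: CariesRiskModel,
                      ages: np.ndarray | None = None) -> np.ndarray:
    ages = population["age"].to_numpy() if ages is None else np.asarray(ages)
    groups = age_group_of(ages)
    eta = np.array([model.intercepts[g] for g in groups])
    eta += np.array([model.sex[s] for s in population["sex"]])
    races = population["race_ethnicity"].to_numpy()
    eta += np.array([model.race_ethnicity[r] for r in races])
    eta += np.array([model.income_group[g] for g in population["income_group"]])
    if model.cell_adjustments:
        keys = np.char.add(np.char.add(groups.astype(str), "|"), races.astype(str))
        eta += np.array([model.cell_adjustments.get(k, 0.0) for k in keys])
    return eta


def annual_caries_probability(
    population: pd.DataFrame,
    params: ParameterSet,
    protected: np.ndarray | bool,
    ages: np.ndarray | None = None,
) -> np.ndarray:
    """Annual probability of a new decayed tooth for each child.

    ``protected`` children have the probability multiplied by
    ``1 - effectiveness``. ``ages`` overrides the frame's ages (used while
    children age during a simulation); under-2s have zero risk.
    """
    try:
        eta = _linear_predictor(population, params.baseline_logit, ages)
    except KeyError as exc:
        raise CalibrationError(f"missing risk coefficient for {exc}") from exc
    p = expit(eta)
    p = np.where(np.asarray(protected, dtype=bool), p * (1.0 - params.effectiveness), p)
    a = population["age"].to_numpy() if ages is None else np.asarray(ages)
    return np.where(a < 2, 0.0, p)


def protection_status(population: pd.DataFrame, scenario) -> np.ndarray:
    """Boolean mask: which children receive fluoride's protective benefit
    under the scenario. See module docstring for the policy rules."""
    stratum = population["fluoride_stratum"].to_numpy()
    policy = scenario.policy
    if policy == "remove_fluoride":
        protected = np.zeros(len(population), dtype=bool)
    elif policy == "status_quo":
        protected = np.isin(stratum, ("optimal", "excessive"))
    elif policy == "optimize_fluoride":
        protected = np.isin(stratum, ("suboptimal", "optimal", "excessive"))
    else:
        raise ValueError(f"unknown policy {policy!r}")
    if scenario.protection_model == "tap_water_only":
        protected &= population["drinks_tap_water"].to_numpy()
    elif scenario.protection_model != "all_residents":
        raise ValueError(f"unknown protection model {scenario.protection_model!r}")
    return protected


def fluorosis_risk(population: pd.DataFrame, params: ParameterSet, scenario) -> np.ndarray:
    """Annual fluorosis hazard per child.

    Nonzero only for the excessive stratum under the status quo (both
    removing and optimizing fluoride eliminate excessive levels). The
    published probability is cumulative over the horizon H, so the annual
    hazard h solves 1 - (1-h)**H = p.
    """
    h = np.zeros(len(population))
    if scenario.policy != "status_quo":
        return h
    p = params.p_fluorosis_excessive
    annual = 1.0 - (1.0 - p) ** (1.0 / scenario.horizon_years)
    h[population["fluoride_stratum"].to_numpy() == "excessive"] = annual
    return h


def mortality_probability(age, params: ParameterSet) -> np.ndarray | float:
    """Annual all-cause mortality probability from the configured band table
    (ages above the last band reuse its rate)."""
    scalar = np.isscalar(age)
    ages = np.atleast_1d(np.asarray(age, dtype=int))
    bands = []
    for key, q in params.mortality.items():
        lo, hi = (int(x) for x in key.split("-"))
        bands.append((lo, hi, float(q)))
    bands.sort()
    out = np.full(ages.shape, bands[-1][2], dtype=float)
    for lo, hi, q in bands:
        out[(ages >= lo) & (ages <= hi)] = q
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# calibration


def exposure_years(age) -> np.ndarray:
    """Completed years of caries risk exposure by the current age (risk runs
    from age 2, so a child aged a has accrued max(a-1, 0) risk-years)."""
    return np.clip(np.asarray(age) - 1, 0, None)


def cumulative_caries_probability(
    population: pd.DataFrame, params: ParameterSet, scenario=None
) -> np.ndarray:
    """Deterministic per-child probability of prevalent caries at the
    current age, i.e. 1 - (1-p_annual)^exposure_years under the reference
    (default status-quo, all-residents) protection pattern."""
    from .simulator import ScenarioSpec  # local import avoids a cycle

    if scenario is None:
        scenario = ScenarioSpec("status_quo", "all_residents", 5)
    protected = protection_status(population, scenario)
    p = annual_caries_probability(population, params, protected)
    r = exposure_years(population["age"].to_numpy())
    return 1.0 - (1.0 - p) ** r


def predicted_prevalence(
    population: pd.DataFrame, params: ParameterSet, targets, scenario=None
) -> dict:
    """Expected (deterministic) weighted prevalence for each target subgroup."""
    probs = cumulative_caries_probability(population, params, scenario)
    w = population["weight"].to_numpy()
    out = {}
    for t in targets:
        mask = _target_mask(population, t)
        if not mask.any():
            raise CalibrationError(f"no children in subgroup {t}")
        out[_target_key(t)] = float(
            np.average(probs[mask], weights=w[mask])
        )
    return out


def _target_mask(population: pd.DataFrame, t: CalibrationTarget) -> np.ndarray:
    mask = population["age_group"].to_numpy() == t.age_group
    # under-2s belong to no calibration subgroup (zero risk until age-in)
    mask &= population["age"].to_numpy() >= 2
    if t.race_ethnicity is not None:
        mask &= population["race_ethnicity"].to_numpy() == t.race_ethnicity
    return mask


def _target_key(t: CalibrationTarget) -> str:
    return t.age_group if t.race_ethnicity is None else f"{t.age_group}|{t.race_ethnicity}"


def calibrate(
    population: pd.DataFrame,
    params: ParameterSet,
    targets: list[CalibrationTarget],
    horizon_to_age: bool = True,
    scenario=None,
    bracket: tuple[float, float] = (-12.0, 8.0),
    xtol: float = 1e-10,
) -> ParameterSet:
    """Set baseline-risk intercepts so the model reproduces the targets.

    For each target subgroup, the intercept (or, for race-specific targets,
    the (age group, race) cell adjustment) is found by deterministic
    root-finding on the closed-form cohort expectation of status-quo
    prevalence -- no Monte Carlo, so calibration is exactly reproducible
    and idempotent. With ``horizon_to_age`` (default) the expectation is
    cumulative prevalence at the child's current age; otherwise it is the
    probability of developing caries within the scenario horizon.

    Raises :class:`CalibrationError` if any subgroup is empty or its target
    cannot be bracketed.
    """
    from .simulator import ScenarioSpec

    if scenario is None:
        scenario = ScenarioSpec("status_quo", "all_residents", 5)
    params = params.replace(baseline_logit=params.baseline_logit.copy())
    model = params.baseline_logit
    protected = protection_status(population, scenario)
    w = population["weight"].to_numpy()
    ages = population["age"].to_numpy()
    r = exposure_years(ages) if horizon_to_age else np.full(len(ages), scenario.horizon_years)

    age_targets = [t for t in targets if t.race_ethnicity is None]
    race_targets = [t for t in targets if t.race_ethnicity is not None]

    def solve(t: CalibrationTarget, apply):
        mask = _target_mask(population, t)
        if not mask.any():
            raise CalibrationError(f"empty calibration subgroup {_target_key(t)!r}")
        sub = population.loc[mask]
        wm, rm, pm = w[mask], r[mask], protected[mask]

        def err(x: float) -> float:
            apply(x)
            p = annual_caries_probability(sub, params, pm)
            prev = np.average(1.0 - (1.0 - p) ** rm, weights=wm)
            return prev - t.target_prevalence

        lo, hi = bracket
        if err(lo) > 0 or err(hi) < 0:
            raise CalibrationError(
                f"target {t.target_prevalence} for {_target_key(t)!r} not "
                f"bracketed in logit range {bracket}"
            )
        root = brentq(err, lo, hi, xtol=xtol)
        apply(root)

    for t in age_targets:
        solve(t, lambda x, g=t.age_group: model.intercepts.__setitem__(g, x))
    for t in race_targets:
        key = f"{t.age_group}|{t.race_ethnicity}"
        solve(t, lambda x, k=key: model.cell_adjustments.__setitem__(k, x))

    calibrated = params.replace(calibrated=True)
    # verify: deterministic expectations must sit within each tolerance
    achieved = predicted_prevalence(population, calibrated, targets, scenario)
    worst = max(
        ((abs(achieved[_target_key(t)] - t.target_prevalence), t) for t in targets),
        key=lambda x: x[0],
    )
    if worst[0] > worst[1].tolerance:
        raise CalibrationError(
            f"worst subgroup {_target_key(worst[1])!r}: "
            f"absolute error {worst[0]:.4f} exceeds tolerance"
        )
    return calibrated


def assign_baseline_caries(
    population: pd.DataFrame, params: ParameterSet, seed: int, scenario=None
) -> pd.DataFrame:
    """Redraw ``baseline_caries`` from the calibrated model's per-child
    cumulative probabilities (model-consistent initial state)."""
    probs = cumulative_caries_probability(population, params, scenario)
    rng = np.random.default_rng(seed)
    out = population.copy()
    out["baseline_caries"] = rng.random(len(population)) < probs
    return out
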