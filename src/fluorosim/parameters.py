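"""Model parameters, their uncertainty distributions, and (de)serialization.

Every quantity that drives the simulation lives in a :class:`ParameterSet`:
the effectiveness of water fluoridation (relative reduction in annual caries
risk for protected children), the probabilities along the untreated-caries
complication pathway, disutility weights (annual QALY decrements for disease
states), unit treatment costs in 2024 USD, the annual per-capita cost of
running a fluoridation program, the discount rate, the calibrated baseline
caries-risk coefficients, and an all-cause child mortality table.

Each uncertain parameter also carries a :class:`DistributionSpec` describing
its probabilistic-sensitivity-analysis distribution: beta for probabilities
and disutility weights, gamma for costs, matched to the published mean/SD (or
a PERT-style scaled beta when only a base case and range are published).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "RACE_ETHNICITIES",
    "INCOME_GROUPS",
    "INSURANCE_TYPES",
    "FLUORIDE_STRATA",
    "DistributionSpec",
    "CariesRiskModel",
    "ParameterSet",
    "default_parameters",
    "default_distribution_specs",
    "config_hash",
]

AGE_GROUPS = ("2-5", "6-12", "13-19")
SEXES = ("female", "male")
RACE_ETHNICITIES = ("hispanic", "nh_black", "nh_white", "other")
INCOME_GROUPS = ("low", "middle", "high")
INSURANCE_TYPES = ("private", "public", "uninsured")
FLUORIDE_STRATA = ("below_detection", "suboptimal", "optimal", "excessive")

#: Parameters that may be varied in sensitivity analyses.
UNCERTAIN_PARAMETERS = (
    "effectiveness",
    "p_untreated",
    "p_abscess_given_untreated",
    "p_toothloss_given_untreated",
    "p_fluorosis_excessive",
    "disutility_caries",
    "disutility_abscess",
    "disutility_toothloss",
    "cost_exam",
    "cost_caries",
    "cost_abscess",
    "cost_extraction",
    "cost_fluorosis",
    "fluoridation_cost_per_capita_yr",
)


class SpecError(ValueError):
    """Raised for an invalid distribution specification."""


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty distribution of one scalar parameter.

    Parameters
    ----------
    family
        ``"beta"``, ``"gamma"`` or ``"fixed"``.
    mean
        Base-case value. For a range-only beta (``sd is None``) it is
        treated as the distribution's mode (PERT-style).
    sd
        Standard deviation used for moment matching; ``0`` degenerates to
        the mean, ``None`` (beta only) selects the PERT parameterization
        on ``[lower, upper]``.
    lower, upper
        Optional truncation bounds (the published range).
    """

    family: str
    mean: float
    sd: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise SpecError(f"unknown distribution family {self.family!r}")
        if self.sd is not None and self.sd < 0:
            raise SpecError("sd must be >= 0")
        if self.family == "gamma" and self.mean <= 0:
            raise SpecError("gamma requires mean > 0")
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise SpecError("requires lower < upper")
        if self.family == "beta":
            lo = 0.0 if self.lower is None else self.lower
            hi = 1.0 if self.upper is None else self.upper
            if not (0.0 <= lo < hi <= 1.0):
                raise SpecError("beta requires 0 <= lower < upper <= 1")
            if self.sd is None and (self.lower is None or self.upper is None):
                raise SpecError("range-only beta needs explicit lower and upper")


@dataclass
class CariesRiskModel:
    """Additive logistic model for the annual caries-incidence probability.

    logit(p) = intercept[age_group] + sex[s] + race_ethnicity[r]
               + income_group[g] (+ cell_adjustment[age_group|race]).

    Intercepts (and, when race-specific calibration targets are supplied,
    the per-(age group, race) cell adjustments) are set by calibration; the
    covariate coefficients encode relative disparities and are configurable.
    """

    intercepts: dict[str, float] = field(
        default_factory=lambda: {g: -2.5 for g in AGE_GROUPS}
    )
    sex: dict[str, float] = field(
        default_factory=lambda: {"female": 0.0, "male": 0.0}
    )
    race_ethnicity: dict[str, float] = field(
        default_factory=lambda: {
            "hispanic": 0.30,
            "nh_black": 0.20,
            "nh_white": 0.0,
            "other": 0.10,
        }
    )
    income_group: dict[str, float] = field(
        default_factory=lambda: {"low": 0.40, "middle": 0.20, "high": 0.0}
    )
    # keys "age_group|race_ethnicity", populated by race-specific calibration
    cell_adjustments: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "CariesRiskModel":
        return CariesRiskModel(
            intercepts=dict(self.intercepts),
            sex=dict(self.sex),
            race_ethnicity=dict(self.race_ethnicity),
            income_group=dict(self.income_group),
            cell_adjustments=dict(self.cell_adjustments),
        )


#: Annual all-cause mortality probability by age band (order-of-magnitude
#: child rates; configurable). Band keys are "lo-hi" inclusive ranges.
DEFAULT_MORTALITY = {"0-4": 2.5e-4, "5-14": 1.5e-4, "15-19": 5.0e-4}


@dataclass
class ParameterSet:
    """One concrete value for every model parameter.

    Probabilities are annual unless noted; costs are 2024 USD.
    """

    effectiveness: float = 0.25  # relative caries-risk reduction if protected
    p_untreated: float = 0.72
    p_abscess_given_untreated: float = 0.321
    p_toothloss_given_untreated: float = 0.766
    p_fluorosis_excessive: float = 0.07  # cumulative over the horizon
    disutility_caries: float = 0.010
    disutility_abscess: float = 0.069
    disutility_toothloss: float = 0.067
    cost_exam: float = 185.0
    cost_caries: float = 530.0
    cost_abscess: float = 818.0
    cost_extraction: float = 181.0
    cost_fluorosis: float = 1468.0
    fluoridation_cost_per_capita_yr: float = 0.8
    discount_rate: float = 0.03
    baseline_logit: CariesRiskModel = field(default_factory=CariesRiskModel)
    mortality: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MORTALITY)
    )
    calibrated: bool = False

    def __post_init__(self) -> None:
        for name in (
            "effectiveness",
            "p_untreated",
            "p_abscess_given_untreated",
            "p_toothloss_given_untreated",
            "p_fluorosis_excessive",
            "disutility_caries",
            "disutility_abscess",
            "disutility_toothloss",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.effectiveness >= 1.0:
            raise ValueError("effectiveness must be < 1")
        for name in (
            "cost_exam",
            "cost_caries",
            "cost_abscess",
            "cost_extraction",
            "cost_fluorosis",
            "fluoridation_cost_per_capita_yr",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        for band, q in self.mortality.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"mortality[{band}]={q} outside [0, 1]")

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given scalar fields replaced."""
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        d = dict(d)
        bl = d.get("baseline_logit")
        if isinstance(bl, Mapping):
            d["baseline_logit"] = CariesRiskModel(
                intercepts=dict(bl["intercepts"]),
                sex=dict(bl["sex"]),
                race_ethnicity=dict(bl["race_ethnicity"]),
                income_group=dict(bl["income_group"]),
                cell_adjustments=dict(bl.get("cell_adjustments", {})),
            )
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_parameters() -> ParameterSet:
    """Base-case parameter set (uncalibrated baseline risk)."""
    return ParameterSet()


def default_distribution_specs() -> dict[str, DistributionSpec]:
    """Published uncertainty distribution for each uncertain parameter.

    Probabilities and disutilities are beta (moment-matched when an SD is
    published, PERT-style on the published range otherwise); costs are gamma
    moment-matched to mean/SD and truncated to the published range.
    """
    return {
        "effectiveness": DistributionSpec("beta", 0.25, None, 0.075, 0.35),
        "p_untreated": DistributionSpec("beta", 0.72, None, 0.458, 0.72),
        "p_abscess_given_untreated": DistributionSpec("beta", 0.321, None, 0.30, 0.464),
        "p_toothloss_given_untreated": DistributionSpec("beta", 0.766, None, 0.663, 0.855),
        "p_fluorosis_excessive": DistributionSpec("beta", 0.07, None, 0.07, 0.12),
        "disutility_caries": DistributionSpec("beta", 0.010, 0.003, 0.004, 0.019),
        "disutility_abscess": DistributionSpec("beta", 0.069, 0.015, 0.029, 0.110),
        "disutility_toothloss": DistributionSpec("beta", 0.067, 0.013, 0.045, 0.095),
        "cost_exam": DistributionSpec("gamma", 185.0, 10.0, 45.0, 210.0),
        "cost_caries": DistributionSpec("gamma", 530.0, 20.0, 325.0, 977.0),
        "cost_abscess": DistributionSpec("gamma", 818.0, 45.0, 309.0, 1220.0),
        "cost_extraction": DistributionSpec("gamma", 181.0, 10.0, 96.0, 360.0),
        "cost_fluorosis": DistributionSpec("gamma", 1468.0, 420.0, 1050.0, 1850.0),
        "fluoridation_cost_per_capita_yr": DistributionSpec("gamma", 0.8, 3.5, 0.6, 15.0),
    }


def config_hash(obj) -> str:
    """Stable short hash of any YAML-serializable configuration object."""
    payload = yaml.safe_dump(obj, sort_keys=True).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:16]
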