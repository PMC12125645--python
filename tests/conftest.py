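import numpy as np
import pandas as pd
import pytest

import fluorosim as fs

PREVALENCE_TARGETS = {"2-5": 0.213, "6-12": 0.516, "13-19": 0.572}


def make_targets():
    return [fs.CalibrationTarget(g, p) for g, p in PREVALENCE_TARGETS.items()]


def homogeneous_population(n, *, age=10, stratum="below_detection", weight_total=None,
                           baseline=False, tap=True):
    """n identical children (useful for closed-form oracles)."""
    w = (weight_total or float(n)) / n
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "age": np.full(n, age),
            "age_group": np.full(n, fs.population.age_group_of(age)),
            "sex": np.full(n, "female"),
            "race_ethnicity": np.full(n, "nh_white"),
            "income_group": np.full(n, "high"),
            "insurance": np.full(n, "private"),
            "fluoride_stratum": np.full(n, stratum),
            "drinks_tap_water": np.full(n, tap),
            "weight": np.full(n, w),
            "baseline_caries": np.full(n, baseline),
        }
    )


def params_with_annual_probability(p, **overrides):
    """ParameterSet whose annual caries probability is exactly p for every
    child (all covariate coefficients zeroed), mortality off."""
    from scipy.special import logit

    model = fs.CariesRiskModel(
        intercepts={g: float(logit(p)) for g in ("2-5", "6-12", "13-19")},
        sex={"female": 0.0, "male": 0.0},
        race_ethnicity={r: 0.0 for r in ("hispanic", "nh_black", "nh_white", "other")},
        income_group={"low": 0.0, "middle": 0.0, "high": 0.0},
    )
    base = dict(
        baseline_logit=model,
        mortality={"0-19": 0.0},
        calibrated=True,
    )
    base.update(overrides)
    return fs.default_parameters().replace(**base)


@pytest.fixture(scope="session")
def base_population():
    """Mid-sized synthetic cohort used across tests."""
    return fs.generate_population(fs.PopulationConfig(n=6000, seed=11))


@pytest.fixture(scope="session")
def calibrated(base_population):
    """(population-with-model-consistent-baseline, calibrated params)."""
    params = fs.calibrate(base_population, fs.default_parameters(), make_targets())
    pop = fs.assign_baseline_caries(base_population, params, seed=12)
    return pop, params
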