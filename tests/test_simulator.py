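"""Simulation engine: discounting, oracles, common random numbers,
conservation and monotonicity properties."""

import numpy as np
import pytest

import fluorosim as fs
from fluorosim.simulator import draw_uniforms

from conftest import homogeneous_population, params_with_annual_probability


# ---------------------------------------------------------------------------
# discount factor


@pytest.mark.parametrize(
    "cycle, rate, expected",
    [(0, 0.03, 1.0), (5, 0.03, 0.862609), (7, 0.0, 1.0), (3, 0.0, 1.0)],
)
def test_discount_factor(cycle, rate, expected):
    assert fs.discount_factor(cycle, rate) == pytest.approx(expected, abs=1e-6)


def test_discount_factor_rejects_negative_cycle():
    with pytest.raises(ValueError):
        fs.discount_factor(-1, 0.03)


# ---------------------------------------------------------------------------
# degenerate and closed-form oracles


def test_null_model_generates_no_events():
    pop = homogeneous_population(2000, age=8)
    params = params_with_annual_probability(0.0)
    res = fs.run_scenario(pop, params, fs.ScenarioSpec("status_quo"), seed=5)
    assert res.event_totals["incident"] == 0
    assert res.total_qaly_loss == 0.0
    assert res.total_cost == res.cost_components["program"]  # program cost only
    assert (res.child_decayed == 0).all()


def test_homogeneous_cohort_matches_closed_forms():
    """Monte Carlo means of decayed teeth and end prevalence match the
    independent-annual-indicator closed forms H*p and 1-(1-p)^H within
    3 Monte Carlo standard errors (n = 100000)."""
    n, p, H = 100_000, 0.1, 5
    pop = homogeneous_population(n, age=8)
    params = params_with_annual_probability(p)
    res = fs.run_scenario(pop, params, fs.ScenarioSpec("status_quo", horizon_years=H), seed=17)

    mean_teeth = res.child_decayed.mean()
    se_teeth = np.sqrt(H * p * (1 - p) / n)
    assert abs(mean_teeth - H * p) < 3 * se_teeth

    prev = res.prevalence_end
    p_ever = 1 - (1 - p) ** H
    se_prev = np.sqrt(p_ever * (1 - p_ever) / n)
    assert abs(prev - p_ever) < 3 * se_prev


def test_homogeneous_cohort_cost_and_qaly_match_expectation():
    """Discounted per-child cost and QALY loss match their deterministic
    cohort expectations within 3 MC standard errors."""
    n, p, H = 100_000, 0.1, 5
    pop = homogeneous_population(n, age=8)
    params = params_with_annual_probability(p)
    res = fs.run_scenario(pop, params, fs.ScenarioSpec("status_quo", horizon_years=H), seed=19)

    pu = params.p_untreated
    pa = params.p_abscess_given_untreated
    pl = params.p_toothloss_given_untreated
    cost_per_incident = (
        (1 - pu) * (params.cost_exam + params.cost_caries)
        + pu * (pa * params.cost_abscess + pl * params.cost_extraction)
    )
    disc = np.array([fs.discount_factor(t, params.discount_rate) for t in range(H)])
    expected_cost = p * cost_per_incident * disc.sum()

    # QALY loss: caries state = incident now or persistent untreated tooth;
    # abscess transient; tooth loss chronic from extraction cycle onward.
    q_persist = p * pu * (1 - pl)   # per-cycle probability of a new persistent untreated tooth
    q_loss = p * pu * pl
    expected_qaly = 0.0
    for t in range(H):
        p_caries_state = 1 - (1 - q_persist) ** t * (1 - p)
        p_abscess = p * pu * pa
        p_any_loss = 1 - (1 - q_loss) ** (t + 1)
        expected_qaly += disc[t] * (
            params.disutility_caries * p_caries_state
            + params.disutility_abscess * p_abscess
            + params.disutility_toothloss * p_any_loss
        )

    # per-cycle cost variance from the event mixture (discounting <= 1)
    e_cost2 = (
        (1 - pu) * (params.cost_exam + params.cost_caries) ** 2
        + pu * (pa * params.cost_abscess**2 + pl * params.cost_extraction**2)
    )
    var_cycle = p * e_cost2 - (p * cost_per_incident) ** 2
    se_cost = 3 * np.sqrt(var_cycle * H / n)
    assert abs(res.child_cost.mean() - expected_cost) < se_cost
    se_qaly = 3 * np.sqrt(0.146**2 * H / n)
    assert abs(res.child_qaly_loss.mean() - expected_qaly) < se_qaly


# ---------------------------------------------------------------------------
# common random numbers


def test_null_effect_scenarios_identical_under_shared_stream(calibrated):
    """With zero effectiveness and no fluorosis, removing fluoride changes
    nothing except the fluoridation program cost (exact CRN equivalence)."""
    pop, params = calibrated
    params0 = params.replace(effectiveness=0.0, p_fluorosis_excessive=0.0)
    inc = fs.run_incremental(
        pop,
        params0,
        fs.ScenarioSpec("remove_fluoride"),
        fs.ScenarioSpec("status_quo"),
        seed=23,
    )
    assert inc.d_prevalence_pp == 0.0
    assert inc.d_decayed_teeth == 0.0
    assert inc.d_fluorosis == 0.0
    assert inc.d_qalys == 0.0
    assert inc.d_cost_usd == pytest.approx(inc.cost_components["program"])
    assert inc.cost_components["program"] < 0  # removal saves program cost


def test_self_comparison_yields_all_zero(calibrated):
    pop, params = calibrated
    sq = fs.ScenarioSpec("status_quo")
    inc = fs.run_incremental(pop, params, sq, sq, seed=29)
    assert inc.d_prevalence_pp == 0.0
    assert inc.d_decayed_teeth == 0.0
    assert inc.d_fluorosis == 0.0
    assert inc.d_qalys == 0.0
    assert inc.d_cost_usd == 0.0


def test_removing_fluoride_worsens_outcomes(calibrated):
    pop, params = calibrated
    inc = fs.run_incremental(
        pop, params, fs.ScenarioSpec("remove_fluoride"), fs.ScenarioSpec("status_quo"), seed=31
    )
    assert inc.d_prevalence_pp > 0
    assert inc.d_decayed_teeth > 0
    assert inc.d_qalys < 0          # QALYs lost
    assert inc.d_cost_usd > 0
    assert inc.d_fluorosis <= 0     # excessive-stratum fluorosis disappears


def test_optimizing_fluoride_improves_outcomes(calibrated):
    pop, params = calibrated
    inc = fs.run_incremental(
        pop, params, fs.ScenarioSpec("optimize_fluoride"), fs.ScenarioSpec("status_quo"), seed=31
    )
    assert inc.d_prevalence_pp < 0
    assert inc.d_decayed_teeth < 0
    assert inc.d_qalys > 0
    assert inc.d_fluorosis <= 0


def test_monotonicity_in_effectiveness(calibrated):
    """Higher effectiveness weakly lowers status-quo prevalence and weakly
    widens the removal increment (exact under a shared stream)."""
    pop, params = calibrated
    sq, rm = fs.ScenarioSpec("status_quo"), fs.ScenarioSpec("remove_fluoride")
    prev, incs = [], []
    for eff in (0.075, 0.25, 0.35):
        p = params.replace(effectiveness=eff)
        res = fs.run_scenario(pop, p, sq, seed=37)
        prev.append(res.prevalence_end)
        incs.append(fs.run_incremental(pop, p, rm, sq, seed=37).d_prevalence_pp)
    assert prev[0] >= prev[1] >= prev[2]
    assert incs[0] <= incs[1] <= incs[2]


def test_tap_water_only_increment_weakly_smaller(calibrated):
    """Restricting protection to tap-water drinkers shrinks the removal
    increment (protected set is a subset; CRN makes this exact)."""
    pop, params = calibrated
    inc_all = fs.run_incremental(
        pop, params,
        fs.ScenarioSpec("remove_fluoride", "all_residents"),
        fs.ScenarioSpec("status_quo", "all_residents"), seed=41,
    )
    inc_tap = fs.run_incremental(
        pop, params,
        fs.ScenarioSpec("remove_fluoride", "tap_water_only"),
        fs.ScenarioSpec("status_quo", "tap_water_only"), seed=41,
    )
    assert 0 <= inc_tap.d_prevalence_pp <= inc_all.d_prevalence_pp
    assert 0 <= inc_tap.d_decayed_teeth <= inc_all.d_decayed_teeth


def test_seed_determinism_and_uniform_stream_shape(calibrated):
    pop, params = calibrated
    sq = fs.ScenarioSpec("status_quo")
    a = fs.run_scenario(pop, params, sq, seed=43)
    b = fs.run_scenario(pop, params, sq, seed=43)
    assert (a.child_decayed == b.child_decayed).all()
    assert a.total_cost == b.total_cost
    U = draw_uniforms(43, 10, 5)
    assert U.shape == (10, 5, 6)


# ---------------------------------------------------------------------------
# conservation and structural invariants


def test_event_stream_conservation(calibrated):
    pop, params = calibrated
    res = fs.run_scenario(pop, params, fs.ScenarioSpec("status_quo", horizon_years=10), seed=47)
    ev = res.event_totals
    assert ev["treated"] + ev["untreated"] == ev["incident"]
    assert ev["abscess"] <= ev["untreated"]
    assert ev["extraction"] <= ev["untreated"]
    assert (res.child_teeth_lost <= res.child_decayed).all()
    assert res.per_cycle["cum_incident_teeth_weighted"].is_monotonic_increasing
    assert res.per_cycle["cum_cost_weighted"].is_monotonic_increasing
    assert res.per_cycle["prevalence"].between(0, 1).all()


def test_at_most_one_tooth_per_cycle():
    pop = homogeneous_population(5000, age=8)
    params = params_with_annual_probability(0.95)
    res = fs.run_scenario(pop, params, fs.ScenarioSpec("status_quo", horizon_years=3), seed=51)
    assert res.child_decayed.max() <= 3


def test_cost_linearity_in_unit_price(calibrated):
    """Doubling the restoration price doubles the restoration component of
    the incremental cost exactly (shared seed)."""
    pop, params = calibrated
    sq, rm = fs.ScenarioSpec("status_quo"), fs.ScenarioSpec("remove_fluoride")
    inc1 = fs.run_incremental(pop, params, rm, sq, seed=53)
    inc2 = fs.run_incremental(
        pop,
        params.replace(cost_caries=2 * params.cost_caries, cost_exam=2 * params.cost_exam),
        rm, sq, seed=53,
    )
    assert inc2.cost_components["restoration"] == pytest.approx(
        2 * inc1.cost_components["restoration"], rel=1e-12
    )
    assert inc2.cost_components["complication"] == pytest.approx(
        inc1.cost_components["complication"], rel=1e-12
    )


def test_run_scenario_requires_calibrated_params(calibrated):
    pop, params = calibrated
    with pytest.raises(ValueError, match="calibrated"):
        fs.run_scenario(pop, params.replace(calibrated=False), fs.ScenarioSpec("status_quo"), seed=1)


def test_mismatched_horizons_rejected(calibrated):
    pop, params = calibrated
    with pytest.raises(ValueError, match="horizon"):
        fs.run_incremental(
            pop, params,
            fs.ScenarioSpec("remove_fluoride", horizon_years=5),
            fs.ScenarioSpec("status_quo", horizon_years=10),
            seed=1,
        )


def test_invalid_scenario_spec_rejected():
    with pytest.raises(ValueError):
        fs.ScenarioSpec("status_quo", horizon_years=0)
    with pytest.raises(ValueError):
        fs.ScenarioSpec("ban_toothpaste")
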