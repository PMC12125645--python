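"""Probabilistic and one-way (tornado) sensitivity analysis.

The probabilistic sensitivity analysis (PSA) redraws every uncertain
parameter from its published distribution each iteration -- beta for
probabilities and disutility weights, gamma for costs, both moment-matched
to the published mean/SD (or a PERT-style scaled beta with mode at the base
case when only a range is published) -- then recomputes the incremental
outcome with common random numbers across the compared scenarios. Empirical
2.5th/97.5th percentiles over iterations form 95% uncertainty intervals.

The one-way analysis sets one parameter at a time to its lower and upper
bound (all others at base case, simulation stream fixed) and ranks
parameters by the induced range of each outcome ("tornado" ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import IncrementalResult
from .parameters import DistributionSpec, ParameterSet, SpecError
from .simulator import ScenarioSpec, run_incremental

__all__ = [
    "PSASummary",
    "TornadoEntry",
    "sample_value",
    "sample_parameters",
    "run_psa",
    "one_way_sensitivity",
    "plot_tornado",
    "PSA_OUTCOMES",
]

PSA_OUTCOMES = ("d_prevalence_pp", "d_decayed_teeth", "d_fluorosis", "d_qalys", "d_cost_usd")

_PERT_LAMBDA = 4.0
_MAX_TRUNCATION_ATTEMPTS = 1000


def _beta_moment_shapes(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise SpecError(
            f"beta moment matching impossible: mean={mean}, sd={sd} imply nu<=0"
        )
    return mean * nu, (1.0 - mean) * nu


def _truncated(draw, lower, upper, rng) -> float:
    x = draw(rng)
    attempts = 0
    while (lower is not None and x < lower) or (upper is not None and x > upper):
        attempts += 1
        if attempts >= _MAX_TRUNCATION_ATTEMPTS:
            raise SpecError("truncation resampling exceeded 1000 attempts")
        x = draw(rng)
    return float(x)


def sample_value(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value from a parameter's uncertainty distribution.

    * ``fixed`` or ``sd == 0``: the mean, always.
    * ``beta`` with mean/sd: moment-matched shapes
      (nu = m(1-m)/sd^2 - 1, a = m*nu, b = (1-m)*nu), then resampled into
      [lower, upper] if bounds are given.
    * ``beta`` range-only (sd None): PERT-style scaled beta on
      [lower, upper] with mode at the base-case value (lambda = 4).
    * ``gamma``: shape = (mean/sd)^2, scale = sd^2/mean, resampled into the
      published range.
    """
    if spec.family == "fixed" or (spec.sd is not None and spec.sd == 0.0):
        return float(spec.mean)
    if spec.family == "beta":
        if spec.sd is None:
            lo, hi, mode = spec.lower, spec.upper, spec.mean
            a = 1.0 + _PERT_LAMBDA * (mode - lo) / (hi - lo)
            b = 1.0 + _PERT_LAMBDA * (hi - mode) / (hi - lo)
            return float(lo + (hi - lo) * rng.beta(a, b))
        a, b = _beta_moment_shapes(spec.mean, spec.sd)
        return _truncated(lambda r: r.beta(a, b), spec.lower, spec.upper, rng)
    if spec.family == "gamma":
        shape = (spec.mean / spec.sd) ** 2
        scale = spec.sd**2 / spec.mean
        return _truncated(
            lambda r: r.gamma(shape, scale), spec.lower, spec.upper, rng
        )
    raise SpecError(f"unknown family {spec.family!r}")


def sample_parameters(
    specs: dict[str, DistributionSpec],
    rng: np.random.Generator,
    base: ParameterSet | None = None,
) -> ParameterSet:
    """One joint parameter draw; fields without a spec keep base values
    (including the calibrated risk coefficients)."""
    base = base if base is not None else ParameterSet()
    draws = {name: sample_value(spec, rng) for name, spec in sorted(specs.items())}
    return base.replace(**draws)


@dataclass
class PSASummary:
    """Per-iteration outcomes and their percentile summary.

    ``summary`` has one row per outcome with columns mean/lo95/hi95;
    percentiles are empirical (linear interpolation between order
    statistics).
    """

    iterations: pd.DataFrame
    summary: pd.DataFrame
    n_iterations: int
    master_seed: int


def run_psa(
    population: pd.DataFrame,
    specs: dict[str, DistributionSpec],
    scenario: ScenarioSpec,
    reference: ScenarioSpec,
    n_iter: int,
    master_seed: int,
    base_params: ParameterSet,
    simulation_seed: int | None = None,
    progress_every: int | None = None,
) -> PSASummary:
    """Monte Carlo PSA of the incremental comparison.

    Iteration ``i`` uses parameter draw ``i`` (from a SeedSequence spawned
    off ``master_seed``) and a per-iteration simulation seed -- unless
    ``simulation_seed`` pins the event stream, in which case only parameter
    uncertainty propagates. The same synthetic population is reused across
    iterations; parameter draws are shared by both scenarios within an
    iteration (coupled comparison).
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_iter)
    records = []
    for i, child in enumerate(children):
        try:
            rng = np.random.default_rng(child)
            params_i = sample_parameters(specs, rng, base=base_params)
            seed_i = (
                simulation_seed
                if simulation_seed is not None
                else int(child.generate_state(1, dtype=np.uint32)[0] >> 1)
            )
            inc = run_incremental(population, params_i, scenario, reference, seed_i)
        except Exception as exc:  # pragma: no cover - abort semantics
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
        rec = {"iteration": i, "simulation_seed": seed_i}
        rec.update({f"param_{k}": getattr(params_i, k) for k in sorted(specs)})
        rec.update({k: getattr(inc, k) for k in PSA_OUTCOMES})
        records.append(rec)
        if progress_every and (i + 1) % progress_every == 0:
            import logging

            logging.getLogger(__name__).info("PSA iteration %d/%d", i + 1, n_iter)

    iterations = pd.DataFrame.from_records(records)
    rows = []
    for outcome in PSA_OUTCOMES:
        vals = iterations[outcome].to_numpy()
        lo, hi = np.percentile(vals, [2.5, 97.5], method="linear")
        rows.append(
            {"outcome": outcome, "mean": float(vals.mean()),
             "lo95": float(lo), "hi95": float(hi)}
        )
    return PSASummary(
        iterations=iterations,
        summary=pd.DataFrame(rows).set_index("outcome"),
        n_iterations=n_iter,
        master_seed=master_seed,
    )


@dataclass
class TornadoEntry:
    """Outcome swing from setting one parameter to its bounds."""

    parameter: str
    at_lower: float
    at_upper: float

    @property
    def range(self) -> float:
        return abs(self.at_upper - self.at_lower)


def one_way_sensitivity(
    population: pd.DataFrame,
    specs: dict[str, DistributionSpec],
    parameter_names: list[str],
    scenario: ScenarioSpec,
    reference: ScenarioSpec,
    seed: int,
    base_params: ParameterSet,
    outcomes: tuple[str, ...] = ("d_cost_usd", "d_qalys"),
) -> dict[str, list[TornadoEntry]]:
    """One-way sensitivity at parameter extremes, tornado-ordered.

    For each named parameter, the incremental comparison is rerun with that
    parameter at its lower then upper bound, all others at base case, and a
    shared simulation stream. Returns, per outcome, entries sorted by
    descending range.
    """
    lows, highs = {}, {}
    for name in parameter_names:
        if name not in specs:
            raise ValueError(f"unknown parameter {name!r}")
        spec = specs[name]
        if spec.lower is None or spec.upper is None:
            raise ValueError(f"parameter {name!r} has no lower/upper bounds")
        for store, value in ((lows, spec.lower), (highs, spec.upper)):
            params = base_params.replace(**{name: value})
            store[name] = run_incremental(population, params, scenario, reference, seed)

    result: dict[str, list[TornadoEntry]] = {}
    for outcome in outcomes:
        entries = [
            TornadoEntry(
                parameter=name,
                at_lower=float(getattr(lows[name], outcome)),
                at_upper=float(getattr(highs[name], outcome)),
            )
            for name in parameter_names
        ]
        entries.sort(key=lambda e: (-e.range, e.parameter))
        result[outcome] = entries
    return result


def plot_tornado(entries: list[TornadoEntry], base_value: float, path,
                 title: str = "") -> None:
    """Export a tornado diagram as SVG (largest swing on top)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.5 * len(entries) + 1.5))
    names = [e.parameter for e in entries][::-1]
    for y, e in enumerate(entries[::-1]):
        lo, hi = sorted((e.at_lower, e.at_upper))
        ax.barh(y, hi - lo, left=lo, color="#4878b0", height=0.6)
    ax.axvline(base_value, color="k", lw=1)
    ax.set_yticks(range(len(names)), names)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
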