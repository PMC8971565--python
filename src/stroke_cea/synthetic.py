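"""Oracle scenarios and randomized fixtures for testing the pipeline.

Three generators, each returning a :class:`Scenario` bundling a parameter
set, a life table, and (where available) closed-form expected quantities:

* :func:`null_scenario` — both arms made identical; any correct
  implementation must report zero incremental cost and QALYs.
* :func:`constant_hazard_scenario` — a single alive state with constant
  monthly death probability and no recurrence, whose lifetime discounted
  QALY is a geometric series in closed form.
* :func:`perturbed_scenarios` — parameter sets drawn uniformly within
  the plausible ranges (range endpoints get exercised, unlike the PSA
  distributions, which concentrate near the mean), for invariant sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mortality import LifeTable, default_life_table, gompertz_life_table
from .parameters import DistributionSpec, ParameterSet, registry

__all__ = ["Scenario", "null_scenario", "constant_hazard_scenario",
           "perturbed_scenarios"]


@dataclass
class Scenario:
    name: str
    params: ParameterSet
    life_table: LifeTable
    expected: dict = field(default_factory=dict)  # quantity -> value; keys
    # ending in "_rule" carry the derivation of the like-named quantity


def null_scenario() -> Scenario:
    """Both arms coincide: hazard ratio 1, equal 30-day outcomes, no drug cost.

    All arm-specific sampling distributions are degenerated to point
    masses, so even a PSA on this scenario draws identical arms (shared
    inputs are drawn once and applied to both).
    """
    base = ParameterSet()
    overrides = {"hr_primary": 1.0, "ticagrelor_additional": 0.0}
    for name in ("prop_death", "prop_is", "prop_ich", "p_major_ech",
                 *[f"mrs{s}" for s in range(6)]):
        overrides[f"ticagrelor_{name}"] = base[f"aspirin_{name}"]
    arm_specific = [n for n, d in registry().items()
                    if d.arm is not None and d.dist is not None]
    dists = {n: DistributionSpec("point", overrides.get(n, base[n]))
             for n in arm_specific + ["ticagrelor_additional", "hr_primary"]}
    params = base.with_overrides(overrides, dist_overrides=dists)
    return Scenario(
        name="null",
        params=params,
        life_table=default_life_table(),
        expected={"delta_cost": 0.0, "delta_qaly": 0.0,
                  "status": "equivalent",
                  "delta_rule": "identical arms cancel exactly"},
    )


def constant_hazard_scenario(monthly_death: float, utility: float = 1.0,
                             discount: float = 0.0) -> Scenario:
    """Single alive state, constant hazard, closed-form lifetime QALY.

    The whole cohort enters at mRS 0, never recurs, and dies at constant
    monthly probability ``d``; utilities are flat, costs zero. The
    engine's discounted QALY must equal the geometric series

        sum_{t=1..T} [(1 - d) * (1 + r)^(-1/12)]^(t-1) * u / 12

    with T = 360 cycles.
    """
    if not 0.0 <= monthly_death < 1.0:
        raise ValueError("monthly_death must lie in [0, 1)")
    # annual qx reproducing the requested constant monthly probability
    qx = 1.0 - (1.0 - monthly_death) ** 12
    lt = LifeTable(np.arange(65, 111), np.full(46, qx), stroke_fraction=0.0,
                   source=f"constant-hazard(d={monthly_death:g})")
    overrides: dict[str, float] = {
        "p_primary_30d": 0.0, "hr_primary": 1.0,
        "aspirin_p_major_ech": 0.0, "ticagrelor_p_major_ech": 0.0,
        "annual_recurrence": 0.0,
        "disutility_recurrent_stroke": 0.0, "disutility_major_ech": 0.0,
        "ticagrelor_additional": 0.0,
        "discount_annual": discount,
    }
    for s in range(6):
        overrides[f"aspirin_mrs{s}"] = 1.0 if s == 0 else 0.0
        overrides[f"ticagrelor_mrs{s}"] = 1.0 if s == 0 else 0.0
        overrides[f"utility_mrs{s}"] = utility
        overrides[f"mortality_hr_mrs{s}"] = 1.0
    for name in ("is_hosp_independent", "is_hosp_dependent", "is_hosp_death",
                 "ich_hosp_independent", "ich_hosp_dep_or_death", "ech_hosp",
                 "annual_post_independent", "annual_post_dependent"):
        overrides[name] = 0.0
    params = ParameterSet().with_overrides(overrides)

    ratio = (1.0 - monthly_death) * (1.0 + discount) ** (-1.0 / 12.0)
    T = params.econ().horizon_cycles
    if ratio == 1.0:
        series = float(T)
    else:
        series = (1.0 - ratio**T) / (1.0 - ratio)
    expected_qaly = series * utility / 12.0
    return Scenario(
        name=f"constant-hazard(d={monthly_death:g}, u={utility:g}, r={discount:g})",
        params=params,
        life_table=lt,
        expected={
            "total_qaly": expected_qaly,
            "total_cost": 0.0,
            "total_qaly_rule": "geometric series "
                               "sum_{t=1..360} ((1-d)(1+r)^(-1/12))^(t-1) u/12",
        },
    )


def perturbed_scenarios(n: int, seed: int) -> list[Scenario]:
    """Parameter sets drawn uniformly within the plausible ranges.

    Utilities are post-processed with a running minimum so the
    monotonicity invariant (utility non-increasing in mRS) holds by
    construction; each candidate value stays inside its own printed
    range. Inputs without a range keep their base value. Reproducible
    for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    reg = registry()
    lt = default_life_table()
    scenarios = []
    for i in range(n):
        overrides: dict[str, float] = {}
        for name, d in reg.items():
            if d.low is not None and d.high is not None and d.low < d.high:
                overrides[name] = float(rng.uniform(d.low, d.high))
        # enforce utility ordering (each clipped value stays in range
        # because consecutive ranges overlap at their boundaries)
        running = overrides["utility_mrs0"]
        for s in range(1, 6):
            running = min(running, overrides[f"utility_mrs{s}"])
            overrides[f"utility_mrs{s}"] = running
        scenarios.append(Scenario(name=f"perturbed-{i}",
                                  params=ParameterSet().with_overrides(overrides),
                                  life_table=lt))
    return scenarios
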