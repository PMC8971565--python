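"""Monthly Markov cohort engine over mRS health states.

From day 30 to the 30-year horizon the cohort is propagated in monthly
cycles over seven states (mRS 0-5 and death). At each cycle boundary,
per alive state:

1. background (non-stroke) death at the age- and mRS-specific monthly
   probability from the life table;
2. among survivors, recurrent stroke at a monthly probability derived
   from the annual recurrence rate, with the hazard escalating by a
   fixed relative risk per completed life-year;
3. a recurrence is fatal with a fixed probability and is an intracranial
   hemorrhage (ICH) with a fixed probability, otherwise an ischemic
   stroke (IS);
4. non-fatal recurrences are reallocated uniformly over the states of
   equal or greater disability; everyone else stays put.

Rewards for cycle ``t`` are accrued on the post-transition occupancy
(TreeAge-style cycle rewards): state utilities and maintenance costs on
the occupancy of cycle ``t``, event tariffs and disutilities on the
transitions that produced it, all discounted by ``(1+r)^(-(t-1)/12)``.
Cycle 1 carries the acute-phase cost and QALY at discount factor 1;
maintenance costs start at cycle 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .decision_tree import AcuteResult
from .mortality import LifeTable
from .parameters import EconSettings, ParameterSet

__all__ = [
    "CohortState", "CohortTrace", "ArmResult",
    "monthly_recurrence_probability", "reallocation_weights",
    "step", "run_cohort", "run_cohort_arrays", "engine_inputs",
]

# reallocation matrix: row s spreads mass uniformly over states s..5
_REALLOC = np.zeros((6, 6))
for _s in range(6):
    _REALLOC[_s, _s:] = 1.0 / (6 - _s)

#: share of a reallocation from state s landing in an independent state (mRS 0-2)
_IND_SHARE = np.array([max(0, 3 - s) / (6 - s) for s in range(6)])

_INDEP = slice(0, 3)   # mRS 0-2
_DEP = slice(3, 6)     # mRS 3-5


def monthly_recurrence_probability(annual_p, rr_per_year, years_since_entry):
    """Monthly recurrent-stroke probability with stepwise annual escalation.

    The annual hazard ``-ln(1 - annual_p)`` is scaled by
    ``rr_per_year**floor(years_since_entry)``, divided by 12 and converted
    back to a probability.
    """
    annual_p = np.asarray(annual_p, dtype=float)
    if np.any(annual_p < 0) or np.any(annual_p >= 1):
        raise ValueError("annual_p must lie in [0, 1)")
    hazard = -np.log1p(-annual_p) * np.asarray(rr_per_year, float) ** math.floor(years_since_entry)
    out = -np.expm1(-hazard / 12.0)
    return out if out.ndim else float(out)


def reallocation_weights(from_mrs: int) -> dict[int, float]:
    """Uniform weights over the states of equal or greater disability."""
    if not 0 <= from_mrs <= 5:
        raise ValueError("from_mrs must be 0..5")
    n = 6 - from_mrs
    return {s: 1.0 / n for s in range(from_mrs, 6)}


@dataclass(frozen=True)
class CohortState:
    """Cohort occupancy at one cycle."""

    occupancy: np.ndarray  # mRS 0-5 and death; sums to 1
    cycle: int             # 1-based
    age: float             # years at the start of this cycle

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.shape != (7,) or np.any(occ < -1e-12):
            raise ValueError("occupancy must be seven non-negative entries")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError(f"occupancy sums to {occ.sum()!r}, not 1")


@dataclass
class CohortTrace:
    """Per-cycle occupancies and (un)discounted cost/QALY increments."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CohortTrace":
        return cls(pd.read_csv(path))


@dataclass
class ArmResult:
    """Lifetime discounted totals for one strategy."""

    total_cost: float
    total_qaly: float
    trace: Optional[CohortTrace] = None

    def to_dict(self) -> dict:
        return {"total_cost": float(self.total_cost),
                "total_qaly": float(self.total_qaly)}


# ---------------------------------------------------------------------------
# engine inputs
# ---------------------------------------------------------------------------

def engine_inputs(values: Mapping) -> dict[str, np.ndarray]:
    """Collect the long-term engine inputs from a flat name->value mapping.

    Values may be scalars or batch arrays; mRS-indexed families are
    stacked on a trailing axis of length 6.
    """
    def arr(name):
        return np.asarray(values[name], dtype=float)

    def stack(prefix):
        return np.stack([arr(f"{prefix}{s}") for s in range(6)], axis=-1)

    return {
        "utility": stack("utility_mrs"),
        "mortality_hr": stack("mortality_hr_mrs"),
        "annual_recurrence": arr("annual_recurrence"),
        "rr_per_year": arr("rr_recurrence_per_year"),
        "p_fatal": arr("p_death_after_recurrence"),
        "prop_ich": arr("prop_recurrence_ich"),
        "c_is_ind": arr("is_hosp_independent"),
        "c_is_dep": arr("is_hosp_dependent"),
        "c_is_death": arr("is_hosp_death"),
        "c_ich_ind": arr("ich_hosp_independent"),
        "c_ich_dd": arr("ich_hosp_dep_or_death"),
        "c_ann_ind": arr("annual_post_independent"),
        "c_ann_dep": arr("annual_post_dependent"),
        "d_stroke": arr("disutility_recurrent_stroke"),
    }


def _cycle_update(occ: np.ndarray, qx: float, years_since_entry: float,
                  stroke_fraction: float, ep: Mapping[str, np.ndarray]):
    """One transition + undiscounted rewards; ``occ`` has shape (..., 7).

    Returns ``(occ_new, cost, qaly, rec_total)`` where cost includes the
    monthly maintenance of the new occupancy plus recurrence tariffs.
    """
    alive = occ[..., :6]
    annual_hazard = -math.log1p(-qx) * (1.0 - stroke_fraction)
    p_b = -np.expm1(-(annual_hazard / 12.0) * ep["mortality_hr"])
    p_r = monthly_recurrence_probability(ep["annual_recurrence"],
                                         ep["rr_per_year"], years_since_entry)

    dead_bg = alive * p_b
    surv = alive - dead_bg
    rec = surv * np.asarray(p_r)[..., None]
    stay = surv - rec
    rec_fatal = rec * ep["p_fatal"][..., None]
    rec_alive = rec - rec_fatal

    new_alive = stay + rec_alive @ _REALLOC
    occ_new = np.concatenate(
        [new_alive,
         (occ[..., 6] + dead_bg.sum(axis=-1) + rec_fatal.sum(axis=-1))[..., None]],
        axis=-1)

    # --- costs ------------------------------------------------------------
    maint = (new_alive[..., _INDEP].sum(axis=-1) * ep["c_ann_ind"]
             + new_alive[..., _DEP].sum(axis=-1) * ep["c_ann_dep"]) / 12.0
    rec_fatal_tot = rec_fatal.sum(axis=-1)
    ind_mass = (rec_alive * _IND_SHARE).sum(axis=-1)
    dep_mass = rec_alive.sum(axis=-1) - ind_mass
    pich = ep["prop_ich"]
    ev_cost = ((1.0 - pich) * (ind_mass * ep["c_is_ind"]
                               + dep_mass * ep["c_is_dep"]
                               + rec_fatal_tot * ep["c_is_death"])
               + pich * (ind_mass * ep["c_ich_ind"]
                         + (dep_mass + rec_fatal_tot) * ep["c_ich_dd"]))
    cost = maint + ev_cost

    # --- QALYs: state utilities on the new occupancy; the recurrence
    # disutility is a one-time decrement per event (not scaled by cycle
    # length), attributed to the state of origin and floored at 0 per state
    util = new_alive * ep["utility"] / 12.0
    dis = rec * ep["d_stroke"][..., None]
    qaly = np.maximum(util - dis, 0.0).sum(axis=-1)

    return occ_new, cost, qaly, rec.sum(axis=-1)


def run_cohort_arrays(start, acute_cost, acute_qaly,
                      ep: Mapping[str, np.ndarray], life_table: LifeTable,
                      econ: EconSettings, trace: bool = False):
    """Propagate (a batch of) cohorts over the full horizon.

    ``start`` has shape ``(..., 7)``; every entry of ``ep`` broadcasts
    against the leading batch shape. Returns a dict with discounted
    ``total_cost`` and ``total_qaly`` (batch-shaped), the maximum
    occupancy-conservation error across cycles, and (if ``trace``) the
    per-cycle record arrays.
    """
    T = econ.horizon_cycles
    entry = econ.entry_age_years
    r = econ.discount_annual
    sf = life_table.stroke_fraction
    last_age = entry + (T - 1) / 12.0
    if not life_table.covers(entry, math.floor(last_age)):
        raise ValueError(
            f"life table covers [{life_table.min_age}, {life_table.max_age}] "
            f"but the model needs ages {entry} to {math.floor(last_age)}")

    start = np.asarray(start, dtype=float)
    batch = np.broadcast_shapes(
        start.shape[:-1], np.shape(acute_cost), np.shape(acute_qaly),
        *(np.shape(v)[:-1] if k in ("utility", "mortality_hr") else np.shape(v)
          for k, v in ep.items()))
    occ = np.broadcast_to(start, batch + (7,)).copy()

    total_cost = np.broadcast_to(np.asarray(acute_cost, float), batch).copy()
    total_qaly = np.broadcast_to(np.asarray(acute_qaly, float), batch).copy()
    conservation_err = float(np.abs(occ.sum(axis=-1) - 1.0).max())

    rows = []
    if trace:
        rows.append((1, entry, occ.copy(), np.array(acute_cost, float),
                     np.array(acute_qaly, float), 1.0))

    monthly_discount = (1.0 + r) ** (-1.0 / 12.0)
    for t in range(2, T + 1):
        age = entry + (t - 1) / 12.0
        qx = life_table.annual_qx(age)
        occ, cost, qaly, _ = _cycle_update(occ, qx, (t - 1) / 12.0, sf, ep)
        df = monthly_discount ** (t - 1)
        total_cost += cost * df
        total_qaly += qaly * df
        err = float(np.abs(occ.sum(axis=-1) - 1.0).max())
        conservation_err = max(conservation_err, err)
        if trace:
            rows.append((t, age, occ.copy(), cost, qaly, df))

    out = {"total_cost": total_cost, "total_qaly": total_qaly,
           "conservation_err": conservation_err}
    if trace:
        out["rows"] = rows
    return out


def step(state: CohortState, params: ParameterSet, life_table: LifeTable,
         econ: Optional[EconSettings] = None):
    """Advance the cohort one cycle; returns the next state and increments.

    Increments are reported both undiscounted and discounted with the
    factor of the new cycle, ``(1+r)^(-(cycle_new - 1)/12)``.
    """
    econ = econ or params.econ()
    ep = engine_inputs(params.to_dict())
    t_new = state.cycle + 1
    age_new = econ.entry_age_years + (t_new - 1) / 12.0
    qx = life_table.annual_qx(age_new)
    occ_new, cost, qaly, rec = _cycle_update(
        np.asarray(state.occupancy, float), qx, (t_new - 1) / 12.0,
        life_table.stroke_fraction, ep)
    df = (1.0 + econ.discount_annual) ** (-(t_new - 1) / 12.0)
    increments = {
        "cost": float(cost), "qaly": float(qaly),
        "cost_discounted": float(cost) * df, "qaly_discounted": float(qaly) * df,
        "recurrences": float(rec), "discount_factor": df,
    }
    return CohortState(occ_new, t_new, age_new), increments


def run_cohort(acute: AcuteResult, params: ParameterSet,
               life_table: LifeTable,
               econ: Optional[EconSettings] = None,
               trace: bool = True) -> ArmResult:
    """Run one arm from the acute phase to the horizon."""
    econ = econ or params.econ()
    ep = engine_inputs(params.to_dict())
    out = run_cohort_arrays(acute.start_vector, acute.acute_cost,
                            acute.acute_qaly, ep, life_table, econ,
                            trace=trace)
    trace_obj = None
    if trace:
        recs = []
        for t, age, occ, cost, qaly, df in out["rows"]:
            recs.append({
                "cycle": t, "age": age,
                **{f"mrs{s}": float(occ[..., s]) for s in range(6)},
                "death": float(occ[..., 6]),
                "cost_inc": float(cost), "qaly_inc": float(qaly),
                "cost_inc_disc": float(cost) * df, "qaly_inc_disc": float(qaly) * df,
            })
        trace_obj = CohortTrace(pd.DataFrame.from_records(recs))
    return ArmResult(total_cost=float(out["total_cost"]),
                     total_qaly=float(out["total_qaly"]),
                     trace=trace_obj)
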