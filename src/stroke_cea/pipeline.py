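"""Full two-arm model evaluation (acute phase -> Markov phase -> comparison).

Two entry points:

* :func:`evaluate` — one parameter set at point values, returning both
  :class:`~stroke_cea.markov.ArmResult` objects (with cohort traces) and
  the :class:`~stroke_cea.economics.CEComparison`.
* :func:`evaluate_batch` — a batch of parameter substitutions evaluated
  in one vectorized pass (used by the tornado and probabilistic
  sensitivity analyses). Both paths run the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from . import decision_tree, markov
from .economics import CEComparison, compare
from .mortality import LifeTable, default_life_table
from .parameters import EconSettings, ParameterSet

__all__ = ["evaluate", "evaluate_batch", "BatchResult"]


def _acute_arrays(values: Mapping, arm: str):
    """Acute phase from a flat mapping of scalars or batch arrays."""
    mrs = np.stack([np.asarray(values[f"{arm}_mrs{s}"], float) for s in range(6)],
                   axis=-1)
    utility = np.stack([np.asarray(values[f"utility_mrs{s}"], float)
                        for s in range(6)], axis=-1)
    hr = values["hr_primary"] if arm == "ticagrelor" else 1.0
    drug = values["ticagrelor_additional"] if arm == "ticagrelor" else 0.0
    return decision_tree.acute_phase_arrays(
        values["p_primary_30d"], hr,
        values[f"{arm}_prop_death"], values[f"{arm}_prop_is"],
        values[f"{arm}_prop_ich"], values[f"{arm}_p_major_ech"],
        mrs, drug,
        values["is_hosp_independent"], values["is_hosp_dependent"],
        values["is_hosp_death"], values["ich_hosp_independent"],
        values["ich_hosp_dep_or_death"], values["ech_hosp"],
        utility, values["disutility_recurrent_stroke"],
        values["disutility_major_ech"],
    )


@dataclass
class BatchResult:
    """Vectorized two-arm evaluation over a batch of parameter draws."""

    cost_aspirin: np.ndarray
    qaly_aspirin: np.ndarray
    cost_ticagrelor: np.ndarray
    qaly_ticagrelor: np.ndarray
    conservation_err: float

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_ticagrelor - self.cost_aspirin

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly_ticagrelor - self.qaly_aspirin

    def icer(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.delta_qaly != 0,
                            self.delta_cost / self.delta_qaly, np.nan)


def evaluate_batch(params: ParameterSet,
                   overrides: Mapping[str, np.ndarray],
                   life_table: Optional[LifeTable] = None) -> BatchResult:
    """Evaluate both arms with per-entry parameter substitutions.

    ``overrides`` maps parameter names to scalars or equal-length arrays;
    unnamed parameters stay at the values in ``params``. Validation of
    cross-parameter invariants is intentionally bypassed so sensitivity
    analyses can push single inputs to their range limits.
    """
    life_table = life_table if life_table is not None else default_life_table()
    values: dict[str, np.ndarray] = {k: np.asarray(v, dtype=float)
                                     for k, v in params.to_dict().items()}
    for name, arr in overrides.items():
        if name not in values:
            raise KeyError(f"unknown parameter: {name}")
        values[name] = np.asarray(arr, dtype=float)

    # analysis settings are scalar by contract (not batched)
    econ = EconSettings(**{f: float(np.asarray(values[f]).flat[0])
                           for f in ("discount_annual", "wtp", "horizon_years",
                                     "cycle_length_months", "entry_age_years")})
    ep = markov.engine_inputs(values)
    results = {}
    for arm in ("aspirin", "ticagrelor"):
        start, acute_cost, acute_qaly, _ = _acute_arrays(values, arm)
        out = markov.run_cohort_arrays(start, acute_cost, acute_qaly,
                                       ep, life_table, econ, trace=False)
        results[arm] = out
    return BatchResult(
        cost_aspirin=np.asarray(results["aspirin"]["total_cost"]),
        qaly_aspirin=np.asarray(results["aspirin"]["total_qaly"]),
        cost_ticagrelor=np.asarray(results["ticagrelor"]["total_cost"]),
        qaly_ticagrelor=np.asarray(results["ticagrelor"]["total_qaly"]),
        conservation_err=max(results["aspirin"]["conservation_err"],
                             results["ticagrelor"]["conservation_err"]),
    )


def evaluate(params: ParameterSet,
             life_table: Optional[LifeTable] = None,
             wtp: Optional[float] = None):
    """Run both arms at point values and compare them.

    Returns ``(aspirin: ArmResult, ticagrelor: ArmResult, CEComparison)``.
    """
    life_table = life_table if life_table is not None else default_life_table()
    econ = params.econ()
    wtp = econ.wtp if wtp is None else wtp
    costs, utils = params.costs(), params.utilities()
    arms = {}
    for arm in ("aspirin", "ticagrelor"):
        drug = costs.ticagrelor_additional if arm == "ticagrelor" else 0.0
        acute = decision_tree.acute_phase(params.acute(arm), costs, utils, drug)
        arms[arm] = markov.run_cohort(acute, params, life_table, econ)
    comparison = compare(arms["ticagrelor"], arms["aspirin"], wtp)
    return arms["aspirin"], arms["ticagrelor"], comparison
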