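"""Acute 30-day phase of the model (the decision-tree part).

Each arm's first month is resolved here: the probability of the primary
outcome (composite of stroke or death within 30 days), its decomposition
into death / ischemic stroke (IS) / intracranial hemorrhage (ICH), major
extracranial hemorrhage (ECH), the expected acute cost (hospitalizations
plus, for the intervention arm, the 30-day ticagrelor course), the
expected first-cycle QALY net of event disutilities, and the state vector
over mRS 0-5 and death with which the cohort enters the monthly Markov
phase.

Conventions:

* The intervention arm's primary-outcome probability is obtained from the
  reference arm's on the hazard scale: ``1 - (1 - p_ref)**hr``.
* 30-day death is the residual of the printed 30-day mRS 0-5
  distribution; the death/IS/ICH decomposition (renormalized to a
  partition, since the printed category proportions overlap slightly) is
  used for event costing and disutility only.
* Hospitalization tariffs given by dependency are mixed with the arm's
  own split of survivors into independent (mRS 0-2) and dependent
  (mRS 3-5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import AcuteParameters, CostParameters, UtilityParameters

__all__ = ["AcuteResult", "primary_outcome_probability", "acute_phase",
           "acute_phase_arrays"]


@dataclass(frozen=True)
class AcuteResult:
    """Outcome of the 30-day phase for one arm."""

    start_vector: np.ndarray          # occupancy over mRS 0-5 and death, sums to 1
    acute_cost: float                 # expected cost in cycle 1, yuan
    acute_qaly: float                 # expected QALY in cycle 1, undiscounted
    event_probs: dict                 # p_primary, p_death30, p_is30, p_ich30, p_ech30

    def to_dict(self) -> dict:
        return {
            "start_vector": [float(x) for x in self.start_vector],
            "acute_cost": float(self.acute_cost),
            "acute_qaly": float(self.acute_qaly),
            "event_probs": {k: float(v) for k, v in self.event_probs.items()},
        }


def primary_outcome_probability(p_ref, hr):
    """Apply a hazard ratio to a cumulative event probability.

    ``1 - (1 - p_ref)**hr``; with ``hr = 1`` the reference probability is
    returned unchanged. Accepts scalars or arrays.
    """
    p_ref = np.asarray(p_ref, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(p_ref < 0) or np.any(p_ref > 1):
        raise ValueError("p_ref must be a probability")
    if np.any(hr <= 0):
        raise ValueError("hr must be positive")
    if np.any((p_ref == 1.0) & (hr != 1.0)):
        raise ValueError("p_ref = 1 leaves the hazard undefined")
    out = -np.expm1(hr * np.log1p(-p_ref))
    return out if out.ndim else float(out)


def acute_phase_arrays(p_ref, hr, prop_death, prop_is, prop_ich, p_ech,
                       mrs_dist, drug_cost,
                       c_is_ind, c_is_dep, c_is_death,
                       c_ich_ind, c_ich_dep_death, c_ech,
                       utility_by_mrs, d_stroke, d_ech):
    """Vectorized acute phase; every argument broadcasts over a batch.

    ``mrs_dist`` has shape ``(..., 6)`` and ``utility_by_mrs`` shape
    ``(..., 6)``. Returns ``(start_vector, acute_cost, acute_qaly,
    event_probs)`` with ``start_vector`` of shape ``(..., 7)``.
    """
    mrs_dist = np.asarray(mrs_dist, dtype=float)
    alive = mrs_dist.sum(axis=-1)
    if np.any(alive > 1.0 + 1e-12):
        raise ValueError("30-day mRS proportions sum to more than 1")
    death30 = np.clip(1.0 - alive, 0.0, 1.0)

    p_primary = primary_outcome_probability(p_ref, hr)
    total = np.asarray(prop_death, float) + np.asarray(prop_is, float) \
        + np.asarray(prop_ich, float)
    # printed event-category proportions overlap (fatal strokes); renormalize
    p_death30 = p_primary * prop_death / total
    p_is30 = p_primary * prop_is / total
    p_ich30 = p_primary * prop_ich / total
    p_ech30 = np.asarray(p_ech, dtype=float) + 0.0 * p_primary

    with np.errstate(invalid="ignore", divide="ignore"):
        s_ind = np.where(alive > 0, mrs_dist[..., :3].sum(axis=-1) / alive, 0.0)
    s_dep = 1.0 - s_ind

    acute_cost = (
        p_is30 * (s_ind * c_is_ind + s_dep * c_is_dep)
        + p_death30 * c_is_death
        + p_ich30 * (s_ind * c_ich_ind + s_dep * c_ich_dep_death)
        + p_ech30 * c_ech
        + drug_cost
    )
    base_qaly = (mrs_dist * np.asarray(utility_by_mrs, float)).sum(axis=-1) / 12.0
    # event disutilities are one-time decrements per event (not scaled by
    # the cycle length), the usual transition-reward convention
    disutility = (p_is30 + p_ich30) * d_stroke + p_ech30 * d_ech
    acute_qaly = np.maximum(base_qaly - disutility, 0.0)

    batch = np.broadcast_shapes(mrs_dist.shape[:-1], np.shape(death30))
    start = np.concatenate(
        [np.broadcast_to(mrs_dist, batch + (6,)),
         np.broadcast_to(np.asarray(death30)[..., None], batch + (1,))], axis=-1)
    event_probs = {"p_primary": p_primary, "p_death30": p_death30,
                   "p_is30": p_is30, "p_ich30": p_ich30, "p_ech30": p_ech30}
    return start, acute_cost, acute_qaly, event_probs


def acute_phase(arm: AcuteParameters, costs: CostParameters,
                utils: UtilityParameters, drug_cost: float) -> AcuteResult:
    """Resolve the 30-day phase for one arm at point values."""
    start, cost, qaly, probs = acute_phase_arrays(
        arm.p_primary_30d, arm.hr_primary,
        arm.prop_death, arm.prop_is, arm.prop_ich, arm.p_major_ech_30d,
        np.asarray(arm.mrs_distribution_30d, dtype=float), drug_cost,
        costs.is_hosp_independent, costs.is_hosp_dependent, costs.is_hosp_death,
        costs.ich_hosp_independent, costs.ich_hosp_dep_or_death, costs.ech_hosp,
        np.asarray(utils.utility_by_mrs, dtype=float),
        utils.disutility_recurrent_stroke, utils.disutility_major_ech,
    )
    return AcuteResult(start_vector=np.asarray(start, dtype=float),
                       acute_cost=float(cost), acute_qaly=float(qaly),
                       event_probs={k: float(v) for k, v in probs.items()})
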