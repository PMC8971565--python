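"""Two-strategy cost-effectiveness comparison.

Computes incremental cost and QALYs, the incremental cost-effectiveness
ratio (ICER = delta-cost / delta-QALY, defined only when delta-QALY is
nonzero), the net monetary benefit (NMB = WTP * delta-QALY - delta-cost)
and a dominance classification. A strategy is deemed cost-effective at a
willingness-to-pay (WTP) threshold when it dominates the comparator or
when it buys additional QALYs at an ICER below the threshold; negative
ICERs are never reported as bare ratios — the status field carries the
dominance information instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .markov import ArmResult

__all__ = ["CEComparison", "compare", "cost_effective_mask"]


@dataclass(frozen=True)
class CEComparison:
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]          # None when delta_qaly == 0
    nmb_at_wtp: float
    status: str                    # dominant | dominated | tradeoff | equivalent
    cost_effective_at_wtp: bool
    wtp: float

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "nmb_at_wtp": self.nmb_at_wtp,
            "status": self.status,
            "cost_effective_at_wtp": self.cost_effective_at_wtp,
            "wtp": self.wtp,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def compare(intervention: ArmResult, comparator: ArmResult,
            wtp: float) -> CEComparison:
    """Compare an intervention against a comparator at a WTP threshold."""
    dc = float(intervention.total_cost) - float(comparator.total_cost)
    de = float(intervention.total_qaly) - float(comparator.total_qaly)
    if not (np.isfinite(dc) and np.isfinite(de)):
        raise ValueError("arm results must be finite")

    if dc == 0.0 and de == 0.0:
        status = "equivalent"
    elif dc <= 0.0 and de >= 0.0:
        status = "dominant"
    elif dc >= 0.0 and de <= 0.0:
        status = "dominated"
    else:
        status = "tradeoff"

    icer = dc / de if de != 0.0 else None
    nmb = wtp * de - dc
    cost_effective = status == "dominant" or (
        status == "tradeoff" and de > 0.0 and icer < wtp)
    return CEComparison(delta_cost=dc, delta_qaly=de, icer=icer,
                        nmb_at_wtp=nmb, status=status,
                        cost_effective_at_wtp=cost_effective, wtp=float(wtp))


def cost_effective_mask(delta_cost, delta_qaly, wtp) -> np.ndarray:
    """Vectorized WTP decision with the same semantics as :func:`compare`."""
    dc = np.asarray(delta_cost, dtype=float)
    de = np.asarray(delta_qaly, dtype=float)
    dominant = (dc <= 0) & (de >= 0) & ~((dc == 0) & (de == 0))
    gains = (de > 0) & (wtp * de - dc > 0)
    return dominant | gains
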