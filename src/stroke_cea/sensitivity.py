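"""One-way, probabilistic, and subgroup sensitivity analyses.

* **One-way (tornado)** — each input with a plausible range is pushed to
  its low and high endpoint with everything else fixed; the two full
  two-arm evaluations give the ICER span attributable to that input.
* **Probabilistic (PSA)** — every distributed input is drawn jointly per
  Monte-Carlo iteration (shared inputs once per iteration, applied to
  both arms; arm-specific inputs are, by name, applied only to their
  arm) and the cost-effectiveness decision is taken at the
  willingness-to-pay threshold. Also produces the cost-effectiveness
  acceptability curve (CEAC) over a WTP grid.
* **Subgroups** — the hazard ratio of the primary outcome is replaced by
  a subgroup's mean/low/high estimate with all else at base case.

All analyses run through the same vectorized pipeline as the base case,
so the one-way evaluation at (base, base) reproduces the base-case ICER
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import cost_effective_mask
from .mortality import LifeTable, default_life_table
from .parameters import ParameterSet, registry
from .pipeline import evaluate_batch

__all__ = ["TornadoEntry", "PSAResult", "SubgroupResult",
           "one_way", "tornado", "run_psa", "subgroups",
           "DEFAULT_CEAC_GRID"]

DEFAULT_CEAC_GRID = np.arange(0, 150_001, 5_000)


# ---------------------------------------------------------------------------
# one-way sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way(param: str, low: float, high: float,
            params: Optional[ParameterSet] = None,
            life_table: Optional[LifeTable] = None) -> TornadoEntry:
    """ICER at the two endpoints of one input, all else at base case."""
    if param not in registry():
        raise KeyError(f"unknown parameter: {param}")
    if low > high:
        raise ValueError("low must not exceed high")
    params = params or ParameterSet()
    res = evaluate_batch(params, {param: np.array([low, high], dtype=float)},
                         life_table)
    icers = res.icer()
    return TornadoEntry(parameter=param, low_input=float(low),
                        high_input=float(high),
                        icer_at_low=float(icers[0]), icer_at_high=float(icers[1]))


def tornado(params: Optional[ParameterSet] = None,
            life_table: Optional[LifeTable] = None,
            parameters: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """One-way sweep over every rangeable input, sorted by ICER span.

    Inputs with a printed range use it; distributed inputs without one
    (the mRS mortality hazard ratios) use mean +/- 1.96 sd; inputs with
    neither (the 30-day mRS proportions and the analysis settings) are
    excluded. Columns: ``parameter, low, high, icer_low, icer_high, span``.
    """
    params = params or ParameterSet()
    reg = registry()
    names = list(parameters) if parameters is not None else list(reg)
    swept, bounds = [], []
    for name in names:
        b = reg[name].tornado_bounds()
        if b is not None:
            swept.append(name)
            bounds.append(b)
    # one batched evaluation: row 2i = low endpoint, row 2i+1 = high
    overrides = {}
    n = 2 * len(swept)
    for i, (name, (lo, hi)) in enumerate(zip(swept, bounds)):
        col = np.full(n, params[name], dtype=float)
        col[2 * i], col[2 * i + 1] = lo, hi
        overrides[name] = col
    res = evaluate_batch(params, overrides, life_table)
    icers = res.icer()
    frame = pd.DataFrame({
        "parameter": swept,
        "low": [b[0] for b in bounds],
        "high": [b[1] for b in bounds],
        "icer_low": icers[0::2],
        "icer_high": icers[1::2],
    })
    frame["span"] = (frame["icer_high"] - frame["icer_low"]).abs()
    return frame.sort_values("span", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    n: int
    seed: int
    wtp: float
    samples: pd.DataFrame          # one row per iteration: draws + outcomes
    frac_cost_effective: float
    ceac: pd.DataFrame             # columns: wtp, fraction

    def to_csvs(self, samples_path=None, ceac_path=None) -> None:
        if samples_path is not None:
            self.samples.to_csv(samples_path, index=False)
        if ceac_path is not None:
            self.ceac.to_csv(ceac_path, index=False)


def run_psa(n: int, seed: int,
            wtp: Optional[float] = None,
            params: Optional[ParameterSet] = None,
            life_table: Optional[LifeTable] = None,
            ceac_grid: Optional[np.ndarray] = None) -> PSAResult:
    """Joint Monte-Carlo sampling of all distributed inputs.

    Each iteration draws every distributed input once (in fixed registry
    order from a single seeded generator, so results are reproducible)
    and evaluates both arms; the reported fraction is the share of
    iterations in which the intervention is cost-effective at ``wtp``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or ParameterSet()
    wtp = params.econ().wtp if wtp is None else float(wtp)
    rng = np.random.default_rng(seed)

    draws: dict[str, np.ndarray] = {}
    for name in registry():
        spec = params.distribution(name)
        if spec is None or spec.sd == 0:
            continue
        draws[name] = np.asarray(spec.sample(rng, n), dtype=float)

    res = evaluate_batch(params, draws, life_table)
    dc, de = res.delta_cost, res.delta_qaly
    ce = cost_effective_mask(dc, de, wtp)

    samples = pd.DataFrame(draws)
    samples.insert(0, "iteration", np.arange(1, n + 1))
    samples["delta_cost"] = dc
    samples["delta_qaly"] = de
    samples["cost_effective"] = ce

    grid = DEFAULT_CEAC_GRID if ceac_grid is None else np.asarray(ceac_grid)
    fractions = [float(cost_effective_mask(dc, de, w).mean()) for w in grid]
    ceac = pd.DataFrame({"wtp": grid, "fraction": fractions})

    return PSAResult(n=n, seed=seed, wtp=wtp, samples=samples,
                     frac_cost_effective=float(ce.mean()), ceac=ceac)


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupResult:
    label: str
    hr_mean: float
    hr_low: float
    hr_high: float
    icer_mean: float
    icer_low: float
    icer_high: float


def subgroups(table, params: Optional[ParameterSet] = None,
              life_table: Optional[LifeTable] = None) -> list[SubgroupResult]:
    """ICER per subgroup at the subgroup's mean/low/high primary-outcome HR.

    ``table`` is a DataFrame (or path to CSV) with columns
    ``label, hr_mean, hr_low, hr_high``; all other inputs stay at base
    case. An empty table yields an empty list.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
        table = pd.read_csv(table)
    table = pd.DataFrame(table)
    if table.empty:
        return []
    missing = {"label", "hr_mean", "hr_low", "hr_high"} - set(table.columns)
    if missing:
        raise ValueError(f"subgroup table lacks column(s): {sorted(missing)}")
    hrs = table[["hr_mean", "hr_low", "hr_high"]].to_numpy(dtype=float)
    if np.any(hrs <= 0):
        raise ValueError("subgroup hazard ratios must be positive")
    params = params or ParameterSet()
    res = evaluate_batch(params, {"hr_primary": hrs.ravel()}, life_table)
    icers = res.icer().reshape(hrs.shape)
    return [
        SubgroupResult(label=str(row.label), hr_mean=float(row.hr_mean),
                       hr_low=float(row.hr_low), hr_high=float(row.hr_high),
                       icer_mean=float(icers[i, 0]), icer_low=float(icers[i, 1]),
                       icer_high=float(icers[i, 2]))
        for i, row in enumerate(table.itertuples(index=False))
    ]
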