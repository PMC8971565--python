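"""Model inputs: base-case values, plausible ranges, and sampling distributions.

Every quantity the model consumes is registered here with its base-case
value, its plausible range (used by one-way sensitivity analysis) and its
sampling distribution (used by probabilistic sensitivity analysis).
Distributions are parameterized by their natural-scale mean and standard
deviation and converted by the method of moments:

* beta:       nu = m(1-m)/s^2 - 1,  alpha = m*nu,  beta = (1-m)*nu
* gamma:      shape = (m/s)^2,  scale = s^2/m
* lognormal:  sigma^2 = ln(1 + (s/m)^2),  mu = ln(m) - sigma^2/2
* point:      degenerate mass at the mean (sd = 0)

The default parameter set describes a cohort of 65-year-old patients with
an acute mild-to-moderate ischemic stroke or TIA, treated for 30 days with
either aspirin alone or ticagrelor added to aspirin, then followed over a
30-year horizon in monthly cycles across modified Rankin scale (mRS)
health states 0-5 plus death. Costs are direct medical costs in 2020
Chinese yuan; outcomes are QALYs; both discounted at 3% per year.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "ParameterDef",
    "ParameterSet",
    "AcuteParameters",
    "LongTermParameters",
    "CostParameters",
    "UtilityParameters",
    "EconSettings",
    "ParameterError",
    "load_parameter_set",
    "make_sampler",
    "registry",
    "MRS_STATES",
]

#: alive health states (modified Rankin scale scores); index 6 is death
MRS_STATES = (0, 1, 2, 3, 4, 5)


class ParameterError(ValueError):
    """A model input failed validation; the message names the parameter."""


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution given by natural-scale mean and sd."""

    kind: str  # "beta" | "gamma" | "lognormal" | "point"
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "gamma", "lognormal", "point"):
            raise ParameterError(f"unknown distribution kind {self.kind!r}")
        if self.sd < 0:
            raise ParameterError("distribution sd must be >= 0")
        if self.sd == 0:
            return  # degenerates to a point mass regardless of kind
        if self.kind == "beta":
            m = self.mean
            if not 0.0 < m < 1.0:
                raise ParameterError("beta mean must lie strictly in (0, 1)")
            if self.sd**2 >= m * (1.0 - m):
                raise ParameterError(
                    f"beta moments infeasible: sd^2={self.sd**2:.3g} >= "
                    f"mean(1-mean)={m * (1 - m):.3g}"
                )
        elif self.kind in ("gamma", "lognormal") and self.mean <= 0:
            raise ParameterError(f"{self.kind} mean must be positive")

    # -- method-of-moments parameterizations ------------------------------
    def beta_shapes(self) -> tuple[float, float]:
        m, s = self.mean, self.sd
        nu = m * (1.0 - m) / s**2 - 1.0
        return m * nu, (1.0 - m) * nu

    def gamma_shapes(self) -> tuple[float, float]:
        m, s = self.mean, self.sd
        return (m / s) ** 2, s**2 / m

    def lognormal_params(self) -> tuple[float, float]:
        m, s = self.mean, self.sd
        sigma2 = math.log1p((s / m) ** 2)
        return math.log(m) - sigma2 / 2.0, math.sqrt(sigma2)

    def recentered(self, mean: float) -> "DistributionSpec":
        """Same family and sd, shifted to a new mean."""
        return replace(self, mean=mean)

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        if self.sd == 0 or self.kind == "point":
            return np.full(size, self.mean) if size is not None else np.float64(self.mean)
        if self.kind == "beta":
            a, b = self.beta_shapes()
            return rng.beta(a, b, size)
        if self.kind == "gamma":
            k, theta = self.gamma_shapes()
            return rng.gamma(k, theta, size)
        mu, sigma = self.lognormal_params()
        return rng.lognormal(mu, sigma, size)


class Sampler:
    """Reproducible stream of draws from one :class:`DistributionSpec`."""

    def __init__(self, spec: DistributionSpec, seed: int):
        self.spec = spec
        self._rng = np.random.default_rng(seed)

    def draw(self, size=None) -> np.ndarray:
        return self.spec.sample(self._rng, size)

    __call__ = draw

    def __iter__(self) -> Iterator[float]:
        while True:
            yield float(self.draw())


def make_sampler(spec: DistributionSpec, seed: int) -> Sampler:
    """Build a reproducible sampler for one distribution spec."""
    return Sampler(spec, seed)


# ---------------------------------------------------------------------------
# parameter registry (every model input with range and distribution)
# ---------------------------------------------------------------------------

#: how a value is bounded when validated and when range endpoints are clipped
_KIND_BOUNDS = {
    "probability": (0.0, 1.0),
    "utility": (0.0, 1.0),
    "positive": (np.nextafter(0.0, 1.0), math.inf),
    "nonneg": (0.0, math.inf),
}


@dataclass(frozen=True)
class ParameterDef:
    """One registered model input."""

    name: str
    base: float
    low: Optional[float] = None
    high: Optional[float] = None
    dist: Optional[DistributionSpec] = None
    kind: str = "nonneg"  # probability | utility | positive | nonneg
    arm: Optional[str] = None  # "aspirin" | "ticagrelor" | None (shared)
    label: str = ""

    def __post_init__(self) -> None:
        lo, hi = _KIND_BOUNDS[self.kind]
        if not lo <= self.base <= hi:
            raise ParameterError(f"{self.name}: base {self.base} outside {self.kind} bounds")
        if self.low is not None and self.high is not None:
            if not self.low <= self.base <= self.high:
                raise ParameterError(f"{self.name}: base outside [low, high]")

    @property
    def sampled(self) -> bool:
        return self.dist is not None and self.dist.sd > 0

    def validate(self, value: float) -> None:
        if not isinstance(value, (int, float)) or isinstance(value, bool) or not math.isfinite(value):
            raise ParameterError(f"{self.name}: value {value!r} is not a finite number")
        lo, hi = _KIND_BOUNDS[self.kind]
        if not lo <= value <= hi:
            raise ParameterError(
                f"{self.name}: value {value} outside allowed {self.kind} bounds [{lo}, {hi}]"
            )

    def tornado_bounds(self) -> Optional[tuple[float, float]]:
        """Range swept in one-way sensitivity analysis, or None if excluded.

        Inputs with a printed range use it; distributed inputs without a
        range (the mRS-specific mortality hazard ratios) use mean +/- 1.96 sd;
        inputs with neither are excluded. Probability endpoints are clipped
        to [0, 1].
        """
        if self.low is not None and self.high is not None:
            lo, hi = self.low, self.high
        elif self.sampled:
            lo = self.dist.mean - 1.96 * self.dist.sd
            hi = self.dist.mean + 1.96 * self.dist.sd
        else:
            return None
        blo, bhi = _KIND_BOUNDS[self.kind]
        return max(lo, blo), min(hi, bhi)


def _beta(m: float, s: float) -> DistributionSpec:
    return DistributionSpec("beta", m, s)


def _gamma(m: float, s: float) -> DistributionSpec:
    return DistributionSpec("gamma", m, s)


def _logn(m: float, s: float) -> DistributionSpec:
    return DistributionSpec("lognormal", m, s)


def _registry() -> dict[str, ParameterDef]:
    P = ParameterDef
    defs = [
        # --- 30-day acute phase, aspirin alone ---------------------------
        P("p_primary_30d", 0.066, 0.060, 0.073, _beta(0.066, 0.003), "probability",
          "aspirin", "30-day probability of primary outcome (stroke or death), aspirin"),
        P("aspirin_prop_death", 0.075, 0.052, 0.106, _beta(0.075, 0.014), "probability",
          "aspirin", "proportion of death among primary outcomes, aspirin"),
        P("aspirin_prop_is", 0.953, 0.926, 0.970, _beta(0.953, 0.011), "probability",
          "aspirin", "proportion of ischemic stroke among primary outcomes, aspirin"),
        P("aspirin_prop_ich", 0.017, 0.008, 0.036, _beta(0.017, 0.007), "probability",
          "aspirin", "proportion of intracranial hemorrhage among primary outcomes, aspirin"),
        P("aspirin_p_major_ech", 0.001, 0.000, 0.003, _beta(0.001, 0.001), "probability",
          "aspirin", "30-day probability of major extracranial hemorrhage, aspirin"),
        P("aspirin_mrs0", 0.365, kind="probability", arm="aspirin", label="30-day mRS 0, aspirin"),
        P("aspirin_mrs1", 0.395, kind="probability", arm="aspirin", label="30-day mRS 1, aspirin"),
        P("aspirin_mrs2", 0.140, kind="probability", arm="aspirin", label="30-day mRS 2, aspirin"),
        P("aspirin_mrs3", 0.056, kind="probability", arm="aspirin", label="30-day mRS 3, aspirin"),
        P("aspirin_mrs4", 0.034, kind="probability", arm="aspirin", label="30-day mRS 4, aspirin"),
        P("aspirin_mrs5", 0.004, kind="probability", arm="aspirin", label="30-day mRS 5, aspirin"),
        # --- 30-day acute phase, ticagrelor added to aspirin --------------
        P("hr_primary", 0.830, 0.710, 0.960, _beta(0.830, 0.060), "positive",
          "ticagrelor", "hazard ratio of primary outcome, ticagrelor+aspirin vs aspirin"),
        P("ticagrelor_prop_death", 0.119, 0.087, 0.160, _beta(0.119, 0.018), "probability",
          "ticagrelor", "proportion of death among primary outcomes, ticagrelor+aspirin"),
        P("ticagrelor_prop_is", 0.911, 0.874, 0.938, _beta(0.911, 0.016), "probability",
          "ticagrelor", "proportion of ischemic stroke among primary outcomes, ticagrelor+aspirin"),
        P("ticagrelor_prop_ich", 0.066, 0.043, 0.100, _beta(0.066, 0.014), "probability",
          "ticagrelor", "proportion of intracranial hemorrhage among primary outcomes, ticagrelor+aspirin"),
        P("ticagrelor_p_major_ech", 0.005, 0.004, 0.007, _beta(0.005, 0.001), "probability",
          "ticagrelor", "30-day probability of major extracranial hemorrhage, ticagrelor+aspirin"),
        P("ticagrelor_mrs0", 0.372, kind="probability", arm="ticagrelor", label="30-day mRS 0, ticagrelor+aspirin"),
        P("ticagrelor_mrs1", 0.390, kind="probability", arm="ticagrelor", label="30-day mRS 1, ticagrelor+aspirin"),
        P("ticagrelor_mrs2", 0.139, kind="probability", arm="ticagrelor", label="30-day mRS 2, ticagrelor+aspirin"),
        P("ticagrelor_mrs3", 0.057, kind="probability", arm="ticagrelor", label="30-day mRS 3, ticagrelor+aspirin"),
        P("ticagrelor_mrs4", 0.031, kind="probability", arm="ticagrelor", label="30-day mRS 4, ticagrelor+aspirin"),
        P("ticagrelor_mrs5", 0.004, kind="probability", arm="ticagrelor", label="30-day mRS 5, ticagrelor+aspirin"),
        # --- long-term probabilities --------------------------------------
        P("annual_recurrence", 0.122, 0.116, 0.128, _beta(0.122, 0.003), "probability",
          None, "recurrent stroke rate per life-year"),
        P("prop_recurrence_ich", 0.075, 0.075, 0.146, _beta(0.075, 0.018), "probability",
          None, "proportion of recurrent strokes that are intracranial hemorrhage"),
        P("rr_recurrence_per_year", 1.030, 1.020, 1.040, _logn(1.030, 0.005), "positive",
          None, "relative increase of recurrence hazard per life-year"),
        P("p_death_after_recurrence", 0.193, 0.174, 0.213, _beta(0.193, 0.010), "probability",
          None, "probability of death after recurrent stroke"),
        # --- mortality hazard ratios by mRS state -------------------------
        P("mortality_hr_mrs0", 1.000, dist=_logn(1.000, 0.050), kind="positive",
          label="background mortality hazard ratio, mRS 0"),
        P("mortality_hr_mrs1", 1.000, dist=_logn(1.000, 0.050), kind="positive",
          label="background mortality hazard ratio, mRS 1"),
        P("mortality_hr_mrs2", 1.110, dist=_logn(1.110, 0.083), kind="positive",
          label="background mortality hazard ratio, mRS 2"),
        P("mortality_hr_mrs3", 1.270, dist=_logn(1.270, 0.127), kind="positive",
          label="background mortality hazard ratio, mRS 3"),
        P("mortality_hr_mrs4", 1.710, dist=_logn(1.710, 0.171), kind="positive",
          label="background mortality hazard ratio, mRS 4"),
        P("mortality_hr_mrs5", 2.370, dist=_logn(2.370, 0.237), kind="positive",
          label="background mortality hazard ratio, mRS 5"),
        # --- costs, 2020 Chinese yuan -------------------------------------
        P("ticagrelor_additional", 394, 174, 593, _gamma(394, 105), "nonneg",
          "ticagrelor", "additional drug cost of the 30-day ticagrelor course"),
        # the printed range for this row is reversed in the source table;
        # stored low-to-high (it is the +/-25% band around the base value)
        P("is_hosp_independent", 10958, 8219, 13698, _gamma(10958, 1370), "nonneg",
          None, "hospitalization cost, ischemic stroke, independent (mRS 0-2)"),
        P("is_hosp_dependent", 13605, 10204, 17006, _gamma(13605, 1701), "nonneg",
          None, "hospitalization cost, ischemic stroke, dependent (mRS 3-5)"),
        P("is_hosp_death", 11970, 8978, 14963, _gamma(11970, 1496), "nonneg",
          None, "hospitalization cost, ischemic stroke, fatal"),
        P("ich_hosp_independent", 13174, 9881, 16468, _gamma(13174, 1647), "nonneg",
          None, "hospitalization cost, intracranial hemorrhage, independent"),
        P("ich_hosp_dep_or_death", 17490, 13118, 21863, _gamma(17490, 2186), "nonneg",
          None, "hospitalization cost, intracranial hemorrhage, dependent or fatal"),
        P("ech_hosp", 8535, 6401, 10669, _gamma(8535, 1067), "nonneg",
          None, "hospitalization cost, major extracranial hemorrhage"),
        P("annual_post_independent", 8310, 6233, 10388, _gamma(8310, 1039), "nonneg",
          None, "annual post-hospitalization cost, independent (mRS 0-2)"),
        P("annual_post_dependent", 12771, 9578, 15964, _gamma(12771, 1596), "nonneg",
          None, "annual post-hospitalization cost, dependent (mRS 3-5)"),
        # --- utilities ------------------------------------------------------
        P("utility_mrs0", 0.850, 0.800, 1.000, _beta(0.850, 0.050), "utility", None, "utility, mRS 0"),
        P("utility_mrs1", 0.800, 0.800, 0.950, _beta(0.800, 0.038), "utility", None, "utility, mRS 1"),
        P("utility_mrs2", 0.700, 0.680, 0.900, _beta(0.700, 0.055), "utility", None, "utility, mRS 2"),
        P("utility_mrs3", 0.510, 0.450, 0.650, _beta(0.510, 0.050), "utility", None, "utility, mRS 3"),
        P("utility_mrs4", 0.300, 0.100, 0.400, _beta(0.300, 0.075), "utility", None, "utility, mRS 4"),
        P("utility_mrs5", 0.150, 0.000, 0.320, _beta(0.150, 0.080), "utility", None, "utility, mRS 5"),
        P("disutility_recurrent_stroke", 0.660, 0.640, 0.680, _beta(0.660, 0.010), "utility",
          None, "disutility of a recurrent stroke event"),
        P("disutility_major_ech", 0.200, 0.160, 0.230, _beta(0.200, 0.018), "utility",
          None, "disutility of a major extracranial hemorrhage"),
        # --- analysis settings (fixed; no range, no distribution) ----------
        P("discount_annual", 0.03, kind="nonneg", label="annual discount rate for costs and QALYs"),
        P("wtp", 72447, kind="nonneg", label="willingness-to-pay threshold, yuan per QALY"),
        P("horizon_years", 30, kind="positive", label="model time horizon, years"),
        P("cycle_length_months", 1, kind="positive", label="Markov cycle length, months"),
        P("entry_age_years", 65, kind="positive", label="cohort age at model entry, years"),
    ]
    return {d.name: d for d in defs}


_REGISTRY: dict[str, ParameterDef] = _registry()


def registry() -> dict[str, ParameterDef]:
    """The full input registry (name -> definition), in model order."""
    return dict(_REGISTRY)


# ---------------------------------------------------------------------------
# typed views
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcuteParameters:
    """30-day inputs for one treatment arm."""

    p_primary_30d: float
    hr_primary: float
    prop_death: float
    prop_is: float
    prop_ich: float
    p_major_ech_30d: float
    mrs_distribution_30d: tuple[float, ...]  # mRS 0-5; residual is 30-day death


@dataclass(frozen=True)
class LongTermParameters:
    annual_recurrence: float
    prop_recurrence_ich: float
    rr_recurrence_per_year: float
    p_death_after_recurrence: float
    mortality_hr_by_mrs: tuple[float, ...]


@dataclass(frozen=True)
class CostParameters:
    ticagrelor_additional: float
    is_hosp_independent: float
    is_hosp_dependent: float
    is_hosp_death: float
    ich_hosp_independent: float
    ich_hosp_dep_or_death: float
    ech_hosp: float
    annual_post_independent: float
    annual_post_dependent: float


@dataclass(frozen=True)
class UtilityParameters:
    utility_by_mrs: tuple[float, ...]
    disutility_recurrent_stroke: float
    disutility_major_ech: float
    utility_death: float = 0.0


@dataclass(frozen=True)
class EconSettings:
    discount_annual: float = 0.03
    wtp: float = 72447.0
    horizon_years: float = 30.0
    cycle_length_months: float = 1.0
    entry_age_years: float = 65.0

    @property
    def horizon_cycles(self) -> int:
        return int(round(self.horizon_years * 12 / self.cycle_length_months))


# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------

class ParameterSet:
    """A complete, validated set of model inputs.

    Values default to the registered base case; any subset may be
    overridden. ``dist_overrides`` replaces the sampling distribution of
    named inputs (used e.g. to degenerate arm-specific inputs to point
    masses in diagnostic scenarios).
    """

    def __init__(self, values: Optional[Mapping[str, float]] = None,
                 dist_overrides: Optional[Mapping[str, DistributionSpec]] = None):
        values = dict(values or {})
        unknown = sorted(set(values) - set(_REGISTRY))
        if unknown:
            raise ParameterError(f"unknown parameter(s): {', '.join(unknown)}")
        self._values = {name: float(d.base) for name, d in _REGISTRY.items()}
        for name, value in values.items():
            _REGISTRY[name].validate(value)
            self._values[name] = float(value)
        self.dist_overrides = dict(dist_overrides or {})
        for name in self.dist_overrides:
            if name not in _REGISTRY:
                raise ParameterError(f"unknown parameter in dist_overrides: {name}")
        self._check_invariants()

    # -- mapping-ish access -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def get(self, name: str, default=None):
        return self._values.get(name, default)

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def overridden(self) -> dict[str, float]:
        """Inputs that differ from the registered base case."""
        return {n: v for n, v in self._values.items() if v != _REGISTRY[n].base}

    def distribution(self, name: str) -> Optional[DistributionSpec]:
        """Sampling distribution for one input, recentered at its current value."""
        if name in self.dist_overrides:
            return self.dist_overrides[name]
        d = _REGISTRY[name]
        if d.dist is None:
            return None
        return d.dist.recentered(self._values[name])

    def with_overrides(self, overrides: Mapping[str, float],
                       dist_overrides: Optional[Mapping[str, DistributionSpec]] = None
                       ) -> "ParameterSet":
        merged = self.to_dict()
        merged.update(overrides)
        dists = dict(self.dist_overrides)
        dists.update(dist_overrides or {})
        return ParameterSet(merged, dists)

    # -- structural invariants ----------------------------------------------
    def _check_invariants(self) -> None:
        v = self._values
        for arm in ("aspirin", "ticagrelor"):
            total = sum(v[f"{arm}_mrs{s}"] for s in MRS_STATES)
            if total > 1.0 + 1e-12:
                raise ParameterError(
                    f"{arm}_mrs0..5: 30-day mRS proportions sum to {total:.6f} > 1"
                )
        hrs = [v[f"mortality_hr_mrs{s}"] for s in MRS_STATES]
        if any(b < a - 1e-12 for a, b in zip(hrs, hrs[1:])):
            raise ParameterError("mortality_hr_mrs0..5 must be non-decreasing in mRS")
        utils = [v[f"utility_mrs{s}"] for s in MRS_STATES]
        if any(b > a + 1e-12 for a, b in zip(utils, utils[1:])):
            raise ParameterError("utility_mrs0..5 must be non-increasing in mRS")

    # -- typed views ----------------------------------------------------------
    def acute(self, arm: str) -> AcuteParameters:
        if arm not in ("aspirin", "ticagrelor"):
            raise ParameterError(f"unknown arm {arm!r}")
        v = self._values
        return AcuteParameters(
            p_primary_30d=v["p_primary_30d"],
            hr_primary=v["hr_primary"] if arm == "ticagrelor" else 1.0,
            prop_death=v[f"{arm}_prop_death"],
            prop_is=v[f"{arm}_prop_is"],
            prop_ich=v[f"{arm}_prop_ich"],
            p_major_ech_30d=v[f"{arm}_p_major_ech"],
            mrs_distribution_30d=tuple(v[f"{arm}_mrs{s}"] for s in MRS_STATES),
        )

    def long_term(self) -> LongTermParameters:
        v = self._values
        return LongTermParameters(
            annual_recurrence=v["annual_recurrence"],
            prop_recurrence_ich=v["prop_recurrence_ich"],
            rr_recurrence_per_year=v["rr_recurrence_per_year"],
            p_death_after_recurrence=v["p_death_after_recurrence"],
            mortality_hr_by_mrs=tuple(v[f"mortality_hr_mrs{s}"] for s in MRS_STATES),
        )

    def costs(self) -> CostParameters:
        v = self._values
        return CostParameters(**{f: v[f] for f in CostParameters.__dataclass_fields__})

    def utilities(self) -> UtilityParameters:
        v = self._values
        return UtilityParameters(
            utility_by_mrs=tuple(v[f"utility_mrs{s}"] for s in MRS_STATES),
            disutility_recurrent_stroke=v["disutility_recurrent_stroke"],
            disutility_major_ech=v["disutility_major_ech"],
        )

    def econ(self) -> EconSettings:
        v = self._values
        return EconSettings(
            discount_annual=v["discount_annual"],
            wtp=v["wtp"],
            horizon_years=v["horizon_years"],
            cycle_length_months=v["cycle_length_months"],
            entry_age_years=v["entry_age_years"],
        )

    # -- serialization --------------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "ParameterSet":
        with open(path, "r", encoding="utf-8") as fh:
            return cls._from_text(fh.read(), source=str(path))

    @classmethod
    def _from_text(cls, text: str, source: str = "<text>") -> "ParameterSet":
        try:
            data = yaml.safe_load(io.StringIO(text))
        except yaml.YAMLError as exc:
            raise ParameterError(f"cannot parse parameter source {source}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ParameterError(f"parameter source {source} is not a key/value mapping")
        return cls(data)


def load_parameter_set(source=None) -> ParameterSet:
    """Load a parameter set from a path, config text, mapping, or None.

    Keys absent from the source fall back to the registered base-case
    values; unknown keys and invariant violations raise
    :class:`ParameterError` naming the offending parameter. The config
    dialect is flat YAML (of which flat JSON is a subset).
    """
    if source is None:
        return ParameterSet()
    if isinstance(source, ParameterSet):
        return source
    if isinstance(source, Mapping):
        return ParameterSet(source)
    if isinstance(source, (str, os.PathLike)):
        if isinstance(source, os.PathLike) or (len(str(source)) < 4096 and os.path.exists(source)):
            return ParameterSet.from_file(source)
        return ParameterSet._from_text(str(source))
    raise ParameterError(f"cannot load parameters from {type(source).__name__}")
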