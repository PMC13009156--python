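"""Typed model-parameter registry with uncertainty distributions.

Every input to the economic model is a named :class:`Parameter` carrying a
base-case value, units, and a :class:`DistributionSpec` used by the
probabilistic sensitivity analysis (PSA).  Proportions use beta
distributions, costs use gamma distributions (parameterized by mean and
coefficient of variation), utilities and QALY losses use normal
distributions (truncated to their valid support when sampled), and the
treatment effect uses a lognormal distribution on the relative risk.

Parameter sets are read from and written to a strict YAML dialect with
exact numeric round-trip, and can be exported as a flat CSV table for
audit.
"""

from __future__ import annotations

import io
import math
from typing import Any, Iterator, Literal, Mapping, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "DistributionSpec",
    "FixedDist",
    "BetaDist",
    "GammaMeanCVDist",
    "NormalDist",
    "LognormalRRDist",
    "Parameter",
    "ParameterSet",
    "REQUIRED_PARAMETERS",
    "gamma_from_mean_cv",
    "lognormal_rr_from_ci",
    "load_parameter_set",
    "dump_parameter_set",
    "sample_draw",
]

#: Names every complete model configuration must define exactly once.
REQUIRED_PARAMETERS: tuple[str, ...] = (
    "cad_incidence_10y_top20",
    "stroke_incidence_10y_top20",
    "relative_risk_reduction",
    "utility_10_40",
    "utility_40_60",
    "utility_60plus",
    "cad_fatality",
    "stroke_fatality",
    "qaly_loss_fatal_cad",
    "qaly_loss_fatal_stroke",
    "genetic_test_cost",
    "statin_monitoring_annual_cost",
    "lifetime_cad_cost",
    "lifetime_stroke_cost",
    "discount_rate",
    "medical_inflation",
    "qaly_monetary_value",
    "productivity_per_case",
    "cobenefit_multiplier",
    "qaly_gain_per_case",
    "cohort_size",
    "high_risk_fraction",
    "very_high_risk_fraction",
    "horizon_years",
)

_MEAN_TOL = 1e-9


def gamma_from_mean_cv(mean: float, cv: float) -> tuple[float, float]:
    """Convert a (mean, coefficient-of-variation) pair to gamma (shape, scale).

    shape = 1/cv**2 and scale = mean*cv**2, so that shape*scale == mean and
    1/sqrt(shape) == cv.

    >>> gamma_from_mean_cv(400, 0.20)
    (25.0, 16.0)
    """
    if mean <= 0 or cv <= 0:
        raise ValueError(f"mean and cv must be positive, got mean={mean}, cv={cv}")
    shape = 1.0 / cv**2
    scale = mean * cv**2
    return shape, scale


def lognormal_rr_from_ci(
    median: float, ci95: tuple[float, float]
) -> tuple[float, float]:
    """Lognormal (mu, sigma) for a relative risk given its median and 95% CI.

    mu = ln(median); sigma is derived from the CI width on the log scale,
    sigma = ln(high/low) / (2 * 1.96).  The interval need not be
    multiplicatively symmetric about the median; the median anchors mu.
    """
    low, high = ci95
    if not (0.0 < low < median < high < 1.0):
        raise ValueError(
            f"require 0 < low < median < high < 1, got median={median}, ci95={ci95}"
        )
    mu = math.log(median)
    sigma = math.log(high / low) / (2.0 * 1.96)
    return mu, sigma


class FixedDist(BaseModel):
    """Degenerate distribution: the parameter never varies in the PSA."""

    model_config = ConfigDict(frozen=True)
    kind: Literal["fixed"] = "fixed"


class BetaDist(BaseModel):
    """Beta(alpha, beta) for proportions; mean alpha/(alpha+beta)."""

    model_config = ConfigDict(frozen=True)
    kind: Literal["beta"] = "beta"
    alpha: float
    beta: float

    @model_validator(mode="after")
    def _check(self) -> "BetaDist":
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta distribution requires alpha > 0 and beta > 0")
        return self

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        n = self.alpha + self.beta
        return math.sqrt(self.alpha * self.beta / (n**2 * (n + 1.0)))


class GammaMeanCVDist(BaseModel):
    """Gamma for nonnegative costs, parameterized by mean and CV."""

    model_config = ConfigDict(frozen=True)
    kind: Literal["gamma-by-mean-cv"] = "gamma-by-mean-cv"
    mean: float
    cv: float

    @model_validator(mode="after")
    def _check(self) -> "GammaMeanCVDist":
        gamma_from_mean_cv(self.mean, self.cv)  # validates positivity
        return self

    @property
    def shape_scale(self) -> tuple[float, float]:
        return gamma_from_mean_cv(self.mean, self.cv)


class NormalDist(BaseModel):
    """Normal(mean, sd) for utilities and QALY losses.

    Draws are truncated to the parameter's valid support at sampling time
    (utilities to [0, 1], losses to [0, inf)) by resampling, which preserves
    the conditional distribution shape rather than piling mass at the bounds.
    """

    model_config = ConfigDict(frozen=True)
    kind: Literal["normal"] = "normal"
    mean: float
    sd: float

    @model_validator(mode="after")
    def _check(self) -> "NormalDist":
        if self.sd <= 0:
            raise ValueError("normal distribution requires sd > 0")
        return self


class LognormalRRDist(BaseModel):
    """Lognormal on a relative risk in (0, 1), anchored at its median.

    The owning parameter's base value is the relative risk *reduction*
    1 - median.  Sampling draws RR ~ Lognormal(ln median, sigma) and returns
    the implied reduction 1 - RR.
    """

    model_config = ConfigDict(frozen=True)
    kind: Literal["lognormal-rr"] = "lognormal-rr"
    median: float
    ci_low: float
    ci_high: float

    @model_validator(mode="after")
    def _check(self) -> "LognormalRRDist":
        lognormal_rr_from_ci(self.median, (self.ci_low, self.ci_high))
        return self

    @property
    def mu_sigma(self) -> tuple[float, float]:
        return lognormal_rr_from_ci(self.median, (self.ci_low, self.ci_high))


DistributionSpec = Union[FixedDist, BetaDist, GammaMeanCVDist, NormalDist, LognormalRRDist]

_DIST_CLASSES: dict[str, type] = {
    "fixed": FixedDist,
    "beta": BetaDist,
    "gamma-by-mean-cv": GammaMeanCVDist,
    "normal": NormalDist,
    "lognormal-rr": LognormalRRDist,
}

_PROBABILITY_UNITS = {"probability", "fraction"}


class Parameter(BaseModel):
    """One named model input: base value, units, PSA distribution, provenance."""

    model_config = ConfigDict(frozen=True)
    name: str
    base_value: float
    units: str
    distribution: DistributionSpec = FixedDist()
    source_note: str = ""

    @field_validator("name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        if not v or not v.strip():
            raise ValueError("parameter name must be nonempty")
        return v

    @model_validator(mode="after")
    def _check(self) -> "Parameter":
        if self.units in _PROBABILITY_UNITS and not 0.0 <= self.base_value <= 1.0:
            raise ValueError(
                f"{self.name}: probability value {self.base_value} outside [0, 1]"
            )
        if self.units.startswith("USD") or self.units == "QALY":
            if self.base_value < 0:
                raise ValueError(
                    f"{self.name}: {self.units} value must be nonnegative"
                )
        self._check_mean_consistency()
        return self

    def _check_mean_consistency(self) -> None:
        """Non-fixed distributions must be centered on the base value.

        For beta/gamma/normal the distribution mean equals ``base_value``;
        for lognormal-rr the *median* relative risk equals
        ``1 - base_value`` (the base value being the risk reduction).
        """
        d = self.distribution
        if isinstance(d, FixedDist):
            return
        if isinstance(d, BetaDist):
            implied = d.mean
        elif isinstance(d, GammaMeanCVDist):
            implied = d.mean
        elif isinstance(d, NormalDist):
            implied = d.mean
        elif isinstance(d, LognormalRRDist):
            implied = 1.0 - d.median
        else:  # pragma: no cover
            raise TypeError(f"unknown distribution {d!r}")
        if abs(implied - self.base_value) > _MEAN_TOL:
            raise ValueError(
                f"{self.name}: distribution center {implied!r} does not match "
                f"base value {self.base_value!r}"
            )

    @property
    def is_fixed(self) -> bool:
        return isinstance(self.distribution, FixedDist)


class ParameterSet(Mapping[str, Parameter]):
    """Immutable mapping of parameter name -> :class:`Parameter`.

    Enforces that all :data:`REQUIRED_PARAMETERS` are present exactly once
    and that cross-parameter constraints hold (risk-tier ordering, rate
    bounds).
    """

    def __init__(self, parameters: Mapping[str, Parameter] | list[Parameter]):
        if isinstance(parameters, Mapping):
            items = list(parameters.values())
        else:
            items = list(parameters)
        names = [p.name for p in items]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate parameter name(s): {sorted(dupes)}")
        self._params: dict[str, Parameter] = {p.name: p for p in items}
        missing = [n for n in REQUIRED_PARAMETERS if n not in self._params]
        if missing:
            raise ValueError(f"missing required parameter(s): {missing}")
        self._check_cross_constraints()

    def _check_cross_constraints(self) -> None:
        hi = self.value("high_risk_fraction")
        vhi = self.value("very_high_risk_fraction")
        if not (hi >= vhi > 0):
            raise ValueError(
                f"require high_risk_fraction >= very_high_risk_fraction > 0, "
                f"got {hi} and {vhi}"
            )
        for rate in ("discount_rate", "medical_inflation"):
            v = self.value(rate)
            if not 0.0 <= v <= 0.2:
                raise ValueError(f"{rate} = {v} outside [0, 0.2]")

    # Mapping protocol ----------------------------------------------------
    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._params == other._params

    def value(self, name: str) -> float:
        """Base-case value of parameter ``name``."""
        return self._params[name].base_value

    def replace_values(self, **values: float) -> "ParameterSet":
        """New set with the given base values (distributions untouched)."""
        out = dict(self._params)
        for name, v in values.items():
            if name not in out:
                raise KeyError(name)
            out[name] = out[name].model_copy(update={"base_value": float(v)})
        return ParameterSet(out)

    def to_frame(self) -> pd.DataFrame:
        """Flat audit table: name, base value, units, kind, hyperparameters."""
        rows = []
        for p in self._params.values():
            d = p.distribution.model_dump()
            kind = d.pop("kind")
            rows.append(
                {
                    "name": p.name,
                    "base_value": p.base_value,
                    "units": p.units,
                    "kind": kind,
                    "hyperparameters": ";".join(f"{k}={v}" for k, v in d.items()),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        return buf.getvalue()


# ---------------------------------------------------------------------------
# Configuration I/O (YAML dialect)
# ---------------------------------------------------------------------------

def _parameter_from_entry(name: str, entry: Mapping[str, Any]) -> Parameter:
    if not isinstance(entry, Mapping):
        raise ValueError(f"{name}: entry must be a mapping, got {type(entry).__name__}")
    unknown = set(entry) - {"base_value", "units", "distribution", "source_note"}
    if unknown:
        raise ValueError(f"{name}: unknown field(s) {sorted(unknown)}")
    dist_entry = dict(entry.get("distribution", {"kind": "fixed"}))
    kind = dist_entry.get("kind")
    if kind not in _DIST_CLASSES:
        raise ValueError(
            f"{name}: unknown distribution kind {kind!r}; "
            f"expected one of {sorted(_DIST_CLASSES)}"
        )
    dist = _DIST_CLASSES[kind](**dist_entry)
    return Parameter(
        name=name,
        base_value=entry["base_value"],
        units=entry.get("units", ""),
        distribution=dist,
        source_note=entry.get("source_note", ""),
    )


def load_parameter_set(config_text: str) -> ParameterSet:
    """Parse a YAML configuration into a validated :class:`ParameterSet`.

    The dialect is a mapping ``parameters: {name: {base_value, units,
    distribution: {kind, ...}, source_note}}``.  Raises ``ValueError`` naming
    the offending field for missing/duplicate names or out-of-range values.
    """
    doc = yaml.safe_load(config_text)
    if not isinstance(doc, Mapping) or "parameters" not in doc:
        raise ValueError("configuration must be a mapping with a 'parameters' key")
    entries = doc["parameters"]
    if not isinstance(entries, Mapping):
        raise ValueError("'parameters' must map names to entries")
    params = [_parameter_from_entry(str(n), e) for n, e in entries.items()]
    return ParameterSet(params)


def dump_parameter_set(ps: ParameterSet) -> str:
    """Serialize to the YAML config dialect; round-trips all values exactly.

    Numbers are emitted with ``repr`` (shortest exact float form), so
    ``load_parameter_set(dump_parameter_set(ps)) == ps``.
    """
    entries: dict[str, Any] = {}
    for p in ps.values():
        d = p.distribution.model_dump()
        entry: dict[str, Any] = {
            "base_value": p.base_value,
            "units": p.units,
            "distribution": d,
        }
        if p.source_note:
            entry["source_note"] = p.source_note
        entries[p.name] = entry
    return yaml.safe_dump({"parameters": entries}, sort_keys=False, width=100)


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------

def _truncation_bounds(p: Parameter) -> tuple[float, float]:
    # Utilities live in [0,1]; QALY losses and any other normal quantity in
    # this model are nonnegative.
    if p.units in _PROBABILITY_UNITS or p.name.startswith("utility"):
        return 0.0, 1.0
    return 0.0, math.inf


def _draw_one(p: Parameter, rng: np.random.Generator) -> float:
    d = p.distribution
    if isinstance(d, FixedDist):
        return p.base_value
    if isinstance(d, BetaDist):
        return float(rng.beta(d.alpha, d.beta))
    if isinstance(d, GammaMeanCVDist):
        shape, scale = d.shape_scale
        return float(rng.gamma(shape, scale))
    if isinstance(d, NormalDist):
        lo, hi = _truncation_bounds(p)
        # Resample until the draw lands in the support: keeps the truncated
        # normal shape.  Each rejection consumes one variate from the stream.
        while True:
            x = float(rng.normal(d.mean, d.sd))
            if lo <= x <= hi:
                return x
    if isinstance(d, LognormalRRDist):
        mu, sigma = d.mu_sigma
        rr = float(rng.lognormal(mu, sigma))
        return 1.0 - rr
    raise TypeError(f"unknown distribution {d!r}")  # pragma: no cover


def sample_draw(
    ps: ParameterSet, seed: int | np.random.Generator
) -> ParameterSet:
    """One PSA realization: every non-fixed parameter replaced by a draw.

    Parameters are visited in the set's (insertion) order with a single
    random stream, so a given ``seed`` yields a bit-reproducible draw.
    Accepts either an integer seed or an existing ``numpy`` Generator (the
    latter lets a PSA loop consume one stream across draws).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, Parameter] = {}
    for name, p in ps.items():
        if p.is_fixed:
            out[name] = p
        else:
            v = _draw_one(p, rng)
            # Sampled sets relax the centering invariant: carry the draw as
            # the base value with a fixed distribution.
            out[name] = Parameter(
                name=p.name,
                base_value=v,
                units=p.units,
                distribution=FixedDist(),
                source_note=p.source_note,
            )
    return ParameterSet(out)
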