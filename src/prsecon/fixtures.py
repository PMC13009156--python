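"""Packaged model inputs and seeded synthetic configurations.

The base-case parameter set ships as a YAML file inside the package (every
published input value with its PSA distribution); the three illustrative
scenario rows and the country factor table are encoded here; and
``perturbed_config`` produces seeded, jittered-but-valid configurations
for property tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np

from .markov import ScenarioProfile
from .params import Parameter, ParameterSet, load_parameter_set

__all__ = [
    "ScenarioFixture",
    "default_parameters",
    "default_config_text",
    "scenario_fixtures",
    "perturbed_config",
]

ScenarioName = Literal["low_prs", "high_prs_no_prevention", "high_prs_with_prevention"]


@dataclass(frozen=True)
class ScenarioFixture:
    name: ScenarioName
    profile: ScenarioProfile


def default_config_text() -> str:
    """The packaged base-case YAML configuration, verbatim."""
    return (
        resources.files("prsecon").joinpath("data/base_case.yaml").read_text("utf-8")
    )


def default_parameters() -> ParameterSet:
    """The base-case parameter set (published values and distributions)."""
    return load_parameter_set(default_config_text())


def scenario_fixtures() -> dict[str, ScenarioFixture]:
    """The three published illustrative scenario rows.

    These are scenario *inputs*, not engine outputs: life expectancy, total
    QALYs, and 10-year MI / stroke / fatal-MI risks (percent) for a low-PRS
    baseline, a high-PRS child without prevention, and a high-PRS child with
    prevention.  Only their differences (life-years gained, QALYs added,
    risk folds) are modeled quantities.
    """
    rows: dict[str, tuple[float, float, float, float, float]] = {
        "low_prs": (82, 70.0, 10, 5, 2),
        "high_prs_no_prevention": (72, 53.9, 30, 12, 10),
        "high_prs_with_prevention": (79, 67.2, 15, 7, 4),
    }
    return {
        name: ScenarioFixture(
            name=name,  # type: ignore[arg-type]
            profile=ScenarioProfile(
                life_expectancy=le,
                qalys=q,
                mi_risk=mi,
                stroke_risk=st,
                fatal_mi=fmi,
            ),
        )
        for name, (le, q, mi, st, fmi) in rows.items()
    }


#: Parameters whose jittered values must stay within hard bounds.
_JITTER_BOUNDS = {
    "utility_10_40": (0.0, 1.0),
    "utility_40_60": (0.0, 1.0),
    "utility_60plus": (0.0, 1.0),
    "cad_incidence_10y_top20": (0.0, 1.0),
    "stroke_incidence_10y_top20": (0.0, 1.0),
    "cad_fatality": (0.0, 1.0),
    "stroke_fatality": (0.0, 1.0),
    "relative_risk_reduction": (0.0, 1.0),
}


def perturbed_config(seed: int, jitter: float) -> ParameterSet:
    """Seeded multiplicative jitter of every non-fixed base value.

    Each non-fixed parameter's base value is scaled by an independent factor
    uniform on ``[1 - jitter, 1 + jitter]`` (clipped to the parameter's hard
    bounds) with its distribution re-centered to match, so the result
    satisfies every parameter-set invariant.  ``jitter=0`` returns the
    default set unchanged.
    """
    if not 0.0 <= jitter < 1.0:
        raise ValueError("jitter must be in [0, 1)")
    base = default_parameters()
    if jitter == 0.0:
        return base
    rng = np.random.default_rng(seed)
    updates: dict[str, float] = {}
    new_params = {}
    for name, p in base.items():
        if p.is_fixed:
            new_params[name] = p
            continue
        factor = float(rng.uniform(1.0 - jitter, 1.0 + jitter))
        v = p.base_value * factor
        lo, hi = _JITTER_BOUNDS.get(name, (0.0, np.inf))
        v = float(np.clip(v, lo + 1e-9, hi - 1e-9 if np.isfinite(hi) else np.inf))
        d = p.distribution
        kind = d.kind
        if kind == "beta":
            # keep the effective sample size, move the mean
            n_eff = d.alpha + d.beta
            dist = type(d)(alpha=v * n_eff, beta=(1.0 - v) * n_eff)
        elif kind in ("gamma-by-mean-cv", "normal"):
            dist = type(d)(**{**d.model_dump(), "mean": v})
        elif kind == "lognormal-rr":
            rr = 1.0 - v
            half = (d.ci_high / d.ci_low) ** 0.5
            lo, hi = rr / half, rr * half
            if hi >= 1.0:  # clipped spread would escape (0, 1): keep original
                dist, v = d, p.base_value
            else:
                dist = type(d)(median=rr, ci_low=lo, ci_high=hi)
        else:  # pragma: no cover
            raise TypeError(kind)
        new_params[name] = Parameter(
            name=p.name,
            base_value=v,
            units=p.units,
            distribution=dist,
            source_note=p.source_note,
        )
    return ParameterSet(new_params)
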