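"""Four-state annual-cycle Markov cohort engine.

A cohort enters event-free at age 10 and is followed annually to age 80.
Each cycle an individual may stay event-free, suffer a nonfatal
cardiovascular event (MI or stroke), suffer a fatal event, or die of
non-cardiovascular causes; both death states are absorbing.  Event hazards
switch on at age 40 (a 30-year intervention period precedes the modeled
outcome window) and are annualized from 10-year cumulative incidences.
PRS-guided intervention multiplies event hazards by one minus the relative
risk reduction.

Cycle convention: transitions occur at cycle end; rewards (life years,
utility-weighted QALYs) are credited to the state occupied during the
cycle, with no half-cycle correction by default.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .params import ParameterSet

__all__ = [
    "HealthState",
    "StratumArm",
    "TransitionTable",
    "CohortTrace",
    "TraceSummary",
    "ScenarioProfile",
    "ScenarioDelta",
    "ENTRY_AGE",
    "END_AGE",
    "EVENT_START_AGE",
    "annualize_risk",
    "build_transition_table",
    "run_cohort_trace",
    "summarize_trace",
    "trace_to_frame",
    "project_scenario_delta",
]

ENTRY_AGE = 10
END_AGE = 80
EVENT_START_AGE = 40

_MASS_TOL = 1e-9


class HealthState(enum.IntEnum):
    """Mutually exclusive health states; the two death states are absorbing."""

    EVENT_FREE = 0
    POST_EVENT = 1
    CV_DEATH = 2
    NONCV_DEATH = 3


Stratum = Literal["top2", "next18", "bottom80"]
Arm = Literal["standard", "prs_guided"]

#: Population fraction of each PRS stratum (top 2%, next 18%, bottom 80%).
STRATUM_FRACTIONS: dict[str, float] = {"top2": 0.02, "next18": 0.18, "bottom80": 0.80}


@dataclass(frozen=True)
class StratumArm:
    """One PRS stratum under one model arm.

    Under the PRS-guided arm the top 20% (top2 + next18) receive intensive
    lifestyle intervention; the top 2% additionally receive statin therapy.
    """

    stratum: Stratum
    arm: Arm

    def __post_init__(self) -> None:
        if self.stratum not in STRATUM_FRACTIONS:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.arm not in ("standard", "prs_guided"):
            raise ValueError(f"unknown arm {self.arm!r}")

    @property
    def intervention_active(self) -> bool:
        return self.arm == "prs_guided" and self.stratum in ("top2", "next18")

    @property
    def statin_active(self) -> bool:
        return self.arm == "prs_guided" and self.stratum == "top2"


def annualize_risk(p_cum: float, years: int) -> float:
    """Convert a cumulative multi-year risk to a constant annual probability.

    Returns ``1 - (1 - p_cum)**(1/years)``; compounding the result over
    ``years`` cycles recovers ``p_cum`` exactly (to floating precision).
    """
    if not 0.0 <= p_cum < 1.0:
        raise ValueError(f"p_cum must be in [0, 1), got {p_cum}")
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    return 1.0 - (1.0 - p_cum) ** (1.0 / years)


@dataclass(frozen=True)
class TransitionTable:
    """Per-age annual transition probabilities for one stratum x arm.

    Arrays are indexed by cycle: index t covers ages ``entry_age + t`` to
    ``entry_age + t + 1``.  ``p_stay`` is implied as one minus the row sum.
    """

    stratum_arm: StratumArm
    entry_age: int
    end_age: int
    p_nonfatal_event: np.ndarray
    p_fatal_event: np.ndarray
    p_noncv_death: np.ndarray

    def __post_init__(self) -> None:
        n = self.end_age - self.entry_age
        for name in ("p_nonfatal_event", "p_fatal_event", "p_noncv_death"):
            a = getattr(self, name)
            if a.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {a.shape}")
            if np.any(a < 0) or np.any(a > 1):
                raise ValueError(f"{name} has entries outside [0, 1]")
        row = self.p_nonfatal_event + self.p_fatal_event + self.p_noncv_death
        if np.any(row > 1.0 + 1e-12):
            raise ValueError("transition row sums exceed 1")

    @property
    def n_cycles(self) -> int:
        return self.end_age - self.entry_age

    def ages(self) -> np.ndarray:
        return np.arange(self.entry_age, self.end_age)


def build_transition_table(
    params: ParameterSet,
    sa: StratumArm,
    *,
    event_start_age: int = EVENT_START_AGE,
    entry_age: int = ENTRY_AGE,
    end_age: int = END_AGE,
    background_mortality: np.ndarray | None = None,
) -> TransitionTable:
    """Assemble annual transition probabilities for one stratum and arm.

    Ages below ``event_start_age`` carry zero event risk (the model ignores
    pre-40 mortality and morbidity).  From ``event_start_age`` on, the
    high-PRS strata carry the annualized 10-year CAD and stroke incidences;
    the combined event probability treats the two hazards as independent,
    ``1 - (1 - a_cad) * (1 - a_stroke)``.  An active intervention multiplies
    event hazards by ``1 - relative_risk_reduction``; the acute fatality rate
    splits events into fatal and nonfatal.  ``background_mortality`` is an
    optional per-cycle non-cardiovascular death column (default all zero,
    keeping base-case traces self-contained).
    """
    n = end_age - entry_age
    if background_mortality is None:
        background_mortality = np.zeros(n)
    background_mortality = np.asarray(background_mortality, dtype=float)
    if background_mortality.shape != (n,):
        raise ValueError(f"background_mortality must have shape ({n},)")

    high_risk = sa.stratum in ("top2", "next18")
    if high_risk:
        a_cad = annualize_risk(params.value("cad_incidence_10y_top20"), 10)
        a_stroke = annualize_risk(params.value("stroke_incidence_10y_top20"), 10)
    else:
        # Top-20% risk is ~3x the population average; the bottom 80% gets the
        # complementary share (m/2 where top20 = 3m), i.e. one sixth of the
        # top-20% incidence, preserving the population mean.
        a_cad = annualize_risk(params.value("cad_incidence_10y_top20") / 6.0, 10)
        a_stroke = annualize_risk(params.value("stroke_incidence_10y_top20") / 6.0, 10)

    if sa.intervention_active:
        rrr = params.value("relative_risk_reduction")
        a_cad *= 1.0 - rrr
        a_stroke *= 1.0 - rrr

    p_event_on = 1.0 - (1.0 - a_cad) * (1.0 - a_stroke)
    fatality = params.value("cad_fatality")

    ages = np.arange(entry_age, end_age)
    active = ages >= event_start_age
    p_event = np.where(active, p_event_on, 0.0)
    p_fatal = fatality * p_event
    p_nonfatal = (1.0 - fatality) * p_event
    p_noncv = np.where(ages >= event_start_age, background_mortality, 0.0)

    if np.any(p_nonfatal + p_fatal + p_noncv > 1.0):
        raise ValueError("modified probabilities exceed 1; check inputs")
    return TransitionTable(
        stratum_arm=sa,
        entry_age=entry_age,
        end_age=end_age,
        p_nonfatal_event=p_nonfatal,
        p_fatal_event=p_fatal,
        p_noncv_death=p_noncv,
    )


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy over time for one stratum x arm cohort.

    ``occupancy`` has ``n_cycles + 1`` rows (the first is the entry
    distribution) and four columns ordered as :class:`HealthState`.
    """

    occupancy: np.ndarray
    entry_age: int = ENTRY_AGE
    end_age: int = END_AGE

    def __post_init__(self) -> None:
        n = self.end_age - self.entry_age
        if self.occupancy.shape != (n + 1, 4):
            raise ValueError(
                f"occupancy must have shape ({n + 1}, 4), got {self.occupancy.shape}"
            )
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _MASS_TOL):
            raise ValueError("occupancy rows must each sum to 1")
        dead = self.occupancy[:, [HealthState.CV_DEATH, HealthState.NONCV_DEATH]]
        if np.any(np.diff(dead, axis=0) < -_MASS_TOL):
            raise ValueError("death-state occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.end_age - self.entry_age

    def alive(self) -> np.ndarray:
        """Fraction alive at each cycle boundary."""
        return self.occupancy[:, [HealthState.EVENT_FREE, HealthState.POST_EVENT]].sum(
            axis=1
        )


def run_cohort_trace(table: TransitionTable) -> CohortTrace:
    """Propagate the cohort cycle-by-cycle through the transition table.

    The cohort starts 100% event-free.  Nonfatal events move mass to
    POST_EVENT, fatal events to CV_DEATH; non-cardiovascular death applies
    to both alive states; the death states retain all their mass.
    """
    n = table.n_cycles
    occ = np.zeros((n + 1, 4))
    occ[0, HealthState.EVENT_FREE] = 1.0
    for t in range(n):
        ef = occ[t, HealthState.EVENT_FREE]
        pe = occ[t, HealthState.POST_EVENT]
        pnf = table.p_nonfatal_event[t]
        pf = table.p_fatal_event[t]
        pnc = table.p_noncv_death[t]
        occ[t + 1, HealthState.EVENT_FREE] = ef * (1.0 - pnf - pf - pnc)
        occ[t + 1, HealthState.POST_EVENT] = pe * (1.0 - pnc) + ef * pnf
        occ[t + 1, HealthState.CV_DEATH] = occ[t, HealthState.CV_DEATH] + ef * pf
        occ[t + 1, HealthState.NONCV_DEATH] = (
            occ[t, HealthState.NONCV_DEATH] + (ef + pe) * pnc
        )
    return CohortTrace(occupancy=occ, entry_age=table.entry_age, end_age=table.end_age)


@dataclass(frozen=True)
class TraceSummary:
    life_expectancy: float
    discounted_qalys: float
    discounted_life_years: float
    undiscounted_qalys: float


def _band_utility(age: int, params: ParameterSet) -> float:
    if age < 40:
        return params.value("utility_10_40")
    if age < 60:
        return params.value("utility_40_60")
    return params.value("utility_60plus")


def summarize_trace(
    trace: CohortTrace,
    params: ParameterSet,
    *,
    discount_rate: float | None = None,
    post_event_utility_multiplier: float = 1.0,
) -> TraceSummary:
    """Life expectancy and (discounted) QALYs for a cohort trace.

    Life expectancy is the entry age plus undiscounted expected years alive.
    QALYs weight each cycle's alive occupancy by the age-band utility and the
    discount factor ``(1 + r)**-t``; the first cycle is undiscounted.  By
    default POST_EVENT carries the plain band utility
    (``post_event_utility_multiplier`` scales it for exploration) — per-case
    QALY impacts enter the economic ledger through fixed per-event
    quantities, not through a state-utility decrement.
    """
    r = params.value("discount_rate") if discount_rate is None else discount_rate
    le_years = 0.0
    d_ly = 0.0
    d_q = 0.0
    u_q = 0.0
    for t in range(trace.n_cycles):
        age = trace.entry_age + t
        ef = trace.occupancy[t, HealthState.EVENT_FREE]
        pe = trace.occupancy[t, HealthState.POST_EVENT]
        u = _band_utility(age, params)
        q_t = ef * u + pe * u * post_event_utility_multiplier
        df = (1.0 + r) ** (-t)
        le_years += ef + pe
        d_ly += (ef + pe) * df
        d_q += q_t * df
        u_q += q_t
    return TraceSummary(
        life_expectancy=trace.entry_age + le_years,
        discounted_qalys=d_q,
        discounted_life_years=d_ly,
        undiscounted_qalys=u_q,
    )


def trace_to_frame(trace: CohortTrace, params: ParameterSet) -> pd.DataFrame:
    """Trace as a table: cycle, age, occupancies, cumulative discounted LY/QALY."""
    r = params.value("discount_rate")
    rows = []
    cum_ly = 0.0
    cum_q = 0.0
    for t in range(trace.n_cycles + 1):
        age = trace.entry_age + t
        occ = trace.occupancy[t]
        if t < trace.n_cycles:
            df = (1.0 + r) ** (-t)
            alive = occ[HealthState.EVENT_FREE] + occ[HealthState.POST_EVENT]
            u = _band_utility(age, params)
            cum_ly += alive * df
            cum_q += alive * u * df
        rows.append(
            {
                "cycle": t,
                "age": age,
                "event_free": occ[HealthState.EVENT_FREE],
                "post_event": occ[HealthState.POST_EVENT],
                "cv_death": occ[HealthState.CV_DEATH],
                "noncv_death": occ[HealthState.NONCV_DEATH],
                "cum_discounted_ly": cum_ly,
                "cum_discounted_qaly": cum_q,
            }
        )
    return pd.DataFrame(rows)


class ScenarioProfile(BaseModel):
    """One illustrative projection row: survival, QALYs, and 10-year risks."""

    model_config = ConfigDict(frozen=True)
    life_expectancy: float
    qalys: float
    mi_risk: float  # percent
    stroke_risk: float  # percent
    fatal_mi: float  # percent

    @model_validator(mode="after")
    def _check(self) -> "ScenarioProfile":
        if self.fatal_mi > self.mi_risk:
            raise ValueError("fatal MI risk cannot exceed total MI risk")
        if self.qalys > self.life_expectancy:
            raise ValueError("QALYs cannot exceed life expectancy")
        return self


@dataclass(frozen=True)
class ScenarioDelta:
    """Element-wise differences and fold-changes between two scenario rows."""

    life_expectancy_gain: float
    qaly_gain: float
    mi_risk_reduction: float
    stroke_risk_reduction: float
    fatal_mi_reduction: float
    mi_risk_fold: float
    fatal_mi_fold: float


def project_scenario_delta(
    no_prevention: ScenarioProfile, with_prevention: ScenarioProfile
) -> ScenarioDelta:
    """Gains from prevention: differences (with - without) and risk folds.

    Fold-changes are without/with ratios (``inf`` when the prevented risk is
    zero and the unprevented risk is not, ``nan`` when both are zero).
    """

    def fold(a: float, b: float) -> float:
        if b == 0:
            return math.nan if a == 0 else math.inf
        return a / b

    return ScenarioDelta(
        life_expectancy_gain=with_prevention.life_expectancy
        - no_prevention.life_expectancy,
        qaly_gain=with_prevention.qalys - no_prevention.qalys,
        mi_risk_reduction=no_prevention.mi_risk - with_prevention.mi_risk,
        stroke_risk_reduction=no_prevention.stroke_risk - with_prevention.stroke_risk,
        fatal_mi_reduction=no_prevention.fatal_mi - with_prevention.fatal_mi,
        mi_risk_fold=fold(no_prevention.mi_risk, with_prevention.mi_risk),
        fatal_mi_fold=fold(no_prevention.fatal_mi, with_prevention.fatal_mi),
    )
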