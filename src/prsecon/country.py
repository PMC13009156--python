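"""Country-level localization of ICER and ROI.

Program costs scale with local healthcare cost levels (``cost_factor``,
GDP-per-capita-linked) and monetized benefits with local QALY valuations
(``benefit_factor``, HTA-threshold-linked); the reference country (USA)
has both factors equal to 1.  The shipped factor table is a synthetic
reconstruction back-derived from the published per-country ICER and ROI
cells (each cell divided by the USA cell), since the source analysis does
not print the factors themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ledger import BenefitLedger, ProgramCost, _round_half_up

__all__ = [
    "CountryProfile",
    "DEFAULT_COUNTRY_PROFILES",
    "apply_country_profile",
    "country_table",
]


@dataclass(frozen=True)
class CountryProfile:
    name: str
    cost_factor: float
    benefit_factor: float

    def __post_init__(self) -> None:
        if self.cost_factor <= 0 or self.benefit_factor <= 0:
            raise ValueError(f"{self.name}: scaling factors must be positive")


#: Back-derived (synthetic) localization factors for six high-income
#: countries; the USA row is the identity reference.
DEFAULT_COUNTRY_PROFILES: tuple[CountryProfile, ...] = (
    CountryProfile("USA", 1.00, 1.00),
    CountryProfile("UK", 0.75, 0.65),
    CountryProfile("Germany", 0.80, 0.75),
    CountryProfile("Canada", 0.85, 0.80),
    CountryProfile("Australia", 0.90, 0.80),
    CountryProfile("France", 0.85, 0.75),
)


def apply_country_profile(
    base: BenefitLedger, program_cost: ProgramCost, profile: CountryProfile
) -> tuple[float, float]:
    """Localized (ICER, ROI%) for one country.

    ICER scales the program cost only (QALYs are not re-valued in the
    ratio); ROI scales benefits and costs by their respective factors:
    ``ROI% = 100 * (b * benefit - c * cost) / (c * cost)``.
    """
    c = profile.cost_factor
    b = profile.benefit_factor
    qalys = _round_half_up(base.qalys_gained)
    icer = c * program_cost.total / qalys
    cost = c * program_cost.total
    roi = 100.0 * (b * base.total_benefit - cost) / cost
    return icer, roi


def country_table(
    base: BenefitLedger,
    program_cost: ProgramCost,
    profiles: tuple[CountryProfile, ...] = DEFAULT_COUNTRY_PROFILES,
) -> pd.DataFrame:
    """Per-country ICER and ROI table (reported precision: whole units)."""
    rows = []
    for p in profiles:
        icer, roi = apply_country_profile(base, program_cost, p)
        rows.append(
            {
                "country": p.name,
                "cost_factor": p.cost_factor,
                "benefit_factor": p.benefit_factor,
                "icer_usd_per_qaly": int(_round_half_up(icer)),
                "roi_pct": int(_round_half_up(roi)),
            }
        )
    return pd.DataFrame(rows)
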