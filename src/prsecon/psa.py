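"""Probabilistic sensitivity analysis over the benefit ledger.

Monte Carlo propagation of the parameter distributions: each draw samples
every non-fixed parameter once, recomputes the full cost-benefit ledger,
and records its line items.  Summaries are per-field means with empirical
2.5/97.5 percentile intervals; cost-effectiveness is summarized by net
monetary benefit (NMB) and the cost-effectiveness acceptability curve
(CEAC), the probability of positive NMB as a function of the
willingness-to-pay (WTP) threshold.

One ``numpy`` Generator seeded once drives the whole run, with a fixed
parameter visiting order per draw, so results are bit-reproducible for a
given ``(params, n, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ledger import BenefitLedger, compute_ledger
from .params import ParameterSet, sample_draw

__all__ = [
    "PSAResult",
    "DEFAULT_WTP_GRID",
    "run_psa",
    "nmb",
    "ceac_curve",
    "plot_ceac",
]

#: Default WTP grid: $0 to $100,000 per QALY in $1,000 steps.
DEFAULT_WTP_GRID: tuple[float, ...] = tuple(float(w) for w in range(0, 100_001, 1000))

_DRAW_COLUMNS = (
    "events_prevented",
    "arr_pct",
    "qalys_gained",
    "direct_savings",
    "qaly_value",
    "productivity",
    "screening_savings",
    "cobenefit",
    "total_benefit",
    "program_cost",
    "roi_pct",
    "icer",
    "npv_adjusted",
    "roi_adjusted_pct",
)


def nmb(delta_qalys: float, delta_cost: float, wtp: float) -> float:
    """Net monetary benefit: ``wtp * delta_qalys - delta_cost``."""
    return wtp * delta_qalys - delta_cost


def _ledger_row(ledger: BenefitLedger) -> dict[str, float]:
    return {
        "events_prevented": ledger.events_prevented,
        "arr_pct": ledger.arr_pct,
        "qalys_gained": ledger.qalys_gained,
        "direct_savings": ledger.direct_savings,
        "qaly_value": ledger.qaly_value,
        "productivity": ledger.productivity,
        "screening_savings": ledger.screening_savings,
        "cobenefit": ledger.cobenefit,
        "total_benefit": ledger.total_benefit,
        "program_cost": ledger.program_cost.total,
        "roi_pct": ledger.roi_pct,
        "icer": ledger.icer,
        "npv_adjusted": ledger.npv_adjusted,
        "roi_adjusted_pct": ledger.roi_adjusted_pct,
    }


@dataclass(frozen=True)
class PSAResult:
    """Per-draw ledger matrix plus summaries and the CEAC."""

    draws: pd.DataFrame
    n_draws: int
    seed: int
    summaries: pd.DataFrame
    ceac: pd.DataFrame

    def probability_cost_effective(self, wtp: float) -> float:
        """Fraction of draws with positive NMB at the given WTP threshold."""
        values = nmb(
            self.draws["qalys_gained"].to_numpy(),
            self.draws["program_cost"].to_numpy(),
            wtp,
        )
        return float(np.mean(values > 0))


def _summarize(draws: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mean": draws.mean(),
            "p2.5": draws.quantile(0.025),
            "p97.5": draws.quantile(0.975),
        }
    )


def ceac_curve(
    draws: pd.DataFrame | "PSAResult", wtp_grid: Sequence[float]
) -> pd.DataFrame:
    """Probability of positive NMB at each WTP threshold.

    ``wtp_grid`` must be nonempty and ascending.  QALY gains and program
    costs are taken per draw; the curve is non-decreasing whenever every
    draw gains QALYs.
    """
    if isinstance(draws, PSAResult):
        draws = draws.draws
    grid = list(wtp_grid)
    if not grid:
        raise ValueError("wtp_grid must be nonempty")
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("wtp_grid must be ascending")
    q = draws["qalys_gained"].to_numpy()
    c = draws["program_cost"].to_numpy()
    probs = [float(np.mean(nmb(q, c, w) > 0)) for w in grid]
    return pd.DataFrame({"wtp": grid, "probability": probs})


def run_psa(
    params: ParameterSet,
    n: int,
    seed: int,
    *,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
) -> PSAResult:
    """Run ``n`` Monte Carlo draws of the benefit ledger.

    Each draw samples one realization of every non-fixed parameter and
    recomputes the ledger with the same accounting (and rounding)
    conventions as the deterministic base case, so a degenerate all-fixed
    parameter set reproduces the base case in every draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        try:
            drawn = sample_draw(params, rng)
            ledger = compute_ledger(drawn)
        except ValueError as exc:
            raise ValueError(f"PSA draw {i} failed: {exc}") from exc
        rows.append(_ledger_row(ledger))
    draws = pd.DataFrame(rows, columns=list(_DRAW_COLUMNS))
    return PSAResult(
        draws=draws,
        n_draws=n,
        seed=seed,
        summaries=_summarize(draws),
        ceac=ceac_curve(draws, wtp_grid),
    )


def plot_ceac(
    result: PSAResult,
    path: str,
    *,
    icer: float | None = None,
) -> None:
    """Save a CEAC plot, optionally with a vertical marker at the ICER."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(result.ceac["wtp"], result.ceac["probability"], lw=2)
    if icer is not None:
        ax.axvline(icer, color="purple", ls="--", lw=1.5, label=f"ICER ${icer:,.0f}/QALY")
        ax.legend()
    ax.set_xlabel("Willingness to pay (USD per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
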