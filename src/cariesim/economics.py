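"""Discounting and cost-effectiveness outputs.

Costs are discounted at a fixed annual rate (3% base case) by the whole
year in which they occur; effectiveness (tooth retention years) is not
discounted.  Incremental results are summarized as ICERs with dominance
labels, cost-effectiveness-plane quadrant shares, and acceptability
curves (CEAC) built by net-monetary-benefit maximization over a
willingness-to-pay grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import PSAResults

DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"
UNDEFINED = "undefined"


def discount(cost: float, year: int, rate: float) -> float:
    """Present value of a cost incurred ``year`` whole years from now."""
    if year < 0:
        raise ValueError("year must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return cost / (1.0 + rate) ** year


def discount_factors(horizon: int, rate: float) -> np.ndarray:
    """Vector of 1/(1+r)^t for t = 0 .. horizon-1."""
    return (1.0 + rate) ** -np.arange(horizon, dtype=float)


def icer(mean_dc: float, mean_de: float):
    """Incremental cost-effectiveness ratio or a dominance label.

    The ratio is only meaningful in the trade-off quadrants; when the
    intervention is cheaper and more effective it is 'dominant', when
    costlier and less effective 'dominated'.
    """
    if mean_dc == 0 and mean_de == 0:
        return EQUIVALENT
    if mean_de == 0:
        return UNDEFINED
    if mean_dc < 0 and mean_de > 0:
        return DOMINANT
    if mean_dc > 0 and mean_de < 0:
        return DOMINATED
    return mean_dc / mean_de


def ce_plane_quadrant_shares(delta_costs, delta_effects) -> dict:
    """Share of PSA draws in each quadrant of the incremental CE plane.

    Boundary convention: Δe == 0 counts toward the more-effective side,
    Δc == 0 toward the less-costly side.
    """
    dc = np.asarray(delta_costs, dtype=float)
    de = np.asarray(delta_effects, dtype=float)
    if dc.size == 0:
        raise ValueError("empty set of CE points")
    if dc.shape != de.shape:
        raise ValueError("delta_costs and delta_effects must align")
    costly = dc > 0
    effective = de >= 0
    n = dc.size
    return {
        "more_costly_more_effective": float(np.sum(costly & effective)) / n,
        "more_costly_less_effective": float(np.sum(costly & ~effective)) / n,
        "less_costly_more_effective": float(np.sum(~costly & effective)) / n,
        "less_costly_less_effective": float(np.sum(~costly & ~effective)) / n,
    }


@dataclass
class CEACCurve:
    lambda_grid: np.ndarray
    acceptability: dict  # strategy label -> np.ndarray over the grid


def _nmb_matrix(psa: "PSAResults", lam: float) -> np.ndarray:
    return lam * psa.effects - psa.costs


def ceac(psa: "PSAResults", lambda_grid=None) -> CEACCurve:
    """Probability each strategy maximizes NMB, per willingness-to-pay λ.

    Ties (equal NMB) are split equally among the tied strategies, so the
    acceptability values sum to one across strategies at every λ.
    """
    if len(psa.strategies) < 2:
        raise ValueError("CEAC needs at least two strategies")
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 101.0)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    n = psa.n_draws
    curves = {s: np.zeros(lambda_grid.size) for s in psa.strategies}
    for i, lam in enumerate(lambda_grid):
        nmb = _nmb_matrix(psa, lam)
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb == best
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        share = weights.mean(axis=0)
        for j, s in enumerate(psa.strategies):
            curves[s][i] = share[j]
    return CEACCurve(lambda_grid, curves)
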