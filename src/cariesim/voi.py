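"""Value-of-information analysis.

Decision uncertainty is priced through the net monetary benefit
NMB(λ) = λ·effect − cost.  The expected value of perfect information
(EVPI) is the expected gain from learning all uncertain parameters
before choosing a strategy:

    EVPI(λ) = E[max_s NMB_s] − max_s E[NMB_s]

estimated over the PSA draws.  The expected value of partial perfect
information (EVPPI) for one parameter uses the single-loop
conditional-mean estimator: draws are grouped by the parameter's
sampled value (discrete parameters exactly, continuous ones by quantile
bins), the best strategy is chosen per group on group-mean NMB, and the
frequency-weighted average of those group maxima is compared with the
best overall strategy.  Both are reported per individual, in euros,
with nonparametric bootstrap standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import PSAResults


def nmb(lam: float, effect: float, cost: float) -> float:
    """Net monetary benefit at willingness-to-pay λ (euros per retention year)."""
    return lam * effect - cost


def _nmb_matrix(psa: "PSAResults", lam: float) -> np.ndarray:
    return lam * psa.effects - psa.costs


def evpi(psa: "PSAResults", lam: float) -> float:
    """Expected value of resolving all parameter uncertainty, per individual."""
    if len(psa.strategies) < 2:
        raise ValueError("EVPI needs at least two strategies")
    if psa.n_draws < 2:
        raise ValueError("EVPI needs at least two PSA draws")
    m = _nmb_matrix(psa, lam)
    return float(m.max(axis=1).mean() - m.mean(axis=0).max())


def _group_index(values: pd.Series, n_bins: int) -> np.ndarray:
    """Map each draw to a group id: discrete values group exactly,
    continuous ones by quantile bins."""
    if values.dtype == object or values.nunique() <= n_bins:
        codes, _ = pd.factorize(values)
        return codes.astype(np.intp)
    binned = pd.qcut(values, q=n_bins, duplicates="drop")
    return binned.cat.codes.to_numpy().astype(np.intp)


def _evppi_from_groups(m: np.ndarray, groups: np.ndarray) -> float:
    n = m.shape[0]
    n_groups = int(groups.max()) + 1
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    # group-mean NMB per strategy, then best strategy within each group;
    # groups absent from a bootstrap resample carry zero weight
    sums = np.zeros((n_groups, m.shape[1]))
    for j in range(m.shape[1]):
        sums[:, j] = np.bincount(groups, weights=m[:, j], minlength=n_groups)
    nz = counts > 0
    group_means = sums[nz] / counts[nz, None]
    perfect = float((group_means.max(axis=1) * counts[nz]).sum() / n)
    current = float(m.mean(axis=0).max())
    return perfect - current


def evppi(psa: "PSAResults", parameter_label: str, lam: float, n_bins: int = 10) -> float:
    """Expected value of perfect information on one parameter, per individual."""
    if parameter_label not in psa.sampled.columns:
        raise KeyError(
            f"parameter {parameter_label!r} was not recorded in the PSA draws"
        )
    m = _nmb_matrix(psa, lam)
    groups = _group_index(psa.sampled[parameter_label], n_bins)
    return _evppi_from_groups(m, groups)


@dataclass
class VOICurve:
    lambda_grid: np.ndarray
    values: np.ndarray  # euros per individual at each λ
    stderr: np.ndarray  # bootstrap MC standard error per point
    parameter_label: Optional[str] = None  # None for overall EVPI

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambda_grid,
                "value": self.values,
                "stderr": self.stderr,
                "parameter": self.parameter_label or "all",
            }
        )


def voi_curve(
    psa: "PSAResults",
    lambda_grid=None,
    parameter: Optional[str] = None,
    n_bins: int = 10,
    n_boot: int = 200,
    seed: int = 0,
) -> VOICurve:
    """EVPI (parameter=None) or EVPPI curve over a willingness-to-pay grid,
    with bootstrap-over-draws standard errors."""
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 101.0)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    n = psa.n_draws
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    boot_idx = rng.integers(0, n, size=(n_boot, n))

    groups = None
    if parameter is not None:
        if parameter not in psa.sampled.columns:
            raise KeyError(f"parameter {parameter!r} was not recorded in the PSA draws")
        groups = _group_index(psa.sampled[parameter], n_bins)

    values = np.empty(lambda_grid.size)
    stderr = np.empty(lambda_grid.size)
    for i, lam in enumerate(lambda_grid):
        m = _nmb_matrix(psa, lam)
        if groups is None:
            values[i] = float(m.max(axis=1).mean() - m.mean(axis=0).max())
            # vectorized bootstrap of the EVPI estimator
            rowmax = m.max(axis=1)
            boot = rowmax[boot_idx].mean(axis=1) - m[boot_idx].mean(axis=1).max(axis=1)
        else:
            values[i] = _evppi_from_groups(m, groups)
            boot = np.empty(n_boot)
            for b in range(n_boot):
                idx = boot_idx[b]
                boot[b] = _evppi_from_groups(m[idx], groups[idx])
        stderr[i] = float(boot.std(ddof=1))
    return VOICurve(lambda_grid, values, stderr, parameter)
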