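"""Derive tolerated-stability thresholds from constraint-stratified depletion.

Constrained genes are depleted of large-|ΔΔG| missense variation in
disease-free populations.  Scanning a grid of candidate cut-offs, the
tolerated interval is bounded by the smallest |t| at which the empirical
survival probability of the constrained stratum falls to a small fraction
(``depletion_cutoff``) of the unconstrained stratum's:

    upper = min { t > 0 : P̂_con(ΔΔG > t) / P̂_unc(ΔΔG > t) <= cutoff }

and symmetrically on the left tail.  The published analysis chose ±0.5
kcal/mol by inspection of exactly this depletion; the scan is a
formalisation of that choice.  Survival tails use strict inequalities,
matching the DoS boundary convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dos import StabilityThresholds, is_dos

DEFAULT_GRID_STEP = 0.05
DEFAULT_GRID_MAX = 3.0
# Chosen so that on faithful synthetic data (hard truncation of the
# constrained stratum at the true tolerated bounds) the scan recovers the
# truncation point itself rather than the shoulder below it.
DEFAULT_DEPLETION_CUTOFF = 0.1
DEFAULT_MIN_TAIL_N = 50


@dataclass
class DepletionScan:
    """Result of a two-tailed depletion scan.

    ``upper_tail_ratio[i]`` compares strata at +grid[i]; ``lower_tail_ratio``
    at −grid[i].  Ratios are NaN where the unconstrained tail was too thin
    to evaluate.  ``chosen`` is None when either tail found no qualifying
    grid point (sentinel).
    """

    grid: np.ndarray
    upper_tail_ratio: np.ndarray
    lower_tail_ratio: np.ndarray
    chosen_upper: float | None
    chosen_lower: float | None
    depletion_cutoff: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def chosen(self) -> StabilityThresholds | None:
        if self.chosen_upper is None or self.chosen_lower is None:
            return None
        return StabilityThresholds(lower=self.chosen_lower, upper=self.chosen_upper)


def _tail_ratio(
    constrained: np.ndarray,
    unconstrained: np.ndarray,
    grid: np.ndarray,
    min_tail_n: int,
    side: int,
) -> np.ndarray:
    """Survival-probability ratio constrained/unconstrained at each grid
    point (``side=+1`` right tail above +t, ``side=-1`` left tail below −t)."""
    ratios = np.full(grid.size, np.nan)
    for i, t in enumerate(grid):
        if side > 0:
            n_con = int((constrained > t).sum())
            n_unc = int((unconstrained > t).sum())
        else:
            n_con = int((constrained < -t).sum())
            n_unc = int((unconstrained < -t).sum())
        if n_unc < min_tail_n:
            continue
        p_con = n_con / constrained.size
        p_unc = n_unc / unconstrained.size
        ratios[i] = p_con / p_unc
    return ratios


def derive_thresholds(
    ddg_constrained: Sequence[float],
    ddg_unconstrained: Sequence[float],
    grid_step: float = DEFAULT_GRID_STEP,
    grid_max: float = DEFAULT_GRID_MAX,
    depletion_cutoff: float = DEFAULT_DEPLETION_CUTOFF,
    min_tail_n: int = DEFAULT_MIN_TAIL_N,
) -> DepletionScan:
    """Scan for the tolerated ΔΔG interval from two variant strata.

    Grid points whose unconstrained tail holds fewer than ``min_tail_n``
    variants are not evaluated; if no evaluated point qualifies on a tail,
    that tail's threshold is the None sentinel with a diagnostic.
    """
    con = np.asarray(ddg_constrained, dtype=float)
    unc = np.asarray(ddg_unconstrained, dtype=float)
    if con.size == 0 or unc.size == 0:
        raise ValueError("both ΔΔG samples must be nonempty")
    if not 0.0 < depletion_cutoff < 1.0:
        raise ValueError("depletion_cutoff must lie in (0,1)")
    n_steps = int(round(grid_max / grid_step))
    grid = grid_step * np.arange(1, n_steps + 1)

    upper_ratio = _tail_ratio(con, unc, grid, min_tail_n, side=+1)
    lower_ratio = _tail_ratio(con, unc, grid, min_tail_n, side=-1)

    diagnostics: dict = {
        "n_constrained": int(con.size),
        "n_unconstrained": int(unc.size),
        "n_evaluated_upper": int(np.isfinite(upper_ratio).sum()),
        "n_evaluated_lower": int(np.isfinite(lower_ratio).sum()),
    }

    def _choose(ratios: np.ndarray) -> float | None:
        ok = np.isfinite(ratios) & (ratios <= depletion_cutoff)
        if not ok.any():
            return None
        return float(grid[np.argmax(ok)])

    chosen_upper = _choose(upper_ratio)
    chosen_lower_mag = _choose(lower_ratio)
    if chosen_upper is None:
        diagnostics["upper"] = "no grid point reached the depletion cutoff"
    if chosen_lower_mag is None:
        diagnostics["lower"] = "no grid point reached the depletion cutoff"

    return DepletionScan(
        grid=grid,
        upper_tail_ratio=upper_ratio,
        lower_tail_ratio=lower_ratio,
        chosen_upper=chosen_upper,
        chosen_lower=None if chosen_lower_mag is None else -chosen_lower_mag,
        depletion_cutoff=depletion_cutoff,
        diagnostics=diagnostics,
    )


def compute_fdr(
    benign_ddgs: Sequence[float], thresholds: StabilityThresholds
) -> float:
    """Fraction of benign-labelled variants classified DoS (false discoveries)."""
    ddgs = np.asarray(benign_ddgs, dtype=float)
    if ddgs.size == 0:
        raise ValueError("benign ΔΔG list is empty")
    return float(is_dos(ddgs, thresholds).mean())


def distribution_summary(
    ddgs: Sequence[float],
    probs: Sequence[float] = (0.25, 0.5, 0.75),
) -> dict:
    """Deterministic box-plot summary of a ΔΔG sample.

    Quantiles use linear interpolation between order statistics; whiskers
    extend 1.5·IQR beyond the quartiles, clipped to the data range.
    """
    x = np.asarray(ddgs, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo = max(float(x.min()), q1 - 1.5 * iqr)
    hi = min(float(x.max()), q3 + 1.5 * iqr)
    return {
        "n": int(x.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(lo),
        "whisker_high": float(hi),
        "quantiles": {float(p): float(np.quantile(x, p, method="linear")) for p in probs},
    }
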