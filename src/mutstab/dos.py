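"""Disruption-of-Stability (DoS) classification and Instability Heat Scores.

A missense substitution is a DoS variant when its predicted stability
change lies outside the tolerated interval (default −0.5 to 0.5 kcal/mol).
The Instability Heat Score (IHS) of a protein is the mean of |ΔΔG| over
the set S of all possible substitutions whose absolute stability change
exceeds the threshold:

    IHS = (1/|S|) Σ_{i∈S} |ΔΔG_i|

so IHS is either 0 (empty S) or strictly greater than the threshold —
which makes the empty-S sentinel unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .codon import AA_INDEX, AA_ORDER
from .formats_io import DdgMatrix, VariantObservation

DEFAULT_THRESHOLD = 0.5

WT_TOKEN = "WT"


@dataclass(frozen=True)
class StabilityThresholds:
    """Tolerated ΔΔG interval; substitutions outside it are DoS.

    The boundary is strict: ΔΔG exactly at a cut-off is tolerated.  The
    interval may be asymmetric, though the IHS uses a single symmetric
    |ΔΔG| cutoff.
    """

    lower: float = -DEFAULT_THRESHOLD
    upper: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not (self.lower < 0.0 < self.upper):
            raise ValueError("thresholds must satisfy lower < 0 < upper")


CLASSES = ("destabilizing_dos", "stabilizing_dos", "tolerated")


def classify_substitution(ddg: float, thresholds: StabilityThresholds) -> str:
    """Partition a finite ΔΔG into one of three disjoint classes.

    ``tolerated`` iff ``lower <= ddg <= upper`` (strict-boundary
    convention: the cut-off itself is tolerated), ``destabilizing_dos``
    iff ``ddg > upper``, ``stabilizing_dos`` iff ``ddg < lower``.
    """
    ddg = float(ddg)
    if not np.isfinite(ddg):
        raise ValueError("ddg must be finite")
    if ddg > thresholds.upper:
        return "destabilizing_dos"
    if ddg < thresholds.lower:
        return "stabilizing_dos"
    return "tolerated"


def is_dos(ddg: np.ndarray, thresholds: StabilityThresholds) -> np.ndarray:
    """Vectorised DoS indicator (strict boundaries); NaN is never DoS."""
    ddg = np.asarray(ddg, dtype=float)
    return (ddg > thresholds.upper) | (ddg < thresholds.lower)


@dataclass(frozen=True)
class InstabilityHeatScore:
    protein_id: str
    value: float
    n_qualifying: int
    threshold_used: float

    def __post_init__(self) -> None:
        if (self.n_qualifying == 0) != (self.value == 0.0):
            raise ValueError("IHS must be 0 exactly when no substitution qualifies")
        if self.n_qualifying and self.value <= self.threshold_used:
            raise ValueError("a nonzero IHS must exceed the threshold")


def compute_ihs(matrix: DdgMatrix, threshold: float = DEFAULT_THRESHOLD) -> InstabilityHeatScore:
    """Instability Heat Score of one protein.

    Mean |ΔΔG| over all finite, non-wild-type cells with |ΔΔG| strictly
    above ``threshold``; 0 with ``n_qualifying = 0`` when no cell
    qualifies.  An entirely missing matrix is an error.
    """
    cells = matrix.substitution_values()
    if cells.size == 0:
        raise ValueError(f"{matrix.protein_id}: no non-missing substitution cells")
    mags = np.abs(cells)
    qualifying = mags[mags > threshold]
    if qualifying.size == 0:
        return InstabilityHeatScore(matrix.protein_id, 0.0, 0, threshold)
    return InstabilityHeatScore(
        matrix.protein_id, float(qualifying.mean()), int(qualifying.size), threshold
    )


def ihs_profile(
    matrix: DdgMatrix, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Per-position heat profile: mean |ΔΔG| over qualifying cells and
    their count at each position (0, 0 where nothing qualifies).

    The count-weighted mean of the profile equals :func:`compute_ihs`
    exactly.
    """
    if matrix.substitution_values().size == 0:
        raise ValueError(f"{matrix.protein_id}: no non-missing substitution cells")
    mags = np.abs(matrix.values)
    ok = np.isfinite(matrix.values) & ~matrix.wildtype_mask & (mags > threshold)
    counts = ok.sum(axis=1)
    sums = np.where(ok, mags, 0.0).sum(axis=1)
    means = np.divide(sums, counts, out=np.zeros(len(matrix)), where=counts > 0)
    return pd.DataFrame(
        {
            "position": np.arange(1, len(matrix) + 1),
            "mean_abs_ddg": means,
            "n_qualifying": counts,
        }
    )


def count_dos_fraction(
    variants: Iterable[VariantObservation], thresholds: StabilityThresholds
) -> tuple[int, int, float]:
    """(n_dos, n_total_missense, fraction) over missense variants with ΔΔG.

    Only missense variants carrying a ΔΔG prediction enter the
    denominator; zero eligible variants is an error rather than 0/0.
    """
    ddgs = np.array(
        [v.ddg for v in variants if v.consequence == "missense" and v.ddg is not None],
        dtype=float,
    )
    if ddgs.size == 0:
        raise ValueError("no missense variants with ΔΔG predictions")
    n_dos = int(is_dos(ddgs, thresholds).sum())
    return n_dos, int(ddgs.size), n_dos / ddgs.size


def ihs_table(
    matrices: Iterable[DdgMatrix], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Per-protein IHS table (gene_id, ihs, n_qualifying, threshold)."""
    rows = []
    for m in matrices:
        score = compute_ihs(m, threshold)
        rows.append(
            {
                "gene_id": m.protein_id,
                "ihs": score.value,
                "n_qualifying": score.n_qualifying,
                "threshold": score.threshold_used,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "ihs", "n_qualifying", "threshold"])


def export_heatmap_matrix(matrix: DdgMatrix, path: str | Path) -> None:
    """Lossless tabular export for mutational-scanning heatmaps.

    Rows are positions, columns the 20 amino acids; wild-type cells carry
    a distinguished token and missing predictions are empty fields.
    """
    grid = pd.DataFrame(
        matrix.values, index=np.arange(1, len(matrix) + 1), columns=list(AA_ORDER)
    )
    out = grid.astype(object)
    out = out.where(pd.notna(grid), "")
    wt = matrix.wildtype_mask
    for i in range(len(matrix)):
        for j in np.nonzero(wt[i])[0]:
            out.iat[i, j] = WT_TOKEN
    out.insert(0, "wt_aa", list(matrix.sequence))
    out.index.name = "position"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_heatmap_matrix(path: str | Path, protein_id: str | None = None) -> DdgMatrix:
    """Read a heatmap export back into a :class:`DdgMatrix` (round-trip)."""
    df = pd.read_csv(path, sep="\t", index_col="position", dtype=str, keep_default_na=False)
    seq = "".join(df["wt_aa"])
    values = np.full((len(df), len(AA_ORDER)), np.nan)
    for j, aa in enumerate(AA_ORDER):
        col = df[aa]
        for i, cell in enumerate(col):
            if cell == "" or cell == WT_TOKEN:
                continue
            values[i, j] = float(cell)
    return DdgMatrix(protein_id or Path(path).stem, seq, values)
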