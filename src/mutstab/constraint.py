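"""Observed/expected variant-count constraint scoring (LOEUF-style).

Expected counts come from a trinucleotide-context mutation-rate model:
every possible SNV of a coding sequence is enumerated, each qualifying
substitution contributes its context-specific relative rate, and a
calibration factor k (fitted on synonymous variation, which is assumed
neutral) maps summed rates onto expected cohort counts,

    E(class) = k * Σ_{SNV in class} rate(context, alt).

The per-gene constraint score is the upper bound of the 90% confidence
interval of the Poisson rate ratio O/E (the LOEUF convention; lower =
more constrained), computed for either pLoF variation (SNV nonsense) or
DoS variation (missense with |ΔΔG| beyond the tolerated threshold).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon import (
    AA64,
    AA_INDEX,
    BASES,
    STOP,
    cds_to_indices,
    codon_indices,
    consequences_of,
    reverse_complement,
)
from .dos import DEFAULT_THRESHOLD, StabilityThresholds, is_dos
from .formats_io import DdgMatrix, GeneModel, VariantObservation

logger = logging.getLogger("mutstab")

_BASE_ARR = np.array(list(BASES))
# for each reference base index, the three alternate base indices
_ALT_CHOICES = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


# ---------------------------------------------------------------------------
# Mutation-rate table
# ---------------------------------------------------------------------------

@dataclass
class MutationRateTable:
    """Relative per-site mutation rates keyed by (trinucleotide, alt base).

    A full table holds 64 contexts x 3 alternates.  A strand-collapsed
    table keeps only contexts with central base A or C; lookups for
    central G/T resolve through the reverse complement.
    """

    rates: dict[tuple[str, str], float]
    strand_collapsed: bool = False

    def __post_init__(self) -> None:
        centrals = "AC" if self.strand_collapsed else BASES
        expected_keys = {
            (a + c + b, alt)
            for c in centrals
            for a in BASES
            for b in BASES
            for alt in BASES
            if alt != c
        }
        if set(self.rates) != expected_keys:
            n_exp = len(expected_keys)
            raise ValueError(
                f"rate table must hold exactly the {n_exp} (context, alt) keys"
            )
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be nonnegative")

    def rate(self, context: str, alt: str) -> float:
        if self.strand_collapsed and context[1] in "GT":
            context, alt = reverse_complement(context), reverse_complement(alt)
        return self.rates[(context, alt)]

    @property
    def mean_rate(self) -> float:
        return float(np.mean(list(self.rates.values())))

    def to_series(self) -> pd.Series:
        """Rates for all 192 (context, alt) pairs, indexed ``CTX>ALT``."""
        data = {}
        for ctx in ("".join(t) for t in itertools.product(BASES, repeat=3)):
            for alt in BASES:
                if alt == ctx[1]:
                    continue
                data[f"{ctx}>{alt}"] = self.rate(ctx, alt)
        return pd.Series(data)

    @classmethod
    def uniform(cls, mu: float = 1.0) -> "MutationRateTable":
        rates = {
            (a + c + b, alt): mu
            for c in BASES
            for a in BASES
            for b in BASES
            for alt in BASES
            if alt != c
        }
        return cls(rates)

    @classmethod
    def default_human_like(cls) -> "MutationRateTable":
        """A caricature of empirical human trinucleotide rates: transitions
        4x transversions, CpG C→T (and its complement) boosted 12x,
        normalised to mean 1."""
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
        rates = {}
        for c in BASES:
            for a in BASES:
                for b in BASES:
                    ctx = a + c + b
                    for alt in BASES:
                        if alt == c:
                            continue
                        r = 4.0 if transition[c] == alt else 1.0
                        if c == "C" and b == "G" and alt == "T":
                            r *= 12.0
                        if c == "G" and a == "C" and alt == "A":
                            r *= 12.0
                        rates[(ctx, alt)] = r
        mean = np.mean(list(rates.values()))
        return cls({k: v / mean for k, v in rates.items()})

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"context": ctx, "alt": alt, "rate": r}
            for (ctx, alt), r in sorted(self.rates.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationRateTable":
        df = pd.read_csv(path, sep="\t", dtype={"context": str, "alt": str})
        rates = {
            (row["context"], row["alt"]): float(row["rate"]) for _, row in df.iterrows()
        }
        collapsed = all(k[0][1] in "AC" for k in rates)
        return cls(rates, strand_collapsed=collapsed)


# ---------------------------------------------------------------------------
# SNV enumeration
# ---------------------------------------------------------------------------

def enumerate_snvs(gene: GeneModel, allow_internal_stop: bool = False) -> pd.DataFrame:
    """Enumerate all 3L possible SNVs of a CDS with contexts and consequences.

    Returns a frame with columns ``position, ref, alt, context,
    aa_position, ref_aa, alt_aa, consequence``.  Edge positions lacking a
    flanking base get ``N`` in their context (marked partial).
    """
    idx = cds_to_indices(gene.cds)
    n = idx.size
    cod = codon_indices(idx)
    ref_aa_per_codon = AA64[cod]
    if not allow_internal_stop and STOP in ref_aa_per_codon[:-1]:
        raise ValueError(f"{gene.gene_id}: CDS contains an internal stop codon")

    offset = np.tile(np.array([0, 1, 2]), n // 3)
    mult = np.array([16, 4, 1])[offset]
    alt_idx = _ALT_CHOICES[idx]  # (n, 3)

    position = np.repeat(np.arange(1, n + 1), 3)
    ref_rep = np.repeat(idx, 3)
    alt_flat = alt_idx.ravel()
    codon_rep = np.repeat(np.repeat(cod, 3), 3)
    mult_rep = np.repeat(mult, 3)
    alt_codon = codon_rep + (alt_flat - ref_rep) * mult_rep

    prev = np.empty(n, dtype="<U1")
    nxt = np.empty(n, dtype="<U1")
    chars = _BASE_ARR[idx]
    prev[1:] = chars[:-1]
    prev[0] = gene.upstream_base or "N"
    nxt[:-1] = chars[1:]
    nxt[-1] = gene.downstream_base or "N"
    context = np.char.add(np.char.add(prev, chars), nxt)

    ref_aa = np.repeat(np.repeat(ref_aa_per_codon, 3), 3)
    alt_aa = AA64[alt_codon]
    return pd.DataFrame(
        {
            "position": position,
            "ref": _BASE_ARR[ref_rep],
            "alt": _BASE_ARR[alt_flat],
            "context": np.repeat(context, 3),
            "aa_position": np.repeat(np.arange(n) // 3 + 1, 3),
            "ref_aa": ref_aa,
            "alt_aa": alt_aa,
            "consequence": consequences_of(ref_aa, alt_aa),
        }
    )


def attach_ddg(enum: pd.DataFrame, matrix: DdgMatrix | None) -> pd.Series:
    """ΔΔG for each enumerated SNV (NaN for non-missense or missing cells)."""
    ddg = np.full(len(enum), np.nan)
    if matrix is None:
        return pd.Series(ddg, index=enum.index)
    missense = (enum["consequence"] == "missense").to_numpy()
    aa_pos = enum["aa_position"].to_numpy()
    in_range = missense & (aa_pos <= len(matrix))
    rows = aa_pos[in_range] - 1
    cols = enum["alt_aa"].map(AA_INDEX).to_numpy(dtype=float)
    ddg[in_range] = matrix.values[rows, cols[in_range].astype(int)]
    return pd.Series(ddg, index=enum.index)


# ---------------------------------------------------------------------------
# Expected counts and calibration
# ---------------------------------------------------------------------------

ClassPredicate = str | Callable[[pd.DataFrame], np.ndarray]


def _class_mask(
    enum: pd.DataFrame,
    class_predicate: ClassPredicate,
    ddg: pd.Series | None,
    threshold: float,
) -> tuple[np.ndarray, int]:
    """Boolean mask of qualifying SNVs plus the count of missense SNVs
    excluded from the DoS class for lack of a ΔΔG prediction."""
    n_missing = 0
    if callable(class_predicate):
        mask = np.asarray(class_predicate(enum), dtype=bool)
    elif class_predicate in ("nonsense", "missense", "synonymous", "stop_loss"):
        mask = (enum["consequence"] == class_predicate).to_numpy()
    elif class_predicate == "plof":
        mask = (enum["consequence"] == "nonsense").to_numpy()
    elif class_predicate == "all":
        mask = np.ones(len(enum), dtype=bool)
    elif class_predicate == "dos":
        if ddg is None:
            raise ValueError("the DoS class predicate requires a ΔΔG matrix")
        missense = (enum["consequence"] == "missense").to_numpy()
        vals = ddg.to_numpy()
        have = np.isfinite(vals)
        n_missing = int((missense & ~have).sum())
        mask = missense & have & (np.abs(vals) > threshold)
    else:
        raise ValueError(f"unknown class predicate {class_predicate!r}")
    return mask, n_missing


@dataclass(frozen=True)
class ExpectedCount:
    value: float
    n_qualifying_snvs: int
    n_missing_ddg: int = 0
    n_edge_imputed: int = 0


@dataclass(frozen=True)
class CalibrationFactor:
    """Scale k mapping summed relative rates to expected cohort counts."""

    k: float
    fitted_on: str = ""
    residuals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("calibration factor k must be positive")


def _snv_rates(
    enum: pd.DataFrame, rates: MutationRateTable, edge_policy: str
) -> tuple[np.ndarray, int]:
    key = enum["context"] + ">" + enum["alt"]
    r = key.map(rates.to_series()).to_numpy(dtype=float)
    partial = np.isnan(r)
    n_edge = int(partial.sum())
    if n_edge:
        if edge_policy == "error":
            ctx = enum.loc[partial, "context"].iloc[0]
            raise KeyError(f"no rate for partial context {ctx!r}")
        if edge_policy != "impute":
            raise ValueError(f"unknown edge policy {edge_policy!r}")
        r[partial] = rates.mean_rate
    return r, n_edge


def expected_class_count(
    gene: GeneModel,
    rates: MutationRateTable,
    k: CalibrationFactor,
    class_predicate: ClassPredicate,
    ddg_matrix: DdgMatrix | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    edge_policy: str = "impute",
    enum: pd.DataFrame | None = None,
) -> ExpectedCount:
    """E = k · Σ over qualifying SNVs of rate(context, alt).

    Missense SNVs without a ΔΔG prediction are excluded from the DoS
    class and tallied in the diagnostic.  Edge codons lacking flank
    context follow ``edge_policy`` (mean-rate imputation by default, with
    the imputed count reported).
    """
    if enum is None:
        enum = enumerate_snvs(gene)
    ddg = attach_ddg(enum, ddg_matrix) if ddg_matrix is not None else None
    mask, n_missing = _class_mask(enum, class_predicate, ddg, threshold)
    r, n_edge = _snv_rates(enum, rates, edge_policy)
    return ExpectedCount(
        value=float(k.k * r[mask].sum()),
        n_qualifying_snvs=int(mask.sum()),
        n_missing_ddg=n_missing,
        n_edge_imputed=n_edge,
    )


def calibrate_rate_scale(
    genes: Sequence[GeneModel],
    rates: MutationRateTable,
    observed_synonymous: Mapping[str, int],
    edge_policy: str = "impute",
    enums: Mapping[str, pd.DataFrame] | None = None,
) -> CalibrationFactor:
    """Fit k on synonymous variation: k = Σ observed / Σ per-gene rate sums.

    This is the least-squares-through-origin slope over genes.  Zero total
    rate sum or zero total observed count is a degenerate calibration and
    raises.
    """
    rows = []
    for g in genes:
        enum = enums[g.gene_id] if enums is not None else enumerate_snvs(g)
        mask, _ = _class_mask(enum, "synonymous", None, 0.0)
        r, _ = _snv_rates(enum, rates, edge_policy)
        rows.append(
            {
                "gene_id": g.gene_id,
                "rate_sum": float(r[mask].sum()),
                "observed": float(observed_synonymous.get(g.gene_id, 0)),
            }
        )
    df = pd.DataFrame(rows)
    total_rate = df["rate_sum"].sum()
    total_obs = df["observed"].sum()
    if total_rate <= 0:
        raise ValueError("total synonymous rate sum is zero; cannot calibrate")
    if total_obs <= 0:
        raise ValueError("no observed synonymous variants; degenerate calibration")
    k = total_obs / total_rate
    df["expected"] = k * df["rate_sum"]
    df["residual"] = df["observed"] - df["expected"]
    return CalibrationFactor(
        k=float(k),
        fitted_on=f"synonymous variants of {len(genes)} genes",
        residuals=df,
    )


# ---------------------------------------------------------------------------
# LOEUF upper bound
# ---------------------------------------------------------------------------

DEFAULT_CI = 0.90
DEFAULT_CAP = 2.0


def loeuf_upper_bound(
    observed: int | np.ndarray,
    expected: float | np.ndarray,
    ci: float = DEFAULT_CI,
    cap: float = DEFAULT_CAP,
) -> float | np.ndarray:
    """Upper bound of the ``ci`` confidence interval of the ratio O/E.

    With O ~ Poisson(r·E) and a flat prior on the rate ratio r, the
    posterior of r is Gamma(shape O+1, rate E); the bound is its
    (1+ci)/2 quantile, min-capped at ``cap``.  For O = 0 this reduces to
    the closed form −ln((1−ci)/2)/E.
    """
    observed_arr = np.asarray(observed)
    expected_arr = np.asarray(expected, dtype=float)
    if (observed_arr < 0).any():
        raise ValueError("observed count must be nonnegative")
    if (expected_arr <= 0).any():
        raise ValueError("expected count must be positive")
    if not 0.0 < ci < 1.0:
        raise ValueError("ci must lie in (0,1)")
    q = (1.0 + ci) / 2.0
    bound = stats.gamma.ppf(q, a=observed_arr + 1, scale=1.0 / expected_arr)
    bound = np.minimum(bound, cap)
    return float(bound) if np.isscalar(observed) and np.isscalar(expected) else bound


def loeuf_upper_bound_grid(
    observed: int,
    expected: float,
    ci: float = DEFAULT_CI,
    cap: float = DEFAULT_CAP,
    step: float = 0.001,
) -> float:
    """Grid evaluation of the same bound: accumulate the normalised Poisson
    likelihood over a rate-ratio grid until (1+ci)/2 of the mass is
    covered, then cap.  The grid extends past the cap far enough to cover
    the likelihood mass, so the two methods agree to within ~2 grid steps.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed < 0:
        raise ValueError("observed count must be nonnegative")
    sd = np.sqrt(observed + 1) / expected
    r_max = max(cap, (observed + 1) / expected + 12 * sd, 20.0 / expected)
    r = np.arange(step, r_max + step, step)
    loglik = observed * np.log(r * expected) - r * expected
    w = np.exp(loglik - loglik.max())
    cum = np.cumsum(w)
    q = (1.0 + ci) / 2.0
    idx = int(np.searchsorted(cum, q * cum[-1]))
    return float(min(r[min(idx, r.size - 1)], cap))


# ---------------------------------------------------------------------------
# Deciles, confusion, ranking
# ---------------------------------------------------------------------------

def assign_deciles(scores: Mapping[str, float] | pd.Series) -> pd.Series:
    """Ascending-rank decile bins 0–9 (bin 0 = lowest scores = most
    constrained).  Bin sizes are equal up to the remainder, which goes to
    the lowest bins; ties are broken by gene_id lexicographic order."""
    s = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    n = len(s)
    if n < 10:
        raise ValueError(f"need at least 10 genes to assign deciles, got {n}")
    order = sorted(s.index, key=lambda g: (s[g], g))
    base, rem = divmod(n, 10)
    sizes = [base + 1] * rem + [base] * (10 - rem)
    bins = np.repeat(np.arange(10), sizes)
    return pd.Series(bins, index=order, name="decile").sort_index()


def decile_confusion(
    bins_a: Mapping[str, int] | pd.Series, bins_b: Mapping[str, int] | pd.Series
) -> np.ndarray:
    """10x10 matrix of gene counts: cell (i, j) counts genes in bin i under
    A and bin j under B.  Both inputs must cover the same gene universe."""
    a = pd.Series(dict(bins_a)) if not isinstance(bins_a, pd.Series) else bins_a
    b = pd.Series(dict(bins_b)) if not isinstance(bins_b, pd.Series) else bins_b
    if set(a.index) != set(b.index):
        diff = sorted(set(a.index) ^ set(b.index))
        raise ValueError(f"gene universes differ; symmetric difference {diff}")
    mat = np.zeros((10, 10), dtype=int)
    for g in a.index:
        mat[int(a[g]), int(b[g])] += 1
    return mat


@dataclass(frozen=True)
class ConstraintRecord:
    """Per-gene observed/expected constraint for one variant class."""

    gene_id: str
    variant_class: str
    observed: int
    expected: float
    oe: float
    loeuf: float
    decile: int | None = None

    def __post_init__(self) -> None:
        if self.observed < 0:
            raise ValueError("observed must be nonnegative")
        if self.expected <= 0:
            raise ValueError("expected must be positive")


def observed_class_counts(
    variants: Iterable[VariantObservation],
    variant_class: str,
    thresholds: StabilityThresholds | None = None,
    matrices: Mapping[str, DdgMatrix] | None = None,
) -> pd.Series:
    """Distinct qualifying variants (gene, pos, ref, alt) per gene with
    allele_count >= 1.  ``plof`` counts nonsense SNVs; ``dos`` counts
    missense SNVs whose ΔΔG (from the variant or looked up in
    ``matrices``) is outside the tolerated interval."""
    if variant_class == "dos" and thresholds is None:
        thresholds = StabilityThresholds()
    seen: set[tuple] = set()
    counts: dict[str, int] = {}
    for v in variants:
        if v.allele_count < 1:
            continue
        key = (v.gene_id, v.nt_position, v.ref_base, v.alt_base)
        if key in seen:
            continue
        seen.add(key)
        if variant_class in ("plof", "nonsense"):
            ok = v.consequence == "nonsense"
        elif variant_class == "synonymous":
            ok = v.consequence == "synonymous"
        elif variant_class == "missense":
            ok = v.consequence == "missense"
        elif variant_class == "dos":
            if v.consequence != "missense":
                ok = False
            else:
                ddg = v.ddg
                if ddg is None and matrices is not None and v.gene_id in matrices:
                    m = matrices[v.gene_id]
                    if v.aa_position <= len(m):
                        val = m.get(v.aa_position, v.alt_aa)
                        ddg = None if np.isnan(val) else val
                ok = ddg is not None and bool(is_dos(ddg, thresholds))
        else:
            raise ValueError(f"unknown variant class {variant_class!r}")
        if ok:
            counts[v.gene_id] = counts.get(v.gene_id, 0) + 1
    return pd.Series(counts, dtype=int)


def constraint_table(
    genes: Sequence[GeneModel],
    variants: Iterable[VariantObservation],
    rates: MutationRateTable,
    k: CalibrationFactor,
    variant_class: str,
    matrices: Mapping[str, DdgMatrix] | None = None,
    thresholds: StabilityThresholds | None = None,
    ci: float = DEFAULT_CI,
    cap: float = DEFAULT_CAP,
    edge_policy: str = "impute",
    enums: Mapping[str, pd.DataFrame] | None = None,
    assign_decile_bins: bool = True,
) -> pd.DataFrame:
    """Per-gene observed, expected, O/E and LOEUF for one variant class.

    Gene order follows the input; deciles (bin 0 most constrained) are
    assigned over the LOEUF column when there are at least 10 genes.
    """
    if variant_class not in ("plof", "dos"):
        raise ValueError("variant_class must be 'plof' or 'dos'")
    thr = thresholds or StabilityThresholds()
    observed = observed_class_counts(variants, variant_class, thr, matrices)
    rows = []
    for g in genes:
        enum = enums[g.gene_id] if enums is not None else enumerate_snvs(g)
        matrix = matrices.get(g.gene_id) if matrices else None
        exp = expected_class_count(
            g, rates, k, variant_class,
            ddg_matrix=matrix, threshold=thr.upper,
            edge_policy=edge_policy, enum=enum,
        )
        obs = int(observed.get(g.gene_id, 0))
        expected = exp.value
        rows.append(
            {
                "gene_id": g.gene_id,
                "variant_class": variant_class,
                "observed": obs,
                "expected": expected,
                "oe": obs / expected if expected > 0 else np.nan,
                "loeuf": loeuf_upper_bound(obs, expected, ci, cap)
                if expected > 0
                else np.nan,
                "n_missing_ddg": exp.n_missing_ddg,
            }
        )
    df = pd.DataFrame(rows)
    if assign_decile_bins and len(df) >= 10:
        deciles = assign_deciles(df.set_index("gene_id")["loeuf"])
        df["decile"] = df["gene_id"].map(deciles).astype(int)
    return df


def rank_loeuf_differences(
    records_plof: pd.DataFrame, records_dos: pd.DataFrame
) -> pd.DataFrame:
    """Genes ordered by |LOEUF_plof − LOEUF_dos|, descending, carrying the
    observed/expected columns of both classes (ties broken by gene_id)."""
    cols = ["gene_id", "observed", "expected", "oe", "loeuf"]
    merged = records_plof[cols].merge(
        records_dos[cols], on="gene_id", suffixes=("_plof", "_dos"), how="inner"
    )
    if merged.empty:
        raise ValueError("no genes shared between the two constraint tables")
    merged["loeuf_diff"] = merged["loeuf_plof"] - merged["loeuf_dos"]
    merged["abs_loeuf_diff"] = merged["loeuf_diff"].abs()
    return merged.sort_values(
        ["abs_loeuf_diff", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
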