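"""Synthetic genes, ΔΔG matrices, structure tracks and cohort variants.

The generator reproduces the statistical structure the analysis assumes,
so that every pipeline stage can be exercised without external downloads:

* per-gene selection strength s in [0,1] drives purifying selection —
  candidate variants whose stability effect exceeds the tolerated bound
  (and nonsense candidates) are retained with probability (1 − s), so the
  retained ΔΔG distribution narrows with s, the depletion signal the
  threshold scan inverts;
* more constrained genes (higher s) carry more intrinsic disorder, and
  disordered residues have near-neutral stability effects while ordered
  regions of constrained genes draw from a tighter spread — producing
  lower instability heat scores with constraint;
* pLDDT tracks are high in ordered blocks and low in disordered blocks;
* clinical labels skew pathogenic variants towards destabilising ΔΔG,
  and benign labels carry a small contamination of DoS cells matching
  the false-discovery rate measured against curated benign variants.

Selection acts as hard thinning (not a diffusion model): sufficient to
create the depletion being measured, and analytically checkable.  ΔΔG
draws are independent across cells; disorder forms contiguous blocks so
confidence tracks look AlphaFold-like.  Everything is deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon import AA64, AA_INDEX, AA_ORDER, CODONS, STOP
from .constraint import MutationRateTable, attach_ddg, enumerate_snvs
from .formats_io import (
    DdgMatrix,
    GeneModel,
    StructureConfidence,
    VariantObservation,
    write_cds_fasta,
    write_ddg_table,
    write_variants_tsv,
)

_SENSE_CODONS = [c for c, aa in zip(CODONS, AA64) if aa != STOP]
_STOP_CODONS = [c for c, aa in zip(CODONS, AA64) if aa == STOP]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Lengths are log-normal in amino acids (median ≈ 400, matching the
    human proteome); selection strengths are Beta-distributed over [0,1];
    spreads are in kcal/mol.  ``site_mutation_rate`` is the per-site,
    per-individual probability scale from which observation probabilities
    over the cohort are derived.
    """

    n_genes: int = 200
    length_log_mean: float = 6.0  # log amino acids; median ~403
    length_log_sd: float = 0.45
    min_length_aa: int = 60
    selection_beta_a: float = 0.6
    selection_beta_b: float = 0.6
    selection_s: Sequence[float] | None = None
    disorder_base: float = 0.10
    disorder_slope: float = 0.40  # E[disordered fraction] = base + slope*s
    sigma_disordered: float = 0.15
    sigma_ordered_base: float = 1.0
    sigma_ordered_slope: float = 0.5  # sigma_ordered(s) = base*(1 - slope*s)
    truncation_threshold: float = 0.5
    pathogenic_skew: float = 0.8
    benign_contamination: float = 0.06
    cohort_size: int = 1000
    site_mutation_rate: float = 5e-5
    rates: MutationRateTable = field(
        default_factory=MutationRateTable.default_human_like
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for name in ("sigma_disordered", "sigma_ordered_base", "length_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "disorder_base", "disorder_slope", "pathogenic_skew",
            "benign_contamination",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if not 0.0 <= self.sigma_ordered_slope < 1.0:
            raise ValueError("sigma_ordered_slope must lie in [0,1)")
        if self.selection_s is not None and len(self.selection_s) != self.n_genes:
            raise ValueError("selection_s must provide one value per gene")

    def sigma_ordered(self, s: float) -> float:
        return self.sigma_ordered_base * (1.0 - self.sigma_ordered_slope * s)


def generate_genes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Random coding sequences plus the per-gene truth table (s, disorder).

    Every CDS starts with ATG, contains no internal stop, and ends with a
    stop codon; the flanking bases needed for edge trinucleotide contexts
    are drawn as well.
    """
    rng = rng or np.random.default_rng(config.seed)
    lengths = np.exp(
        rng.normal(config.length_log_mean, config.length_log_sd, config.n_genes)
    )
    lengths = np.maximum(np.round(lengths).astype(int), config.min_length_aa)
    if config.selection_s is not None:
        s_values = np.asarray(config.selection_s, dtype=float)
    else:
        s_values = rng.beta(
            config.selection_beta_a, config.selection_beta_b, config.n_genes
        )
    disorder = np.clip(config.disorder_base + config.disorder_slope * s_values, 0, 1)

    width = len(str(config.n_genes))
    genes, truth_rows = [], []
    for i in range(config.n_genes):
        L = int(lengths[i])
        body = rng.choice(_SENSE_CODONS, size=L - 1)
        stop = rng.choice(_STOP_CODONS)
        cds = "ATG" + "".join(body) + stop
        gid = f"G{i + 1:0{width}d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                transcript_id=f"T{i + 1:0{width}d}",
                cds=cds,
                upstream_base=str(rng.choice(list("ACGT"))),
                downstream_base=str(rng.choice(list("ACGT"))),
            )
        )
        truth_rows.append(
            {
                "gene_id": gid,
                "s": float(s_values[i]),
                "disorder_fraction": float(disorder[i]),
                "length_aa": L,
            }
        )
    return genes, pd.DataFrame(truth_rows)


def _disorder_mask(L: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Contiguous disordered blocks (two-state segment model) totalling
    approximately ``fraction`` of the chain."""
    mask = np.zeros(L, dtype=bool)
    target = int(round(fraction * L))
    if target <= 0:
        return mask
    if target >= L:
        return np.ones(L, dtype=bool)
    n_blocks = min(1 + int(rng.poisson(1)), target)
    # split the disordered budget into block lengths ...
    cuts = (
        np.sort(rng.choice(np.arange(1, target), size=n_blocks - 1, replace=False))
        if n_blocks > 1
        else np.array([], dtype=int)
    )
    block_lengths = np.diff(np.concatenate([[0], cuts, [target]]))
    # ... and the ordered remainder into the surrounding gaps, so coverage
    # is exact (no block overlap)
    free = L - target
    gap_cuts = np.sort(rng.integers(0, free + 1, size=n_blocks))
    gap_lengths = np.diff(np.concatenate([[0], gap_cuts]))
    pos = 0
    for gap, block in zip(gap_lengths, block_lengths):
        pos += int(gap)
        mask[pos : pos + int(block)] = True
        pos += int(block)
    return mask


def generate_ddg_matrices(
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[
    dict[str, DdgMatrix], dict[str, np.ndarray], dict[str, StructureConfidence]
]:
    """ΔΔG grids, per-residue disorder masks and pLDDT tracks per gene.

    Disordered cells draw from Normal(0, sigma_disordered); ordered cells
    from Normal(0, sigma_ordered(s)) which tightens with selection
    strength.  Wild-type cells are exactly 0.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    info = truth.set_index("gene_id")
    matrices: dict[str, DdgMatrix] = {}
    masks: dict[str, np.ndarray] = {}
    tracks: dict[str, StructureConfidence] = {}
    for gene in genes:
        protein = gene.protein
        L = len(protein)
        s = float(info.loc[gene.gene_id, "s"])
        frac = float(info.loc[gene.gene_id, "disorder_fraction"])
        mask = _disorder_mask(L, frac, rng)
        sigma = np.where(mask, config.sigma_disordered, config.sigma_ordered(s))
        values = rng.normal(0.0, 1.0, size=(L, len(AA_ORDER))) * sigma[:, None]
        for i, aa in enumerate(protein):
            values[i, AA_INDEX[aa]] = 0.0
        matrices[gene.gene_id] = DdgMatrix(gene.gene_id, protein, values)
        masks[gene.gene_id] = mask
        plddt = np.where(
            mask, rng.normal(45.0, 8.0, L), rng.normal(88.0, 5.0, L)
        )
        tracks[gene.gene_id] = StructureConfidence(
            protein_id=gene.gene_id,
            residue_index=np.arange(1, L + 1),
            values=np.clip(plddt, 0.0, 100.0),
            source_kind="predicted_model",
        )
    return matrices, masks, tracks


def simulate_population_variants(
    genes: Sequence[GeneModel],
    matrices: Mapping[str, DdgMatrix],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    cohort_label: str = "synthetic_cohort",
    enums: Mapping[str, pd.DataFrame] | None = None,
) -> list[VariantObservation]:
    """Cohort variants under mutation-rate-driven sampling and purifying
    selection.

    Each possible SNV is observed as a candidate with probability
    ``1 − exp(−rate · cohort_size · site_mutation_rate)``.  Candidates are
    then thinned: missense with |ΔΔG| beyond the tolerated bound and
    nonsense (and the rare stop-loss) survive with probability (1 − s);
    synonymous and tolerated missense always survive.  Distinct variants
    only, allele counts geometric.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    rate_series = config.rates.to_series()
    mean_rate = config.rates.mean_rate
    info = truth.set_index("gene_id")
    out: list[VariantObservation] = []
    for gene in genes:
        enum = enums[gene.gene_id] if enums is not None else enumerate_snvs(gene)
        s = float(info.loc[gene.gene_id, "s"])
        r = (enum["context"] + ">" + enum["alt"]).map(rate_series).to_numpy(dtype=float)
        r = np.where(np.isnan(r), mean_rate, r)
        if not r.sum() > 0:
            raise ValueError("mutation-rate table sums to zero")
        p_obs = 1.0 - np.exp(-r * config.cohort_size * config.site_mutation_rate)
        candidate = rng.random(len(enum)) < p_obs

        ddg = attach_ddg(enum, matrices.get(gene.gene_id)).to_numpy()
        cons = enum["consequence"].to_numpy()
        deleterious = (
            ((cons == "missense")
             & np.isfinite(ddg)
             & (np.abs(ddg) > config.truncation_threshold))
            | (cons == "nonsense")
            | (cons == "stop_loss")
        )
        survive = ~deleterious | (rng.random(len(enum)) < (1.0 - s))
        keep = candidate & survive
        if not keep.any():
            continue
        sub = enum[keep]
        kept_ddg = ddg[keep]
        acs = rng.geometric(0.6, size=len(sub))  # support {1,2,...}
        for (pos, ref, alt, aa_pos, ref_aa, alt_aa, consequence), d, ac in zip(
            sub[
                ["position", "ref", "alt", "aa_position", "ref_aa", "alt_aa",
                 "consequence"]
            ].itertuples(index=False),
            kept_ddg,
            acs,
        ):
            out.append(
                VariantObservation(
                    gene_id=gene.gene_id,
                    nt_position=int(pos),
                    ref_base=ref,
                    alt_base=alt,
                    aa_position=int(aa_pos),
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    consequence=consequence,
                    ddg=float(d)
                    if consequence == "missense" and np.isfinite(d)
                    else None,
                    cohort_label=cohort_label,
                    allele_count=int(ac),
                )
            )
    return out


def generate_clinical_labels(
    genes: Sequence[GeneModel],
    matrices: Mapping[str, DdgMatrix],
    config: SimulationConfig,
    n_benign: int = 1000,
    n_pathogenic: int = 1000,
    rng: np.random.Generator | None = None,
    enums: Mapping[str, pd.DataFrame] | None = None,
) -> tuple[list[VariantObservation], list[VariantObservation]]:
    """Benign and pathogenic missense label sets.

    Both are sampled from SNV-reachable missense substitutions so the
    codon-consistency invariant holds.  Benign variants come from
    tolerated cells with a small DoS contamination
    (``benign_contamination``); pathogenic variants put ``pathogenic_skew``
    extra mass on destabilising (ΔΔG > upper) cells, the remainder drawn
    from all missense cells — producing the destabilising skew seen in
    curated pathogenic variation.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    frames = []
    for gene in genes:
        enum = enums[gene.gene_id] if enums is not None else enumerate_snvs(gene)
        sub = enum[enum["consequence"] == "missense"].copy()
        sub["ddg"] = attach_ddg(sub, matrices.get(gene.gene_id)).to_numpy()
        sub = sub[np.isfinite(sub["ddg"])]
        sub["gene_id"] = gene.gene_id
        frames.append(sub)
    pool = pd.concat(frames, ignore_index=True)
    thr = config.truncation_threshold
    tolerated = pool[pool["ddg"].abs() <= thr]
    dos = pool[pool["ddg"].abs() > thr]
    destab = pool[pool["ddg"] > thr]
    if tolerated.empty or destab.empty:
        raise ValueError("no qualifying cells to draw clinical labels from")

    def _sample(frame: pd.DataFrame, n: int) -> pd.DataFrame:
        idx = rng.integers(0, len(frame), size=n)
        return frame.iloc[idx]

    n_contam = int(rng.binomial(n_benign, config.benign_contamination))
    benign_rows = pd.concat(
        [_sample(tolerated, n_benign - n_contam), _sample(dos, n_contam)],
        ignore_index=True,
    )
    n_skew = int(rng.binomial(n_pathogenic, config.pathogenic_skew))
    pathogenic_rows = pd.concat(
        [_sample(destab, n_skew), _sample(pool, n_pathogenic - n_skew)],
        ignore_index=True,
    )

    def _to_variants(rows: pd.DataFrame, label: str) -> list[VariantObservation]:
        return [
            VariantObservation(
                gene_id=r.gene_id,
                nt_position=int(r.position),
                ref_base=r.ref,
                alt_base=r.alt,
                aa_position=int(r.aa_position),
                ref_aa=r.ref_aa,
                alt_aa=r.alt_aa,
                consequence="missense",
                ddg=float(r.ddg),
                clinical_label=label,
            )
            for r in rows.itertuples(index=False)
        ]

    return _to_variants(benign_rows, "benign"), _to_variants(pathogenic_rows, "pathogenic")


def write_simulation(
    outdir: str | Path,
    genes: Sequence[GeneModel],
    matrices: Mapping[str, DdgMatrix],
    truth: pd.DataFrame,
    variants: Sequence[VariantObservation],
    benign: Sequence[VariantObservation],
    pathogenic: Sequence[VariantObservation],
    config: SimulationConfig,
) -> dict[str, Path]:
    """Write every fixture in the pipeline's own input formats, so
    generated data exercises the real readers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cds_fasta": outdir / "genes.fasta",
        "ddg_table": outdir / "ddg.tsv",
        "truth": outdir / "truth.tsv",
        "variants": outdir / "variants.tsv",
        "clinical": outdir / "clinical_variants.tsv",
        "rates": outdir / "rates.tsv",
    }
    write_cds_fasta(genes, paths["cds_fasta"])
    write_ddg_table([matrices[g.gene_id] for g in genes], paths["ddg_table"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    write_variants_tsv(variants, paths["variants"])
    write_variants_tsv(list(benign) + list(pathogenic), paths["clinical"])
    config.rates.to_tsv(paths["rates"])
    return paths
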