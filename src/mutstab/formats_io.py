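"""Readers and writers for every external format the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`DdgMatrix` (per-protein substitution stability grids),
:class:`GeneModel` (coding sequences), :class:`VariantObservation`
(observed or simulated coding variants), :class:`StructureConfidence`
(per-residue B-factor / pLDDT tracks) and :class:`GeneAnnotation`
(external constraint labels).

Conventions: 1-based, CDS-relative coordinates; ΔΔG in kcal/mol with
positive values destabilising; the canonical ΔΔG exchange format is a
long TSV with columns ``protein_id, position, ref_aa, alt_aa, ddg``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import (
    AA_INDEX,
    AA_ORDER,
    BASES,
    STOP,
    consequence_of,
    translate_cds,
)

logger = logging.getLogger("mutstab")


class ParseError(ValueError):
    """A malformed record in an input file (names the offending line)."""


class ConsistencyError(ValueError):
    """Input that parses but violates an internal consistency rule."""


# ---------------------------------------------------------------------------
# ΔΔG matrices
# ---------------------------------------------------------------------------

@dataclass
class DdgMatrix:
    """Exhaustive L x 20 grid of predicted stability changes for one protein.

    ``values[i, j]`` is the ΔΔG (kcal/mol) of substituting position ``i+1``
    (1-based) with amino acid ``AA_ORDER[j]``.  ``NaN`` marks a missing
    prediction.  Wild-type cells (the residue already present) are excluded
    from every aggregation via :attr:`wildtype_mask`.  Unknown residues in a
    partially reconstructed sequence are written ``X``.
    """

    protein_id: str
    sequence: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(AA_ORDER):
            raise ValueError("values must be an L x 20 array")
        if self.values.shape[0] != len(self.sequence):
            raise ValueError(
                f"{self.protein_id}: grid has {self.values.shape[0]} rows "
                f"but sequence length is {len(self.sequence)}"
            )
        bad = set(self.sequence) - set(AA_ORDER) - {"X"}
        if bad:
            raise ValueError(f"{self.protein_id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def wildtype_mask(self) -> np.ndarray:
        """Boolean L x 20 mask of wild-type cells."""
        mask = np.zeros_like(self.values, dtype=bool)
        for i, aa in enumerate(self.sequence):
            j = AA_INDEX.get(aa)
            if j is not None:
                mask[i, j] = True
        return mask

    def substitution_values(self) -> np.ndarray:
        """All finite, non-wild-type ΔΔG values as a flat array."""
        keep = np.isfinite(self.values) & ~self.wildtype_mask
        return self.values[keep]

    def get(self, position: int, alt_aa: str) -> float:
        """ΔΔG at a 1-based position for an alternate residue (NaN if absent)."""
        return float(self.values[position - 1, AA_INDEX[alt_aa]])


_DDG_COLUMNS = ["protein_id", "position", "ref_aa", "alt_aa", "ddg"]


def read_ddg_table(path: str | Path, dialect: str = "long_tsv") -> list[DdgMatrix]:
    """Read a long-format ΔΔG TSV into one :class:`DdgMatrix` per protein.

    Positions never seen for a protein become all-missing rows with residue
    ``X``; duplicated ``(protein, position, alt)`` keys with conflicting ΔΔG
    raise :class:`ConsistencyError`; rows whose ``ref_aa`` disagrees with an
    earlier row at the same position do too.
    """
    if dialect != "long_tsv":
        raise ValueError(f"unknown ΔΔG dialect {dialect!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("ΔΔG table %s is empty; returning no matrices", path)
        return []
    missing = [c for c in _DDG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("ΔΔG table %s has a header but no rows", path)
        return []

    lines = df.index + 2  # header is line 1
    pos = pd.to_numeric(df["position"], errors="coerce")
    bad = pos.isna() | (pos < 1) | (pos != pos.round())
    if bad.any():
        raise ParseError(
            f"{path}: malformed position on line {lines[bad.values][0]}"
        )
    ddg = pd.to_numeric(df["ddg"], errors="coerce")
    bad = ddg.isna() & df["ddg"].notna() & (df["ddg"].str.strip() != "")
    if bad.any():
        raise ParseError(f"{path}: malformed ddg on line {lines[bad.values][0]}")
    for col in ("ref_aa", "alt_aa"):
        ok = df[col].isin(list(AA_ORDER))
        if not ok.all():
            raise ParseError(
                f"{path}: invalid {col} on line {lines[(~ok).values][0]}"
            )
    if (df["ref_aa"] == df["alt_aa"]).any():
        line = lines[(df["ref_aa"] == df["alt_aa"]).values][0]
        raise ParseError(f"{path}: wild-type cell listed as a row on line {line}")

    work = pd.DataFrame(
        {
            "protein_id": df["protein_id"],
            "position": pos.astype(int),
            "ref_aa": df["ref_aa"],
            "alt_aa": df["alt_aa"],
            "ddg": ddg,
        }
    )
    key = ["protein_id", "position", "alt_aa"]
    dup = work.duplicated(key, keep=False)
    if dup.any():
        grouped = work[dup].groupby(key)["ddg"].nunique(dropna=False)
        conflicting = grouped[grouped > 1]
        if not conflicting.empty:
            raise ConsistencyError(
                f"{path}: conflicting duplicate rows for "
                f"{conflicting.index[0]}"
            )
        work = work.drop_duplicates(key)

    matrices: list[DdgMatrix] = []
    for pid, grp in work.groupby("protein_id", sort=False):
        length = int(grp["position"].max())
        seq = np.full(length, "X", dtype="<U1")
        refs = grp.groupby("position")["ref_aa"].agg(["nunique", "first"])
        if (refs["nunique"] > 1).any():
            p = int(refs.index[(refs["nunique"] > 1).values][0])
            raise ConsistencyError(
                f"{path}: inconsistent ref_aa for protein {pid} position {p}"
            )
        seq[refs.index.to_numpy() - 1] = refs["first"].to_numpy()
        values = np.full((length, len(AA_ORDER)), np.nan)
        rows = grp["position"].to_numpy() - 1
        cols = grp["alt_aa"].map(AA_INDEX).to_numpy()
        values[rows, cols] = grp["ddg"].to_numpy()
        matrices.append(DdgMatrix(str(pid), "".join(seq), values))
    return matrices


def write_ddg_table(matrices: Iterable[DdgMatrix], path: str | Path) -> None:
    """Write matrices to the canonical long TSV (missing/wild-type cells omitted)."""
    frames = []
    for m in matrices:
        keep = np.isfinite(m.values) & ~m.wildtype_mask
        rows, cols = np.nonzero(keep)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": m.protein_id,
                    "position": rows + 1,
                    "ref_aa": [m.sequence[r] for r in rows],
                    "alt_aa": [AA_ORDER[c] for c in cols],
                    "ddg": m.values[rows, cols],
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_DDG_COLUMNS)
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A canonical coding sequence for one gene.

    ``upstream_base``/``downstream_base`` are the single flanking
    nucleotides needed to give the first and last CDS positions a full
    trinucleotide context; when absent, edge contexts are marked partial.
    """

    gene_id: str
    cds: str
    transcript_id: str | None = None
    upstream_base: str | None = None
    downstream_base: str | None = None

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        if not self.cds or len(self.cds) % 3:
            raise ValueError(f"{self.gene_id}: CDS length must be a positive multiple of 3")
        if set(self.cds) - set(BASES):
            raise ValueError(f"{self.gene_id}: CDS contains non-ACGT bases")
        for attr in ("upstream_base", "downstream_base"):
            b = getattr(self, attr)
            if b is not None:
                b = b.upper()
                if b not in BASES:
                    raise ValueError(f"{self.gene_id}: {attr} must be one of {BASES}")
                setattr(self, attr, b)

    @property
    def protein(self) -> str:
        """Translation of the CDS, without a terminal stop if present."""
        return translate_cds(self.cds)

    def __len__(self) -> int:
        return len(self.cds)


def read_cds_fasta(
    path: str | Path,
    transcript_table: str | Path | Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Read coding sequences from FASTA; record ids are gene ids.

    ``key=value`` tokens in the description (``transcript=``, ``upstream=``,
    ``downstream=``) are honoured; a separate two-column TSV (gene_id,
    transcript_id) may supply transcript ids instead.
    """
    tx: Mapping[str, str] = {}
    if transcript_table is not None:
        if isinstance(transcript_table, Mapping):
            tx = transcript_table
        else:
            t = pd.read_csv(transcript_table, sep="\t", dtype=str)
            tx = dict(zip(t.iloc[:, 0], t.iloc[:, 1]))
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(
            t.split("=", 1) for t in rec.description.split()[1:] if "=" in t
        )
        genes.append(
            GeneModel(
                gene_id=rec.id,
                cds=str(rec.seq),
                transcript_id=tokens.get("transcript", tx.get(rec.id)),
                upstream_base=tokens.get("upstream"),
                downstream_base=tokens.get("downstream"),
            )
        )
    return genes


def write_cds_fasta(genes: Iterable[GeneModel], path: str | Path) -> None:
    records = []
    for g in genes:
        tokens = []
        if g.transcript_id:
            tokens.append(f"transcript={g.transcript_id}")
        if g.upstream_base:
            tokens.append(f"upstream={g.upstream_base}")
        if g.downstream_base:
            tokens.append(f"downstream={g.downstream_base}")
        records.append(
            SeqRecord(Seq(g.cds), id=g.gene_id, description=" ".join(tokens))
        )
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

CLINICAL_LABELS = ("benign", "pathogenic", "unlabeled")


@dataclass
class VariantObservation:
    """One observed or simulated single-nucleotide coding variant."""

    gene_id: str
    nt_position: int
    ref_base: str
    alt_base: str
    aa_position: int
    ref_aa: str
    alt_aa: str
    consequence: str
    ddg: float | None = None
    cohort_label: str = ""
    clinical_label: str = "unlabeled"
    allele_count: int = 1

    def __post_init__(self) -> None:
        from .codon import CONSEQUENCES

        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.clinical_label not in CLINICAL_LABELS:
            raise ValueError(f"unknown clinical label {self.clinical_label!r}")
        if self.allele_count < 0:
            raise ValueError("allele_count must be nonnegative")
        if self.consequence != "missense" and self.ddg is not None:
            raise ValueError("ddg is defined for missense variants only")


def annotate_snv(gene: GeneModel, nt_position: int, ref: str, alt: str) -> dict:
    """Codon-level annotation of a CDS SNV (1-based position)."""
    if not 1 <= nt_position <= len(gene.cds):
        raise IndexError(f"position {nt_position} outside CDS of {gene.gene_id}")
    if gene.cds[nt_position - 1] != ref:
        raise ConsistencyError(
            f"{gene.gene_id}:{nt_position} reference {ref!r} does not match "
            f"CDS base {gene.cds[nt_position - 1]!r}"
        )
    aa_pos = (nt_position - 1) // 3 + 1
    start = (aa_pos - 1) * 3
    codon = gene.cds[start : start + 3]
    offset = (nt_position - 1) % 3
    alt_codon = codon[:offset] + alt + codon[offset + 1 :]
    ref_aa = translate_cds(codon, strip_terminal_stop=False)
    alt_aa = translate_cds(alt_codon, strip_terminal_stop=False)
    return {
        "aa_position": aa_pos,
        "ref_aa": ref_aa,
        "alt_aa": alt_aa,
        "consequence": consequence_of(ref_aa, alt_aa),
    }


@dataclass
class VariantReadResult:
    """Variants plus tallies of records skipped during reading."""

    variants: list[VariantObservation]
    skipped: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES


def read_variants_vcf(
    path: str | Path,
    genes: Sequence[GeneModel] | Mapping[str, GeneModel],
    cohort_label: str = "",
) -> VariantReadResult:
    """Read SNVs from a VCF whose CHROM column holds gene ids and POS is
    the 1-based CDS coordinate.  Multiallelic records are split; non-SNV
    alleles and positions outside the CDS are skipped and tallied."""
    import pysam

    gene_map = genes if isinstance(genes, Mapping) else {g.gene_id: g for g in genes}
    result = VariantReadResult([])
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.chrom not in gene_map:
                raise KeyError(f"unknown gene_id {rec.chrom!r} in VCF")
            gene = gene_map[rec.chrom]
            for alt in rec.alts or ():
                if not _is_snv(rec.ref, alt):
                    result.skipped["non_snv"] += 1
                    continue
                if not 1 <= rec.pos <= len(gene.cds):
                    result.skipped["outside_cds"] += 1
                    continue
                ann = annotate_snv(gene, rec.pos, rec.ref, alt)
                try:
                    clnsig = str(rec.info.get("CLNSIG", "")).lower()
                except (KeyError, ValueError):  # tag absent from the header
                    clnsig = ""
                label = clnsig if clnsig in CLINICAL_LABELS else "unlabeled"
                try:
                    ac = rec.info.get("AC", 1)
                except (KeyError, ValueError):
                    ac = 1
                if isinstance(ac, tuple):
                    ac = ac[0]
                result.variants.append(
                    VariantObservation(
                        gene_id=gene.gene_id,
                        nt_position=rec.pos,
                        ref_base=rec.ref,
                        alt_base=alt,
                        cohort_label=cohort_label,
                        clinical_label=label,
                        allele_count=int(ac),
                        **ann,
                    )
                )
    if result.skipped:
        logger.info("VCF %s: skipped %s", path, dict(result.skipped))
    return result


_VARIANT_COLUMNS = [
    "gene_id", "nt_position", "ref_base", "alt_base", "aa_position",
    "ref_aa", "alt_aa", "consequence", "ddg", "cohort_label",
    "clinical_label", "allele_count",
]


def read_variants_tsv(
    path: str | Path,
    genes: Sequence[GeneModel] | Mapping[str, GeneModel] | None = None,
    cohort_label: str = "",
) -> VariantReadResult:
    """Read variants from TSV.  If consequence columns are absent, gene
    models must be supplied so records can be annotated by codon
    translation."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    gene_map = None
    if genes is not None:
        gene_map = genes if isinstance(genes, Mapping) else {g.gene_id: g for g in genes}
    has_annotation = {"aa_position", "ref_aa", "alt_aa", "consequence"} <= set(df.columns)
    if not has_annotation and gene_map is None:
        raise ParseError(f"{path}: no consequence columns and no gene models supplied")
    result = VariantReadResult([])
    for _, row in df.iterrows():
        ref, alt = str(row["ref_base"]), str(row["alt_base"])
        if not _is_snv(ref, alt):
            result.skipped["non_snv"] += 1
            continue
        pos = int(row["nt_position"])
        if has_annotation:
            ann = {
                "aa_position": int(row["aa_position"]),
                "ref_aa": str(row["ref_aa"]),
                "alt_aa": str(row["alt_aa"]),
                "consequence": str(row["consequence"]),
            }
        else:
            if row["gene_id"] not in gene_map:
                raise KeyError(f"unknown gene_id {row['gene_id']!r}")
            gene = gene_map[row["gene_id"]]
            if not 1 <= pos <= len(gene.cds):
                result.skipped["outside_cds"] += 1
                continue
            ann = annotate_snv(gene, pos, ref, alt)
        ddg = row.get("ddg")
        ddg = None if pd.isna(ddg) or ann["consequence"] != "missense" else float(ddg)
        cohort = row.get("cohort_label", cohort_label)
        clinical = row.get("clinical_label", "unlabeled")
        ac = row.get("allele_count", 1)
        result.variants.append(
            VariantObservation(
                gene_id=str(row["gene_id"]),
                nt_position=pos,
                ref_base=ref,
                alt_base=alt,
                ddg=ddg,
                cohort_label=str(cohort) if pd.notna(cohort) and cohort else "",
                clinical_label=str(clinical) if pd.notna(clinical) and clinical else "unlabeled",
                allele_count=int(ac) if pd.notna(ac) else 1,
                **ann,
            )
        )
    if result.skipped:
        logger.info("TSV %s: skipped %s", path, dict(result.skipped))
    return result


def read_variants(
    path: str | Path,
    format: str,
    genes: Sequence[GeneModel] | Mapping[str, GeneModel] | None = None,
    cohort_label: str = "",
) -> VariantReadResult:
    """Dispatch to the VCF or TSV variant reader."""
    if format == "vcf":
        if genes is None:
            raise ValueError("VCF reading requires gene models")
        return read_variants_vcf(path, genes, cohort_label)
    if format == "tsv":
        return read_variants_tsv(path, genes, cohort_label)
    raise ValueError(f"unknown variant format {format!r}")


def variants_to_frame(variants: Iterable[VariantObservation]) -> pd.DataFrame:
    rows = [
        {c: getattr(v, c if c != "ddg" else "ddg") for c in _VARIANT_COLUMNS}
        for v in variants
    ]
    df = pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
    return df


def write_variants_tsv(variants: Iterable[VariantObservation], path: str | Path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Structure confidence
# ---------------------------------------------------------------------------

SOURCE_KINDS = ("experimental", "predicted_model")


@dataclass
class StructureConfidence:
    """Per-residue confidence values for one structure.

    ``values`` hold crystallographic B-factors (Å²) for experimental
    structures, or pLDDT (0–100, sometimes 0–1) for predicted models — both
    are stored in the B-factor column of PDB/mmCIF files.
    """

    protein_id: str
    residue_index: np.ndarray
    values: np.ndarray
    source_kind: str = "experimental"

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.residue_index.shape != self.values.shape:
            raise ValueError("residue_index and values must align")
        if self.residue_index.size and (np.diff(self.residue_index) <= 0).any():
            raise ValueError("residue indices must be strictly increasing")
        if self.values.size and (~np.isfinite(self.values) | (self.values < 0)).any():
            raise ValueError("confidence values must be finite and nonnegative")
        if self.source_kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source_kind {self.source_kind!r}")

    @property
    def per_residue(self) -> list[tuple[int, float]]:
        return list(zip(self.residue_index.tolist(), self.values.tolist()))

    def __len__(self) -> int:
        return len(self.values)


def read_structure_confidence(
    path: str | Path,
    chain: str | None = None,
    source_kind: str | None = None,
) -> StructureConfidence:
    """Extract per-residue Cα B-factors from a PDB or mmCIF file.

    The first polypeptide chain is used unless ``chain`` names one.
    Residues lacking a Cα fall back to the mean B-factor over their atoms
    (logged).  ``source_kind`` is detected from the file title when it
    mentions AlphaFold, otherwise defaults to experimental; pass it
    explicitly to override.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    selected = None
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        has_protein = any(
            gemmi.find_tabulated_residue(res.name) is not None
            and gemmi.find_tabulated_residue(res.name).is_amino_acid()
            for res in ch
        )
        if has_protein or chain is not None:
            selected = ch
            break
    if selected is None:
        raise ParseError(f"{path}: no polypeptide chain" + (f" {chain!r}" if chain else ""))

    indices, values = [], []
    for res in selected:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        ca = res.find_atom("CA", "*")
        if ca is not None:
            b = ca.b_iso
        else:
            atoms = [a.b_iso for a in res]
            if not atoms:
                continue
            b = float(np.mean(atoms))
            logger.info(
                "%s: residue %s%d lacks Cα; using mean of %d atom B-factors",
                path, res.name, res.seqid.num, len(atoms),
            )
        indices.append(res.seqid.num)
        values.append(b)
    if not values:
        raise ParseError(f"{path}: no amino-acid residues with B-factors")

    if source_kind is None:
        info_title = st.info["_struct.title"] if "_struct.title" in st.info else ""
        title = " ".join([st.name or "", info_title])
        source_kind = (
            "predicted_model" if "alphafold" in title.lower() else "experimental"
        )
    return StructureConfidence(
        protein_id=st.name or Path(path).stem,
        residue_index=np.array(indices),
        values=np.array(values),
        source_kind=source_kind,
    )


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

SHET_CATEGORIES = ("extreme", "strong", "weak", "neutral")


@dataclass
class GeneAnnotation:
    """External per-gene constraint labels, consumed but never computed."""

    gene_id: str
    loeuf_published: float | None = None
    pli: float | None = None
    shet_category: str | None = None
    bayes_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"{self.gene_id}: pLi must lie in [0,1]")
        if self.shet_category is not None and self.shet_category not in SHET_CATEGORIES:
            raise ValueError(f"{self.gene_id}: unknown S_het category {self.shet_category!r}")


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a per-gene annotation TSV.

    Recognised columns: ``gene_id``, ``loeuf``, ``pli``, ``shet_category``
    and any number of ``bf_<class>`` Bayes-factor columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    bf_cols = [c for c in df.columns if c.startswith("bf_")]
    out = []
    for _, row in df.iterrows():
        out.append(
            GeneAnnotation(
                gene_id=row["gene_id"],
                loeuf_published=float(row["loeuf"]) if pd.notna(row.get("loeuf")) else None,
                pli=float(row["pli"]) if pd.notna(row.get("pli")) else None,
                shet_category=row["shet_category"]
                if pd.notna(row.get("shet_category"))
                else None,
                bayes_factors={
                    c[3:]: float(row[c]) for c in bf_cols if pd.notna(row[c])
                },
            )
        )
    return out


def annotations_to_frame(annotations: Iterable[GeneAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        row = {
            "gene_id": a.gene_id,
            "loeuf": a.loeuf_published,
            "pli": a.pli,
            "shet_category": a.shet_category,
        }
        for k, v in a.bayes_factors.items():
            row[f"bf_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
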