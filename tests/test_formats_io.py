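"""I/O round trips, parse-error reporting, and codon-level annotation."""

import textwrap

import numpy as np
import pytest
from Bio.Seq import Seq

from mutstab.codon import AA_ORDER, BASES
from mutstab.formats_io import (
    ConsistencyError,
    GeneModel,
    ParseError,
    StructureConfidence,
    annotate_snv,
    read_cds_fasta,
    read_ddg_table,
    read_structure_confidence,
    read_variants,
    read_variants_tsv,
    write_cds_fasta,
    write_ddg_table,
    write_variants_tsv,
)

from conftest import random_gene, random_matrix, write_toy_pdb


# ---------------------------------------------------------------------------
# ΔΔG tables
# ---------------------------------------------------------------------------

def _write(tmp_path, text, name="ddg.tsv"):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


class TestDdgTable:
    def test_toy_three_rows(self, tmp_path):
        p = _write(
            tmp_path,
            """\
            protein_id\tposition\tref_aa\talt_aa\tddg
            P1\t1\tM\tA\t0.5
            P1\t1\tM\tC\t-0.25
            P1\t1\tM\tD\t1.5
            """,
        )
        (m,) = read_ddg_table(p)
        assert m.sequence == "M" and len(m) == 1
        assert np.isfinite(m.values).sum() == 3
        assert m.get(1, "A") == 0.5 and m.get(1, "D") == 1.5
        assert np.isnan(m.get(1, "E"))

    def test_empty_file_and_header_only(self, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        assert read_ddg_table(empty) == []
        header = _write(tmp_path, "protein_id\tposition\tref_aa\talt_aa\tddg\n", "h.tsv")
        assert read_ddg_table(header) == []

    def test_conflicting_duplicates_raise(self, tmp_path):
        p = _write(
            tmp_path,
            """\
            protein_id\tposition\tref_aa\talt_aa\tddg
            P1\t2\tM\tA\t0.5
            P1\t2\tM\tA\t0.6
            """,
        )
        with pytest.raises(ConsistencyError, match="P1"):
            read_ddg_table(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(
            tmp_path,
            """\
            protein_id\tposition\tref_aa\talt_aa\tddg
            P1\t1\tM\tA\t0.5
            P1\tx\tM\tC\t0.5
            """,
        )
        with pytest.raises(ParseError, match="line 3"):
            read_ddg_table(p)

    def test_inconsistent_ref_raises(self, tmp_path):
        p = _write(
            tmp_path,
            """\
            protein_id\tposition\tref_aa\talt_aa\tddg
            P1\t1\tM\tA\t0.5
            P1\t1\tW\tC\t0.5
            """,
        )
        with pytest.raises(ConsistencyError, match="position 1"):
            read_ddg_table(p)

    def test_unseen_positions_become_missing_rows(self, tmp_path):
        p = _write(
            tmp_path,
            """\
            protein_id\tposition\tref_aa\talt_aa\tddg
            P1\t3\tK\tA\t0.5
            """,
        )
        (m,) = read_ddg_table(p)
        assert m.sequence == "XXK"
        assert np.isfinite(m.values[:2]).sum() == 0

    def test_round_trip(self, tmp_path, rng):
        mats = [random_matrix(rng, missing_fraction=0.2, protein_id=f"P{i}")
                for i in range(4)]
        out = tmp_path / "rt.tsv"
        write_ddg_table(mats, out)
        back = read_ddg_table(out)
        assert [m.protein_id for m in back] == [m.protein_id for m in mats]
        for a, b in zip(mats, back):
            assert a.sequence == b.sequence
            keep = np.isfinite(a.values) & ~a.wildtype_mask
            np.testing.assert_allclose(
                a.values[keep], b.values[keep], rtol=1e-5
            )
            assert not np.isfinite(b.values[~keep]).any()


# ---------------------------------------------------------------------------
# Gene models / FASTA
# ---------------------------------------------------------------------------

class TestGeneModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            GeneModel("g", cds="ATGA")  # not a codon multiple
        with pytest.raises(ValueError):
            GeneModel("g", cds="ATGNNN")
        g = GeneModel("g", cds="ATGTGGTAA")
        assert g.protein == "MW"

    def test_fasta_round_trip(self, tmp_path, rng):
        genes = [random_gene(rng, n_codons=5, gene_id=f"g{i}") for i in range(3)]
        p = tmp_path / "cds.fasta"
        write_cds_fasta(genes, p)
        back = read_cds_fasta(p)
        for a, b in zip(genes, back):
            assert (a.gene_id, a.cds, a.upstream_base, a.downstream_base) == (
                b.gene_id, b.cds, b.upstream_base, b.downstream_base
            )


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="allele count">
##contig=<ID=TOY,length=9>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
TOY\t6\t.\tG\tA\t.\t.\tAC=3
TOY\t6\t.\tGT\tG\t.\t.\t.
TOY\t4\t.\tT\tA\t.\t.\t.
"""


class TestVariants:
    def test_vcf_nonsense_and_indel_skip(self, toy_gene, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_TEXT)
        result = read_variants(p, "vcf", [toy_gene])
        assert result.skipped["non_snv"] == 1
        nonsense = [v for v in result if v.nt_position == 6]
        assert nonsense[0].consequence == "nonsense"  # TGG -> TGA
        assert nonsense[0].allele_count == 3
        missense = [v for v in result if v.nt_position == 4]
        assert missense[0].consequence == "missense"  # TGG -> AGG (W->R)

    def test_vcf_unknown_gene_raises(self, toy_gene, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_TEXT.replace("TOY\t6", "NOPE\t6", 1))
        with pytest.raises(KeyError):
            read_variants(p, "vcf", [toy_gene])

    def test_synonymous_third_position(self):
        gene = GeneModel("g", cds="ATGGGGTAA")
        ann = annotate_snv(gene, 6, "G", "A")  # GGG -> GGA
        assert ann["consequence"] == "synonymous"

    def test_outside_cds_skipped_and_tallied(self, toy_gene, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "gene_id\tnt_position\tref_base\talt_base\n"
            "TOY\t50\tG\tA\n"
            "TOY\t6\tG\tA\n"
        )
        result = read_variants_tsv(p, [toy_gene])
        assert result.skipped["outside_cds"] == 1
        assert len(result) == 1

    def test_annotation_matches_biopython_oracle(self, rng):
        """Every SNV of random toy genes agrees with direct re-translation."""
        for _ in range(5):
            gene = random_gene(rng, n_codons=8)
            for pos in range(1, len(gene.cds) + 1):
                ref = gene.cds[pos - 1]
                for alt in BASES:
                    if alt == ref:
                        continue
                    ann = annotate_snv(gene, pos, ref, alt)
                    mutated = gene.cds[: pos - 1] + alt + gene.cds[pos:]
                    ref_aa = str(Seq(gene.cds).translate())
                    alt_aa = str(Seq(mutated).translate())
                    i = (pos - 1) // 3
                    assert ann["ref_aa"] == ref_aa[i]
                    assert ann["alt_aa"] == alt_aa[i]
                    if ref_aa[i] == alt_aa[i]:
                        expected = "synonymous"
                    elif alt_aa[i] == "*":
                        expected = "nonsense"
                    elif ref_aa[i] == "*":
                        expected = "stop_loss"
                    else:
                        expected = "missense"
                    assert ann["consequence"] == expected

    def test_tsv_round_trip(self, toy_gene, tmp_path):
        src = tmp_path / "v.tsv"
        src.write_text(
            "gene_id\tnt_position\tref_base\talt_base\tddg\tclinical_label\n"
            "TOY\t4\tT\tA\t1.25\tpathogenic\n"
        )
        variants = read_variants_tsv(src, [toy_gene]).variants
        out = tmp_path / "out.tsv"
        write_variants_tsv(variants, out)
        back = read_variants_tsv(out).variants
        assert back[0] == variants[0]


# ---------------------------------------------------------------------------
# Structure confidence
# ---------------------------------------------------------------------------

class TestStructureConfidence:
    def test_ca_bfactors(self, tmp_path):
        p = tmp_path / "toy.pdb"
        write_toy_pdb(p, [("ALA", [("N", 5.0), ("CA", 10.0)]),
                          ("GLY", [("CA", 20.0)]),
                          ("SER", [("CA", 30.0)])])
        conf = read_structure_confidence(p)
        assert conf.values.tolist() == [10.0, 20.0, 30.0]
        assert conf.residue_index.tolist() == [1, 2, 3]
        assert conf.source_kind == "experimental"

    def test_plddt_style_override(self, tmp_path):
        p = tmp_path / "af.pdb"
        write_toy_pdb(p, [("ALA", [("CA", 90.0)]), ("GLY", [("CA", 95.0)])])
        conf = read_structure_confidence(p, source_kind="predicted_model")
        assert conf.values.tolist() == [90.0, 95.0]
        assert conf.source_kind == "predicted_model"

    def test_missing_ca_falls_back_to_atom_mean(self, tmp_path):
        p = tmp_path / "gap.pdb"
        write_toy_pdb(p, [("ALA", [("CA", 10.0)]),
                          ("GLY", [("N", 10.0), ("C", 14.0)]),
                          ("SER", [("CA", 30.0)])])
        conf = read_structure_confidence(p)
        assert conf.values.tolist() == [10.0, 12.0, 30.0]

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            StructureConfidence("p", [1, 1], [5.0, 5.0])
        with pytest.raises(ValueError):
            StructureConfidence("p", [1, 2], [5.0, -1.0])
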