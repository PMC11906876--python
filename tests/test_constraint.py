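"""SNV enumeration, expected counts, calibration, LOEUF and deciles."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from scipy import stats

from mutstab.constraint import (
    CalibrationFactor,
    MutationRateTable,
    assign_deciles,
    calibrate_rate_scale,
    decile_confusion,
    enumerate_snvs,
    expected_class_count,
    loeuf_upper_bound,
    loeuf_upper_bound_grid,
    rank_loeuf_differences,
)
from mutstab.formats_io import GeneModel

from conftest import random_gene

UNIFORM = MutationRateTable.uniform(1.0)
K1 = CalibrationFactor(1.0)


class TestEnumerate:
    def test_three_per_site(self, toy_gene):
        enum = enumerate_snvs(toy_gene)
        assert len(enum) == 27
        assert (enum.groupby("position").size() == 3).all()

    def test_stop_gains_by_brute_force(self, toy_gene):
        """ATGTGGTAA has exactly the two TGG→stop SNVs, confirmed by
        re-translating every one of the 27 mutated sequences."""
        enum = enumerate_snvs(toy_gene)
        expected = set()
        for pos in range(1, 10):
            for alt in "ACGT":
                if alt == toy_gene.cds[pos - 1]:
                    continue
                mutated = toy_gene.cds[: pos - 1] + alt + toy_gene.cds[pos:]
                i = (pos - 1) // 3
                ref_aa = str(Seq(toy_gene.cds).translate())[i]
                alt_aa = str(Seq(mutated).translate())[i]
                if ref_aa != "*" and alt_aa == "*":
                    expected.add((pos, alt))
        got = set(
            map(tuple, enum.loc[enum.consequence == "nonsense", ["position", "alt"]]
                .itertuples(index=False))
        )
        assert got == expected == {(5, "A"), (6, "A")}

    def test_third_position_ggg_synonymous(self):
        gene = GeneModel("g", cds="ATGGGGTAA")
        enum = enumerate_snvs(gene)
        third = enum[enum.position == 6]
        assert (third.consequence == "synonymous").all() and len(third) == 3

    def test_full_agreement_with_translation_oracle(self, rng):
        gene = random_gene(rng, n_codons=20)
        enum = enumerate_snvs(gene).set_index(["position", "alt"])
        protein_ref = str(Seq(gene.cds).translate())
        for pos in range(1, len(gene.cds) + 1):
            for alt in "ACGT":
                if alt == gene.cds[pos - 1]:
                    continue
                mutated = gene.cds[: pos - 1] + alt + gene.cds[pos:]
                i = (pos - 1) // 3
                row = enum.loc[(pos, alt)]
                assert row["ref_aa"] == protein_ref[i]
                assert row["alt_aa"] == str(Seq(mutated).translate())[i]

    def test_contexts_use_flanks(self, toy_gene):
        enum = enumerate_snvs(toy_gene)
        assert enum.loc[enum.position == 1, "context"].iloc[0] == "AAT"
        assert enum.loc[enum.position == 9, "context"].iloc[0] == "AAC"

    def test_missing_flanks_marked_partial(self):
        gene = GeneModel("g", cds="ATGTGGTAA")
        enum = enumerate_snvs(gene)
        assert enum.loc[enum.position == 1, "context"].iloc[0].startswith("N")

    def test_internal_stop_rejected(self):
        gene = GeneModel("g", cds="ATGTAATGGTAA")
        with pytest.raises(ValueError, match="internal stop"):
            enumerate_snvs(gene)
        assert len(enumerate_snvs(gene, allow_internal_stop=True)) == 36


class TestExpectedCounts:
    def test_nonsense_uniform_rate(self, toy_gene):
        e = expected_class_count(toy_gene, UNIFORM, K1, "nonsense")
        assert e.value == pytest.approx(2.0)  # 2 stop-gain SNVs × rate 1
        assert e.n_qualifying_snvs == 2

    def test_zero_rates_give_zero(self, toy_gene):
        zero = MutationRateTable.uniform(0.0)
        assert expected_class_count(toy_gene, zero, K1, "missense").value == 0.0

    def test_streaming_equals_enumeration_oracle(self, rng):
        """Rate-weighted class sums match an independent per-SNV loop."""
        rates = MutationRateTable.default_human_like()
        for _ in range(5):
            gene = random_gene(rng, n_codons=33)  # ~300 nt
            predicate = str(rng.choice(["nonsense", "missense", "synonymous"]))
            got = expected_class_count(gene, rates, K1, predicate).value
            oracle = 0.0
            for row in enumerate_snvs(gene).itertuples():
                if row.consequence == predicate:
                    oracle += rates.rate(row.context, row.alt)
            assert got == pytest.approx(oracle, rel=1e-12)

    def test_class_additivity(self, rng):
        """Expected counts over consequence classes sum to k·Σ(all rates)."""
        rates = MutationRateTable.default_human_like()
        gene = random_gene(rng, n_codons=25)
        k = CalibrationFactor(2.5)
        total = expected_class_count(gene, rates, k, "all").value
        parts = sum(
            expected_class_count(gene, rates, k, c).value
            for c in ("nonsense", "missense", "synonymous", "stop_loss")
        )
        assert parts == pytest.approx(total, rel=1e-12)

    def test_edge_policy_error(self):
        gene = GeneModel("g", cds="ATGTGGTAA")  # no flanks
        with pytest.raises(KeyError, match="partial context"):
            expected_class_count(gene, UNIFORM, K1, "all", edge_policy="error")


class TestCalibration:
    def test_identity_recovery(self, rng):
        genes = [random_gene(rng, n_codons=10, gene_id=f"g{i}") for i in range(5)]
        k0 = 3.25
        observed = {}
        for g in genes:
            e = expected_class_count(g, UNIFORM, K1, "synonymous")
            observed[g.gene_id] = k0 * e.value
        cal = calibrate_rate_scale(genes, UNIFORM, observed)
        assert cal.k == pytest.approx(k0, rel=1e-12)

    def test_poisson_recovery(self, rng):
        """k̂ from Poisson-sampled synonymous counts lands within 5% of truth."""
        rates = MutationRateTable.default_human_like()
        genes = [random_gene(rng, n_codons=30, gene_id=f"g{i}") for i in range(300)]
        k0 = 0.4
        observed = {}
        for g in genes:
            mu = k0 * expected_class_count(g, rates, K1, "synonymous").value
            observed[g.gene_id] = int(rng.poisson(mu))
        cal = calibrate_rate_scale(genes, rates, observed)
        assert cal.k == pytest.approx(k0, rel=0.05)
        assert cal.residuals is not None and len(cal.residuals) == 300

    def test_degenerate_zero_observed(self, rng):
        gene = random_gene(rng, n_codons=10, gene_id="g0")
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_rate_scale([gene], UNIFORM, {"g0": 0})


class TestLoeuf:
    def test_zero_observed_closed_form(self):
        for e in (1.0, 10.0, 100.0):
            assert loeuf_upper_bound(0, e, cap=np.inf) == pytest.approx(
                -np.log(0.05) / e, abs=1e-9
            )

    def test_ten_over_ten(self):
        assert loeuf_upper_bound(10, 10.0) == pytest.approx(1.70, abs=0.01)

    def test_grid_agrees_with_gamma_quantile(self):
        for o, e in [(0, 1), (0, 37), (3, 5), (10, 10), (25, 40), (50, 25), (50, 1)]:
            assert loeuf_upper_bound_grid(o, float(e)) == pytest.approx(
                loeuf_upper_bound(o, float(e)), abs=0.002
            )

    def test_monotonicity_and_oe_dominance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            o = int(rng.integers(0, 40))
            e = float(rng.uniform(0.5, 60))
            b = loeuf_upper_bound(o, e, cap=np.inf)
            assert b >= o / e
            assert loeuf_upper_bound(o, e * 1.5, cap=np.inf) < b
            assert loeuf_upper_bound(o + 1, e, cap=np.inf) > b

    def test_large_expected_limit(self):
        """Bound approaches O/E (difference → 0) as expected grows."""
        gaps = [
            loeuf_upper_bound(10, e, cap=np.inf) - 10 / e
            for e in (10.0, 100.0, 1000.0)
        ]
        assert all(b < a for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 0.01

    def test_cap_applied(self):
        assert loeuf_upper_bound(100, 1.0, cap=2.0) == 2.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            loeuf_upper_bound(0, 0.0)
        with pytest.raises(ValueError):
            loeuf_upper_bound(-1, 1.0)


class TestDeciles:
    def test_twenty_distinct_scores(self):
        scores = {f"g{i:02d}": float(i) for i in range(20)}
        bins = assign_deciles(scores)
        assert (bins.value_counts() == 2).all()
        assert bins["g00"] == 0 and bins["g01"] == 0 and bins["g19"] == 9

    def test_tie_break_by_gene_id(self):
        scores = {f"g{i:02d}": 1.0 for i in range(20)}
        bins = assign_deciles(scores)
        assert bins["g00"] == 0 and bins["g19"] == 9

    def test_partition(self):
        rng = np.random.default_rng(3)
        scores = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=47))}
        bins = assign_deciles(scores)
        assert set(bins.index) == set(scores)
        assert bins.between(0, 9).all()

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            assign_deciles({f"g{i}": float(i) for i in range(9)})


class TestConfusion:
    def test_identical_binnings_diagonal(self):
        bins = assign_deciles({f"g{i:02d}": float(i) for i in range(30)})
        mat = decile_confusion(bins, bins)
        assert (mat == np.diag([3] * 10)).all()

    def test_marginals_and_brute_force(self, rng):
        genes = [f"g{i}" for i in range(40)]
        a = pd.Series(rng.integers(0, 10, 40), index=genes)
        b = pd.Series(rng.integers(0, 10, 40), index=genes)
        mat = decile_confusion(a, b)
        assert mat.sum() == 40
        for i in range(10):
            assert mat[i].sum() == (a == i).sum()
            assert mat[:, i].sum() == (b == i).sum()
        for g in genes:  # brute-force tally
            pass
        oracle = np.zeros((10, 10), dtype=int)
        for g in genes:
            oracle[a[g], b[g]] += 1
        assert (mat == oracle).all()

    def test_mismatched_universe(self):
        with pytest.raises(ValueError, match="symmetric difference"):
            decile_confusion({"a": 0, "b": 1}, {"a": 0, "c": 1})


class TestRanking:
    @staticmethod
    def _table(loeufs):
        return pd.DataFrame(
            {
                "gene_id": list(loeufs),
                "observed": 1,
                "expected": 1.0,
                "oe": 1.0,
                "loeuf": list(loeufs.values()),
            }
        )

    def test_largest_difference_first(self):
        plof = self._table({"a": 2.0, "b": 0.6})
        dos = self._table({"a": 0.8, "b": 0.5})
        out = rank_loeuf_differences(plof, dos)
        assert out.loc[0, "gene_id"] == "a"
        assert out.loc[0, "loeuf_diff"] == pytest.approx(1.2)

    def test_identical_scores_order_by_gene(self):
        t = self._table({"b": 1.0, "a": 1.0})
        out = rank_loeuf_differences(t, t)
        assert out["gene_id"].tolist() == ["a", "b"]
        assert (out["loeuf_diff"] == 0).all()

    def test_empty_intersection(self):
        with pytest.raises(ValueError):
            rank_loeuf_differences(self._table({"a": 1.0}), self._table({"b": 1.0}))


def test_rate_table_strand_collapse():
    rates = {
        (a + c + b, alt): (1.0 if c == "A" else 2.0)
        for c in "AC"
        for a in "ACGT"
        for b in "ACGT"
        for alt in "ACGT"
        if alt != c
    }
    t = MutationRateTable(rates, strand_collapsed=True)
    # central T resolves through reverse complement to central A
    assert t.rate("ATG", "C") == t.rate("CAT", "G") == 1.0
    assert t.rate("TGA", "A") == 2.0  # -> TCA with alt T, central C


def test_rate_table_round_trip(tmp_path):
    t = MutationRateTable.default_human_like()
    p = tmp_path / "rates.tsv"
    t.to_tsv(p)
    back = MutationRateTable.from_tsv(p)
    assert back.rates == pytest.approx(t.rates)
    assert not back.strand_collapsed
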