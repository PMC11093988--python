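"""TPM, %NWS/%BacNWS, riBAQ and 18S relative-abundance formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pulloop.errors import ParameterError, QuantError
from pulloop.omics_quant import (
    AsvTable,
    ExpressionTable,
    ProteomeTable,
    aggregate_pul_expression,
    bac_nws,
    mag_tpm,
    pct_nws,
    relative_abundance_18s,
    ribaq,
)
from pulloop.pul_caller import PULCall


class TestMagTpm:
    def test_printed_formula(self):
        assert mag_tpm(100, 10_000, 1_000_000) == pytest.approx(0.01, abs=1e-15)

    def test_zero_reads_give_zero(self):
        assert mag_tpm(0, 10_000, 1_000_000) == 0.0

    def test_joint_scaling_invariance(self, rng):
        for _ in range(100):
            reads, length, total = rng.integers(1, 10**7, size=3).astype(float)
            c = float(rng.uniform(0.1, 100))
            assert mag_tpm(reads * c, length, total * c) == pytest.approx(
                mag_tpm(reads, length, total), rel=1e-12
            )

    def test_matches_direct_arithmetic(self, rng):
        for _ in range(1000):
            reads, length, total = rng.integers(1, 10**7, size=3).astype(float)
            assert mag_tpm(reads, length, total) == pytest.approx(
                reads * 1e6 / (length * total), rel=1e-12
            )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            mag_tpm(1, 0, 10)
        with pytest.raises(ParameterError):
            mag_tpm(1, 10, 0)


def _expr_table(counts: dict, lengths: dict, totals: dict) -> ExpressionTable:
    return ExpressionTable(
        counts=pd.DataFrame(counts).T,
        feature_length_bp=pd.Series(lengths, dtype=float),
        sample_total_reads=pd.Series(totals, dtype=float),
    )


def _pul(pul_id, substrate, cazy_tags, all_tags=None):
    tags = all_tags or cazy_tags
    return PULCall(
        pul_id=pul_id, genome_id="G", contig_id="c1",
        member_locus_tags=list(tags), first_gene_index=0,
        last_gene_index=len(tags) - 1, start=1, end=1000,
        suscd_pairs=[], cazyme_inventory=("GH13",),
        member_families={t: frozenset({"GH13"}) for t in cazy_tags},
        substrate=substrate,
    )


class TestAggregate:
    def _fixture(self):
        # lengths/totals chosen so gene TPM is counts/1000
        table = _expr_table(
            {"g1": {"s1": 1000.0}, "g2": {"s1": 2000.0}, "gA": {"s1": 500.0},
             "hyp": {"s1": 99.0}},
            {"g1": 1000, "g2": 1000, "gA": 1000, "hyp": 1000},
            {"s1": 1_000_000},
        )
        pul = _pul("p1", "alpha_glucan", ["g1", "g2"], ["g1", "g2", "hyp"])
        return table, pul

    def test_sum_of_member_cazyme_tpm(self):
        table, pul = self._fixture()
        agg = aggregate_pul_expression(table, [pul], ["gA"])
        assert agg.table.loc["alpha_glucan", "s1"] == pytest.approx(3.0)
        assert agg.table.loc["glgA", "s1"] == pytest.approx(0.5)
        # hypothetical member carries no CAZy family -> excluded
        assert agg.missing_features == []

    def test_absent_class_aggregates_to_zero(self):
        table, pul = self._fixture()
        agg = aggregate_pul_expression(table, [pul], [])
        assert agg.table.loc["beta_glucan", "s1"] == 0.0
        assert agg.table.loc["glgA", "s1"] == 0.0

    def test_missing_member_listed_and_excluded(self):
        table, _ = self._fixture()
        pul = _pul("p1", "alpha_glucan", ["g1", "ghost"])
        agg = aggregate_pul_expression(table, [pul], ["gA"])
        assert agg.missing_features == ["ghost"]
        assert agg.table.loc["alpha_glucan", "s1"] == pytest.approx(1.0)

    def test_invariant_to_member_order(self):
        table, _ = self._fixture()
        a = aggregate_pul_expression(
            table, [_pul("p", "alpha_glucan", ["g1", "g2"])], []
        ).table
        b = aggregate_pul_expression(
            table, [_pul("p", "alpha_glucan", ["g2", "g1"])], []
        ).table
        pd.testing.assert_frame_equal(a, b)

    def test_mean_mode(self):
        table, pul = self._fixture()
        agg = aggregate_pul_expression(table, [pul], [], how="mean")
        assert agg.table.loc["alpha_glucan", "s1"] == pytest.approx(1.5)


def test_uniform_coverage_links_gene_and_mag_tpm(rng):
    """With reads proportional to length (uniform coverage), every member
    gene's TPM equals the MAG TPM; pooling member reads over the MAG length
    recovers MAG TPM x (sum of member lengths / MAG length)."""
    lengths = rng.integers(500, 3000, size=12).astype(float)
    coverage, total = 0.37, 5e6
    reads = coverage * lengths
    mag_length = lengths.sum()
    mt = mag_tpm(reads.sum(), mag_length, total)
    for r, L in zip(reads, lengths):
        assert mag_tpm(r, L, total) == pytest.approx(mt, rel=1e-12)
    member = slice(0, 5)
    pooled = reads[member].sum() * 1e6 / (mag_length * total)
    assert pooled == pytest.approx(
        mt * lengths[member].sum() / mag_length, rel=1e-12
    )


positive_columns = arrays(
    dtype=float,
    shape=st.tuples(st.integers(1, 8), st.integers(1, 4)),
    elements=st.floats(0.0, 1e6, allow_nan=False),
)


class TestPctNws:
    def test_arithmetic_example(self):
        p = ProteomeTable(quant=pd.DataFrame({"s": [2.0, 3.0, 5.0]}))
        assert pct_nws(p)["s"].tolist() == pytest.approx([20.0, 30.0, 50.0])

    def test_single_protein_is_100(self):
        p = ProteomeTable(quant=pd.DataFrame({"s": [7.0]}))
        assert pct_nws(p)["s"].tolist() == [100.0]

    def test_zero_sum_sample_named_in_error(self):
        p = ProteomeTable(quant=pd.DataFrame({"bad": [0.0, 0.0], "ok": [1.0, 1.0]}))
        with pytest.raises(QuantError, match="bad"):
            pct_nws(p)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(positive_columns)
    def test_columns_sum_to_100(self, mat):
        mat = mat + 1e-3  # keep every column sum positive
        out = pct_nws(ProteomeTable(quant=pd.DataFrame(mat)))
        assert np.allclose(out.sum(axis=0), 100.0, atol=1e-9)


class TestBacNws:
    def test_restriction_and_renormalization(self):
        pct = pd.DataFrame({"s": [30.0, 10.0, 60.0]}, index=["b1", "b2", "e1"])
        tax = {"b1": "Bacteria", "b2": "Bacteria", "e1": "Eukaryota"}
        out = bac_nws(pct, tax)
        assert out["s"].tolist() == pytest.approx([75.0, 25.0])

    def test_all_bacterial_column_is_idempotent(self):
        pct = pd.DataFrame({"s": [40.0, 60.0]}, index=["b1", "b2"])
        out = bac_nws(pct, {"b1": "Bacteria", "b2": "Bacteria"})
        assert out["s"].tolist() == pytest.approx([40.0, 60.0])

    def test_no_bacterial_signal_is_error(self):
        pct = pd.DataFrame({"s": [100.0]}, index=["e1"])
        with pytest.raises(QuantError, match="s"):
            bac_nws(pct, {"e1": "Eukaryota"})


class TestRibaq:
    def test_arithmetic_example(self):
        assert ribaq([2, 3, 5]).tolist() == pytest.approx([0.2, 0.3, 0.5])

    def test_single_value(self):
        assert ribaq([7.0]).tolist() == [1.0]

    def test_scale_invariance(self, rng):
        v = rng.uniform(0.1, 10, size=20)
        assert np.allclose(ribaq(v * 13.7), ribaq(v), atol=1e-12)

    def test_zero_sum_is_error(self):
        with pytest.raises(QuantError):
            ribaq([0.0, 0.0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(1e-6, 1e9, allow_nan=False), min_size=1, max_size=50)
    )
    def test_sums_to_one(self, values):
        assert ribaq(values).sum() == pytest.approx(1.0, abs=1e-12)


def _asv_table(counts, taxonomy, fractions=None):
    samples = list(counts.columns)
    fractions = fractions or {
        s: ("gt10um" if s.endswith("a") else "3to10um") for s in samples
    }
    return AsvTable(
        counts=counts,
        taxonomy=taxonomy,
        sample_fraction=fractions,
        sample_timepoint={s: s[:-1] for s in samples},
    )


class TestRelativeAbundance18s:
    def test_filter_combine_normalize(self):
        counts = pd.DataFrame(
            {"t1a": [5.0, 90.0], "t1b": [5.0, 0.0]}, index=["dino", "cope"]
        )
        tax = {
            "dino": ("Eukaryota", "Dinophyceae"),
            "cope": ("Eukaryota", "Metazoa", "Temora"),
        }
        out = relative_abundance_18s(_asv_table(counts, tax))
        assert out.table.loc["dino", "t1"] == pytest.approx(1.0)
        assert "cope" not in out.table.index
        assert out.warnings == []

    def test_no_metazoa_means_normalization_only(self):
        counts = pd.DataFrame({"t1a": [6.0, 2.0], "t1b": [0.0, 0.0]},
                              index=["a1", "a2"])
        tax = {"a1": ("Eukaryota",), "a2": ("Eukaryota",)}
        out = relative_abundance_18s(_asv_table(counts, tax))
        assert out.table["t1"].tolist() == pytest.approx([0.75, 0.25])

    def test_all_metazoa_is_error(self):
        counts = pd.DataFrame({"t1a": [9.0], "t1b": [1.0]}, index=["cope"])
        tax = {"cope": ("Metazoa",)}
        with pytest.raises(QuantError):
            relative_abundance_18s(_asv_table(counts, tax))

    def test_unpaired_fraction_warns_but_proceeds(self):
        counts = pd.DataFrame({"t1a": [4.0]}, index=["a1"])
        table = AsvTable(
            counts=counts,
            taxonomy={"a1": ("Eukaryota",)},
            sample_fraction={"t1a": "gt10um"},
            sample_timepoint={"t1a": "t1"},
        )
        out = relative_abundance_18s(table)
        assert len(out.warnings) == 1 and "t1" in out.warnings[0]
        assert out.table.loc["a1", "t1"] == pytest.approx(1.0)

    def test_exclusion_is_rank_and_case_insensitive(self):
        counts = pd.DataFrame({"t1a": [1.0, 1.0], "t1b": [1.0, 1.0]},
                              index=["a1", "m1"])
        tax = {"a1": ("Eukaryota",), "m1": ("Eukaryota", "METAZOA", "x")}
        out = relative_abundance_18s(_asv_table(counts, tax))
        assert list(out.table.index) == ["a1"]

    def test_columns_sum_to_one(self, rng):
        for _ in range(20):
            counts = pd.DataFrame(
                rng.integers(1, 100, size=(4, 6)).astype(float),
                index=[f"a{i}" for i in range(4)],
                columns=["t0a", "t0b", "t1a", "t1b", "t2a", "t2b"],
            )
            tax = {f"a{i}": ("Eukaryota",) for i in range(4)}
            out = relative_abundance_18s(_asv_table(counts, tax))
            assert np.allclose(out.table.sum(axis=0), 1.0, atol=1e-12)


def test_expression_table_validation():
    with pytest.raises(ParameterError):
        _expr_table({"g": {"s": -1.0}}, {"g": 100}, {"s": 10})
    with pytest.raises(ParameterError):
        _expr_table({"g": {"s": 1.0}}, {"g": 0}, {"s": 10})
    with pytest.raises(ParameterError):
        _expr_table({"g": {"s": 1.0}}, {"g": 100}, {"s": 0})
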