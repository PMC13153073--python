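"""Summary-statistic I/O and effect-allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrmediate import (
    ConfigError,
    DataError,
    EmptyIntersectionError,
    harmonize,
    read_summary_stats,
)
from mrmediate.gwas import _classify_orientation

from conftest import make_dataset, make_variant

HEADER = "variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn"


def write_tsv(path, rows, header=HEADER):
    path.write_text("\n".join([header] + rows) + "\n")


class TestReadSummaryStats:
    def test_well_formed_file_parsed_in_full(self, tmp_path):
        f = tmp_path / "x.tsv"
        write_tsv(f, [
            "rs1\t1\t100\tA\tG\t0.3\t0.10\t0.02\t1e-9\t5000",
            "rs2\t1\t200\tT\tC\t0.4\t-0.05\t0.01\t0.02\t5000",
            "rs3\t2\t300\tG\tA\t0.5\t0.00\t0.03\t0.99\t5000",
        ])
        ds = read_summary_stats(f, trait_id="t")
        assert len(ds) == 3 and ds.n_dropped == 0
        assert ds.get("rs2").beta == -0.05

    def test_invariant_violating_row_dropped_with_count(self, tmp_path):
        f = tmp_path / "x.tsv"
        write_tsv(f, [
            "rs1\t1\t100\tA\tG\t0.3\t0.10\t0.02\t1e-9\t5000",
            "rs2\t1\t200\tT\tC\t0.4\t-0.05\t0.00\t0.02\t5000",  # se = 0
        ])
        ds = read_summary_stats(f)
        assert len(ds) == 1 and ds.n_dropped == 1

    def test_column_permutation_with_map_gives_identical_dataset(self, tmp_path):
        ordered = tmp_path / "a.tsv"
        write_tsv(ordered, ["rs1\t1\t100\tA\tG\t0.3\t0.10\t0.02\t1e-9\t5000"])
        shuffled = tmp_path / "b.tsv"
        shuffled.write_text(
            "p\tB\tSE\tSNP\tCHR\tBP\tA1\tA2\tFRQ\tN\n"
            "1e-9\t0.10\t0.02\trs1\t1\t100\tA\tG\t0.3\t5000\n"
        )
        cmap = {"pval": "p", "beta": "B", "se": "SE", "variant_id": "SNP",
                "chrom": "CHR", "pos": "BP", "effect_allele": "A1",
                "other_allele": "A2", "eaf": "FRQ", "n": "N"}
        a = read_summary_stats(ordered, trait_id="t")
        b = read_summary_stats(shuffled, column_map=cmap, trait_id="t")
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_comma_delimiter_autodetected(self, tmp_path):
        f = tmp_path / "x.csv"
        f.write_text(HEADER.replace("\t", ",") + "\n" +
                     "rs1,1,100,A,G,0.3,0.10,0.02,1e-9,5000\n")
        assert len(read_summary_stats(f)) == 1

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        f = tmp_path / "x.tsv"
        f.write_text("variant_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(ConfigError):
            read_summary_stats(f)

    def test_empty_file_is_data_error(self, tmp_path):
        f = tmp_path / "x.tsv"
        f.write_text("")
        with pytest.raises(DataError):
            read_summary_stats(f)


# hand-built truth table over the allele-pair configurations relative to an
# exposure variant with alleles A/G: expected action on the outcome beta
ALLELE_CONFIGS = [
    ("A", "G", "same"),        # identical orientation
    ("G", "A", "flip"),        # swapped
    ("T", "C", "same"),        # strand complement, same orientation
    ("C", "T", "flip"),        # strand complement, swapped
    ("A", "C", "incompatible"),
    ("A", "T", "incompatible"),
    ("C", "G", "incompatible"),
    ("G", "T", "incompatible"),
    ("C", "A", "incompatible"),
    ("T", "G", "incompatible"),
    ("G", "C", "incompatible"),
    ("T", "A", "incompatible"),
]


class TestHarmonize:
    @pytest.mark.parametrize("o_ea,o_oa,expected", ALLELE_CONFIGS)
    def test_allele_configuration_truth_table(self, o_ea, o_oa, expected):
        assert _classify_orientation("A", "G", o_ea, o_oa) == expected

    @pytest.mark.parametrize("o_ea,o_oa,expected", ALLELE_CONFIGS)
    def test_harmonize_applies_truth_table(self, o_ea, o_oa, expected):
        exp = make_dataset([make_variant(ea="A", oa="G", beta=0.10)], "exp")
        out = make_dataset([make_variant(ea=o_ea, oa=o_oa, beta=0.05)], "out")
        h = harmonize(exp, out)
        if expected == "incompatible":
            assert len(h) == 0
            assert h.dropped.iloc[0]["reason"] == "incompatible_alleles"
        else:
            assert len(h) == 1
            row = h.pairs.iloc[0]
            if expected == "flip":
                assert row["beta_out"] == -0.05 and row["flipped"]
            else:
                assert row["beta_out"] == 0.05 and not row["flipped"]

    def test_swapped_alleles_negate_outcome_beta(self):
        exp = make_dataset([make_variant(ea="A", oa="G", beta=0.10, eaf=0.3)], "exp")
        out = make_dataset([make_variant(ea="G", oa="A", beta=0.05, eaf=0.7)], "out")
        h = harmonize(exp, out)
        row = h.pairs.iloc[0]
        assert row["beta_out"] == -0.05 and row["flipped"]
        assert row["eaf_out"] == pytest.approx(0.3)

    def test_ambiguous_palindrome_dropped(self):
        exp = make_dataset([make_variant(ea="A", oa="T", eaf=0.50)], "exp")
        out = make_dataset([make_variant(ea="A", oa="T", eaf=0.50)], "out")
        h = harmonize(exp, out, palindrome_policy="drop_ambiguous")
        assert len(h) == 0
        assert h.dropped.iloc[0]["reason"] == "palindromic_ambiguous"

    def test_unambiguous_palindrome_aligned_by_frequency(self):
        exp = make_dataset([make_variant(ea="A", oa="T", eaf=0.10, beta=0.1)], "exp")
        # outcome reports the other strand orientation: EAF on the other side of 0.5
        out = make_dataset([make_variant(ea="A", oa="T", eaf=0.90, beta=0.05)], "out")
        h = harmonize(exp, out)
        assert len(h) == 1
        assert h.pairs.iloc[0]["beta_out"] == -0.05

    def test_palindrome_missing_eaf_always_dropped(self):
        exp = make_dataset([make_variant(ea="C", oa="G", eaf=None)], "exp")
        out = make_dataset([make_variant(ea="C", oa="G", eaf=0.2)], "out")
        h = harmonize(exp, out)
        assert len(h) == 0
        assert h.dropped.iloc[0]["reason"] == "palindromic_ambiguous"

    def test_drop_all_policy_excludes_every_palindrome(self):
        exp = make_dataset([make_variant(ea="C", oa="G", eaf=0.1)], "exp")
        out = make_dataset([make_variant(ea="C", oa="G", eaf=0.1)], "out")
        h = harmonize(exp, out, palindrome_policy="drop_all")
        assert len(h) == 0 and h.dropped.iloc[0]["reason"] == "palindromic"

    def test_empty_intersection_raises(self):
        exp = make_dataset([make_variant("rs1")], "exp")
        out = make_dataset([make_variant("rs2")], "out")
        with pytest.raises(EmptyIntersectionError):
            harmonize(exp, out)

    def test_retained_plus_dropped_equals_intersection(self):
        rng = np.random.default_rng(7)
        exp_recs, out_recs = [], []
        for i in range(40):
            ea, oa = ("A", "G") if i % 3 else ("A", "T")
            exp_recs.append(make_variant(f"rs{i}", ea=ea, oa=oa,
                                         eaf=float(rng.uniform(0.05, 0.95))))
            o_ea, o_oa = (oa, ea) if i % 2 else (ea, oa)
            out_recs.append(make_variant(f"rs{i}", ea=o_ea, oa=o_oa,
                                         eaf=float(rng.uniform(0.05, 0.95))))
        # some outcome-only variants not in the intersection
        out_recs.append(make_variant("rs_extra"))
        h = harmonize(make_dataset(exp_recs, "exp"), make_dataset(out_recs, "out"))
        assert len(h) + len(h.dropped) == 40

    def test_harmonization_is_idempotent(self):
        """Re-harmonizing the already-aligned pair set changes nothing."""
        exp_recs = [make_variant(f"rs{i}", ea="A", oa="G", beta=0.1 + 0.01 * i)
                    for i in range(5)]
        out_recs = [make_variant(f"rs{i}", ea="G", oa="A", beta=-0.05, eaf=0.7)
                    for i in range(5)]
        exp, out = make_dataset(exp_recs, "exp"), make_dataset(out_recs, "out")
        h1 = harmonize(exp, out)
        # rebuild the outcome dataset in the orientation harmonize chose
        aligned = [make_variant(f"rs{i}", ea="A", oa="G",
                                beta=float(h1.pairs.iloc[i]["beta_out"]),
                                eaf=float(h1.pairs.iloc[i]["eaf_out"]))
                   for i in range(5)]
        h2 = harmonize(exp, make_dataset(aligned, "out"))
        assert not h2.pairs["flipped"].any()
        np.testing.assert_allclose(h1.beta_out, h2.beta_out)

    @given(beta_out=st.floats(-1, 1, allow_nan=False), flip_exposure=st.booleans())
    @settings(max_examples=30, deadline=None)
    def test_double_flip_preserves_effect_products(self, beta_out, flip_exposure):
        """Negating the exposure's alleles and beta leaves beta_exp*beta_out
        (the causally relevant product) unchanged after harmonization."""
        beta_exp = 0.1
        if flip_exposure:
            exp = make_dataset([make_variant(ea="G", oa="A", beta=-beta_exp)], "exp")
        else:
            exp = make_dataset([make_variant(ea="A", oa="G", beta=beta_exp)], "exp")
        out = make_dataset([make_variant(ea="A", oa="G", beta=beta_out)], "out")
        h = harmonize(exp, out)
        product = h.pairs.iloc[0]["beta_exp"] * h.pairs.iloc[0]["beta_out"]
        assert product == pytest.approx(beta_exp * beta_out)
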