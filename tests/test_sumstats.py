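"""Summary-statistics loading, validation, harmonization and N_eff."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleioscan.errors import ConfigurationError, InputError
from pleioscan.sumstats import (
    StudyMeta,
    annotate_neff,
    harmonize_pair,
    is_strand_ambiguous,
    neff_from_counts,
    neff_per_variant,
    read_sumstats,
    write_sumstats,
)

from conftest import make_sumstats_df, make_table, write_tsv


class TestReadSumstats:
    def test_valid_file_loads_identically(self, three_variant_rows, tmp_path):
        path = write_tsv(make_sumstats_df(three_variant_rows), tmp_path / "ss.tsv")
        table = read_sumstats(path)
        assert len(table) == 3
        assert sum(table.load_report.values()) == 0
        assert list(table.df["id"]) == ["rs1", "rs2", "rs3"]

    def test_nonpositive_se_row_dropped_with_reason(self, three_variant_rows, tmp_path):
        rows = three_variant_rows + [
            dict(id="rs4", chrom="chr2", pos=4000, a1="A", a2="C", beta=0.1, se=0.0, p=0.1)
        ]
        table = read_sumstats(write_tsv(make_sumstats_df(rows), tmp_path / "ss.tsv"))
        assert len(table) == 3
        assert table.load_report["nonpositive SE"] == 1

    def test_column_map_aliases_give_identical_table(self, three_variant_rows, tmp_path):
        canonical = read_sumstats(write_tsv(make_sumstats_df(three_variant_rows), tmp_path / "a.tsv"))
        renamed = make_sumstats_df(three_variant_rows).rename(columns={"p": "P-value", "beta": "BETA"})
        aliased = read_sumstats(
            write_tsv(renamed, tmp_path / "b.tsv"),
            column_map={"p": "P-value", "beta": "BETA"},
        )
        pd.testing.assert_frame_equal(canonical.df, aliased.df)

    def test_missing_mandatory_column_is_configuration_error(self, three_variant_rows, tmp_path):
        df = make_sumstats_df(three_variant_rows).drop(columns=["se"])
        with pytest.raises(ConfigurationError):
            read_sumstats(write_tsv(df, tmp_path / "ss.tsv"))

    def test_empty_file_is_input_error(self, three_variant_rows, tmp_path):
        df = make_sumstats_df(three_variant_rows).iloc[:0]
        with pytest.raises(InputError):
            read_sumstats(write_tsv(df, tmp_path / "ss.tsv"))

    @pytest.mark.parametrize(
        "mutation, reason",
        [
            (dict(p=1.5), "p out of range"),
            (dict(p=0.0), "p out of range"),
            (dict(a2="A"), "identical alleles"),
            (dict(maf=0.7), "MAF out of range"),
        ],
    )
    def test_invariant_violations_dropped(self, three_variant_rows, tmp_path, mutation, reason):
        bad = dict(three_variant_rows[0], id="rsbad", **mutation)
        table = read_sumstats(
            write_tsv(make_sumstats_df(three_variant_rows + [bad]), tmp_path / "ss.tsv")
        )
        assert len(table) == 3
        assert table.load_report[reason] == 1

    def test_duplicate_id_keeps_smallest_p(self, three_variant_rows, tmp_path):
        dup = dict(three_variant_rows[0], p=1e-10, beta=0.3)
        table = read_sumstats(
            write_tsv(make_sumstats_df(three_variant_rows + [dup]), tmp_path / "ss.tsv")
        )
        assert table.load_report["duplicate id"] == 1
        assert float(table.df.loc[table.df["id"] == "rs1", "p"].iloc[0]) == 1e-10

    def test_roundtrip_through_writer(self, three_variant_rows, tmp_path):
        table = read_sumstats(write_tsv(make_sumstats_df(three_variant_rows), tmp_path / "a.tsv"))
        write_sumstats(table, tmp_path / "b.tsv")
        again = read_sumstats(tmp_path / "b.tsv")
        pd.testing.assert_frame_equal(table.df, again.df)


class TestStrandAmbiguity:
    @pytest.mark.parametrize(
        "a1, a2, expected",
        [
            ("A", "T", True),
            ("T", "A", True),
            ("C", "G", True),
            ("G", "C", True),
            ("A", "G", False),
            ("T", "C", False),
            ("CT", "C", False),  # indels are non-ambiguous by convention
            ("A", "ATT", False),
        ],
    )
    def test_examples(self, a1, a2, expected):
        assert is_strand_ambiguous(a1, a2) is expected


class TestHarmonizePair:
    def _pair_tables(self):
        a = make_table(
            [
                dict(id="rs1", chrom="1", pos=100, a1="A", a2="G", beta=0.1, se=0.02, p=1e-6),
                dict(id="rs2", chrom="1", pos=200, a1="A", a2="T", beta=0.2, se=0.02, p=1e-5),
                dict(id="rs3", chrom="1", pos=300, a1="A", a2="G", beta=0.1, se=0.02, p=1e-4),
                dict(id="rs4", chrom="1", pos=400, a1="T", a2="C", beta=0.3, se=0.05, p=1e-3),
            ],
            trait="A",
        )
        b = make_table(
            [
                dict(id="rs1", chrom="1", pos=100, a1="G", a2="A", beta=0.2, se=0.03, p=1e-8),
                dict(id="rs2", chrom="1", pos=200, a1="A", a2="T", beta=0.1, se=0.03, p=1e-2),
                dict(id="rs3", chrom="1", pos=300, a1="A", a2="C", beta=0.1, se=0.03, p=1e-2),
                dict(id="rs4", chrom="1", pos=400, a1="T", a2="C", beta=-0.1, se=0.05, p=1e-2),
            ],
            trait="B",
        )
        return a, b

    def test_swapped_alleles_flip_beta_sign(self):
        a, b = self._pair_tables()
        pair = harmonize_pair(a, b)
        row = pair.df.set_index("id").loc["rs1"]
        assert row["a1"] == "A" and row["a2"] == "G"
        assert row["beta_b"] == pytest.approx(-0.2)
        assert bool(row["flipped"])

    def test_ambiguous_and_mismatched_variants_dropped(self):
        a, b = self._pair_tables()
        pair = harmonize_pair(a, b)
        reasons = dict(zip(pair.drops["id"], pair.drops["reason"]))
        assert reasons["rs2"] == "strand-ambiguous"
        assert reasons["rs3"] == "allele mismatch"
        assert set(pair.df["id"]) == {"rs1", "rs4"}

    def test_same_coding_kept_unchanged(self):
        a, b = self._pair_tables()
        row = harmonize_pair(a, b).df.set_index("id").loc["rs4"]
        assert row["beta_b"] == pytest.approx(-0.1)
        assert not bool(row["flipped"])

    def test_build_mismatch_is_configuration_error(self):
        a, b = self._pair_tables()
        b.meta.build = "hg19"
        with pytest.raises(ConfigurationError):
            harmonize_pair(a, b)

    def test_role_symmetry(self):
        a, b = self._pair_tables()
        ab = harmonize_pair(a, b)
        ba = harmonize_pair(b, a)
        assert set(ab.df["id"]) == set(ba.df["id"])
        left = ab.df.set_index("id")
        right = ba.df.set_index("id")
        for vid in left.index:
            # After role exchange the same per-variant estimates appear, up
            # to re-expression on the other table's effect allele.
            sign = 1.0 if left.loc[vid, "a1"] == right.loc[vid, "a1"] else -1.0
            assert left.loc[vid, "beta_a"] == pytest.approx(sign * right.loc[vid, "beta_b"])
            assert left.loc[vid, "beta_b"] == pytest.approx(sign * right.loc[vid, "beta_a"])
            assert left.loc[vid, "se_a"] == pytest.approx(right.loc[vid, "se_b"])

    def test_flip_invariance(self):
        # Re-expressing every record of B on the opposite allele must leave
        # the harmonized result identical.
        a, b = self._pair_tables()
        flipped_df = b.df.copy()
        flipped_df[["a1", "a2"]] = flipped_df[["a2", "a1"]].to_numpy()
        flipped_df["beta"] = -flipped_df["beta"]
        from pleioscan.sumstats import SumStatsTable

        b_flipped = SumStatsTable(df=flipped_df, meta=StudyMeta(trait_name="B"))
        orig = harmonize_pair(a, b)
        flip = harmonize_pair(a, b_flipped)
        pd.testing.assert_frame_equal(
            orig.df.drop(columns="flipped"), flip.df.drop(columns="flipped")
        )

    def test_positional_match_rescues_id_mismatch(self):
        a = make_table(
            [dict(id="rs10", chrom="1", pos=500, a1="A", a2="G", beta=0.1, se=0.02, p=1e-6)],
            trait="A",
        )
        b = make_table(
            [dict(id="1:500", chrom="1", pos=500, a1="G", a2="A", beta=0.2, se=0.03, p=1e-4)],
            trait="B",
        )
        pair = harmonize_pair(a, b)
        assert len(pair) == 1
        assert pair.df["beta_b"].iloc[0] == pytest.approx(-0.2)


class TestEffectiveSampleSize:
    def test_per_variant_examples(self):
        assert neff_per_variant(0.5, 1.0, 0.0, 0.01) == pytest.approx(80_000)
        assert neff_per_variant(0.5, 1.0, 0.1, 0.01) == pytest.approx(79_900)

    def test_missing_info_defaults_to_one(self):
        assert neff_per_variant(0.5, None, 0.0, 0.01) == pytest.approx(80_000)
        assert neff_per_variant(0.5, np.nan, 0.0, 0.01) == pytest.approx(80_000)

    def test_negative_value_clamped_to_missing(self):
        assert np.isnan(neff_per_variant(0.5, 1.0, 10.0, 0.01))

    def test_degenerate_maf_is_domain_error(self):
        with pytest.raises(ValueError):
            neff_per_variant(0.0, 1.0, 0.0, 0.01)
        with pytest.raises(ValueError):
            neff_per_variant(1.0, 1.0, 0.0, 0.01)

    def test_from_counts_printed_study_sizes(self):
        # Exact rational evaluation of 4 / (1/N_cas + 1/N_con) for the
        # case/control census 21,982 / 41,944.
        exact = 4 / (Fraction(1, 21_982) + Fraction(1, 41_944))
        assert float(exact) == pytest.approx(57_693, abs=1)
        assert neff_from_counts(21_982, 41_944) == pytest.approx(float(exact), rel=1e-12)

    @given(n=st.integers(min_value=1, max_value=10**7))
    @settings(derandomize=True, max_examples=50)
    def test_balanced_design_equals_total(self, n):
        assert neff_from_counts(n, n) == pytest.approx(2 * n)

    @given(
        n_cases=st.integers(min_value=1, max_value=10**7),
        n_controls=st.integers(min_value=1, max_value=10**7),
    )
    @settings(derandomize=True, max_examples=100)
    def test_never_exceeds_total(self, n_cases, n_controls):
        assert neff_from_counts(n_cases, n_controls) <= n_cases + n_controls + 1e-9

    def test_zero_counts_are_domain_error(self):
        with pytest.raises(ValueError):
            neff_from_counts(0, 10)

    def test_monotone_decreasing_in_se_and_minimal_at_half(self):
        ses = np.array([0.005, 0.01, 0.02, 0.05])
        vals = neff_per_variant(0.3, 1.0, 0.0, ses)
        assert np.all(np.diff(vals) < 0)
        mafs = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by_maf = neff_per_variant(mafs, 1.0, 0.0, 0.01)
        assert np.argmin(by_maf) == len(mafs) - 1

    def test_annotate_neff_prefers_per_variant_then_counts(self, three_variant_rows):
        rows = [dict(r) for r in three_variant_rows]
        rows[0]["maf"] = 0.5
        table = make_table(rows, trait="t", n_cases=100, n_controls=100)
        annotate_neff(table)
        assert table.df["n_eff"].iloc[0] == pytest.approx(
            neff_per_variant(0.5, None, rows[0]["beta"], rows[0]["se"])
        )
        assert table.df["n_eff"].iloc[1] == pytest.approx(200)


def test_study_meta_rejects_nonpositive_counts():
    with pytest.raises(ValueError):
        StudyMeta(trait_name="x", n_cases=0, n_controls=5)
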