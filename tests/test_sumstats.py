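"""Reading, validation, harmonisation and round-tripping of summary stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosstrait import (harmonize_pair, read_sumstats, write_sumstats,
                        effective_sample_size)

from conftest import make_sumstats


def _write_table(path, rows, header):
    path.write_text("\t".join(header) + "\n" +
                    "\n".join("\t".join(str(x) for x in r) for r in rows) + "\n")


HEADER = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
          "beta", "se", "pvalue", "z", "n", "eaf", "info"]


class TestRead:
    def test_z_filled_from_beta_se(self, tmp_path):
        f = tmp_path / "s.tsv"
        _write_table(f, [["rs1", 1, 100, "A", "G", 0.1, 0.05, "NA", "NA",
                          1000, "NA", "NA"]], HEADER)
        s = read_sumstats(f)
        assert s.df.loc["rs1", "z"] == pytest.approx(2.0)

    def test_p_filled_from_z_two_sided_tail(self, tmp_path):
        # independent tail evaluation: 2 * (1 - Phi(2)) = 0.04550026...
        expected = 2 * (1 - stats.norm.cdf(2.0))
        f = tmp_path / "s.tsv"
        _write_table(f, [["rs1", 1, 100, "A", "G", "NA", "NA", "NA", 2.0,
                          1000, "NA", "NA"]], HEADER)
        s = read_sumstats(f)
        assert s.df.loc["rs1", "pvalue"] == pytest.approx(expected, rel=1e-9)
        assert s.df.loc["rs1", "pvalue"] == pytest.approx(0.0455, abs=5e-5)

    def test_nonpositive_se_dropped_and_tallied(self, tmp_path):
        f = tmp_path / "s.tsv"
        _write_table(f, [
            ["rs1", 1, 100, "A", "G", 0.1, 0.0, "NA", "NA", 1000, "NA", "NA"],
            ["rs2", 1, 200, "A", "G", 0.1, 0.05, "NA", "NA", 1000, "NA", "NA"],
        ], HEADER)
        s = read_sumstats(f)
        assert list(s.df.index) == ["rs2"]
        assert s.qc_tally["nonpositive_se"] == 1

    def test_odds_ratio_converted_to_log_odds(self, tmp_path):
        f = tmp_path / "s.tsv"
        _write_table(f, [["rs1", 1, 100, "A", "G", 1.5, 0.05, "NA", "NA",
                          1000, "NA", "NA"]],
                     ["variant_id", "chrom", "pos", "effect_allele",
                      "other_allele", "OR", "se", "pvalue", "z", "n", "eaf", "info"])
        s = read_sumstats(f, column_map={
            "variant_id": "variant_id", "chrom": "chrom", "pos": "pos",
            "effect_allele": "effect_allele", "other_allele": "other_allele",
            "or": "OR", "se": "se", "n": "n"})
        assert s.df.loc["rs1", "beta"] == pytest.approx(np.log(1.5))

    def test_binary_trait_effective_n_fallback(self, tmp_path):
        f = tmp_path / "s.tsv"
        _write_table(f, [["rs1", 1, 100, "A", "G", 0.1, 0.05, "NA", "NA",
                          "NA", "NA", "NA"]], HEADER)
        s = read_sumstats(f, trait_meta={"trait_type": "binary",
                                         "n_cases": 7410, "n_controls": 11009})
        assert s.df.loc["rs1", "n"] == pytest.approx(
            effective_sample_size(7410, 11009))
        assert s.df.loc["rs1", "n"] == pytest.approx(17715.77, abs=0.01)

    def test_missing_column_raises(self, tmp_path):
        f = tmp_path / "s.tsv"
        _write_table(f, [["rs1", 1]], ["variant_id", "chrom"])
        with pytest.raises(ValueError, match="absent"):
            read_sumstats(f, column_map={"variant_id": "variant_id",
                                         "beta": "nonexistent"})

    def test_zero_valid_rows_raises(self, tmp_path):
        f = tmp_path / "s.tsv"
        _write_table(f, [["rs1", 1, 100, "A", "A", 0.1, 0.05, "NA", "NA",
                          1000, "NA", "NA"]], HEADER)
        with pytest.raises(ValueError, match="no valid rows"):
            read_sumstats(f)

    def test_retained_p_matches_z_tail(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = [[f"rs{i}", 1, 100 * i, "A", "G", b, s, "NA", "NA", 1000, "NA", "NA"]
                for i, (b, s) in enumerate(zip(rng.normal(size=50),
                                               rng.uniform(0.01, 1, 50)))]
        f = tmp_path / "s.tsv"
        _write_table(f, rows, HEADER)
        s = read_sumstats(f)
        implied = 2 * stats.norm.sf(np.abs(s.df["z"]))
        np.testing.assert_allclose(s.df["pvalue"], implied, rtol=1e-6)


class TestHarmonize:
    def test_allele_swap_negates_effect(self, tiny_pair):
        a, b = tiny_pair
        ha, hb = harmonize_pair(a, b)
        assert hb.df.loc["rs1", "effect_allele"] == "A"
        assert hb.df.loc["rs1", "beta"] == pytest.approx(0.10)

    def test_strand_flip_keeps_sign(self, tiny_pair):
        a, b = tiny_pair
        ha, hb = harmonize_pair(a, b)
        # a rs2 is (C,T,-0.2); b rs2 was (G,A,-0.2): complement of (C,T)
        assert hb.df.loc["rs2", "beta"] == pytest.approx(-0.20)
        assert hb.df.loc["rs2", "effect_allele"] == "C"

    def test_flip_plus_swap_negates(self, tiny_pair):
        a, b = tiny_pair
        ha, hb = harmonize_pair(a, b)
        # a rs5 (T,G, 0.0); b rs5 (A,C, 0.3): complement-swapped
        assert hb.df.loc["rs5", "beta"] == pytest.approx(-0.30)

    def test_ambiguous_dropped_by_default(self, tiny_pair):
        a, b = tiny_pair
        ha, hb = harmonize_pair(a, b)
        assert "rs3" not in ha.df.index and "rs4" not in ha.df.index
        ha2, hb2 = harmonize_pair(a, b, drop_ambiguous=False)
        assert "rs3" in ha2.df.index

    def test_idempotent(self, tiny_pair):
        a, b = tiny_pair
        ha, hb = harmonize_pair(a, b)
        ha2, hb2 = harmonize_pair(ha, hb)
        pd.testing.assert_frame_equal(ha.df, ha2.df)
        pd.testing.assert_frame_equal(hb.df, hb2.df)

    def test_orientation_invariance(self, tiny_pair):
        """Flipping all of b's allele labels and signs first changes nothing."""
        a, b = tiny_pair
        flipped = b.df.copy()
        flipped[["effect_allele", "other_allele"]] = \
            flipped[["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] *= -1
        flipped["z"] *= -1
        from crosstrait import SumStats
        b2 = SumStats(b.trait_name, b.trait_type, flipped)
        _, hb = harmonize_pair(a, b)
        _, hb2 = harmonize_pair(a, b2)
        pd.testing.assert_frame_equal(hb.df, hb2.df)

    def test_empty_intersection_raises(self):
        a = make_sumstats([("rs1", "1", 100, "A", "G", 0.1, 0.05)])
        b = make_sumstats([("rs9", "1", 100, "A", "G", 0.1, 0.05)])
        with pytest.raises(ValueError, match="shared"):
            harmonize_pair(a, b)


class TestWriteRoundTrip:
    def test_round_trip_identity(self, tmp_path, tiny_pair):
        a, _ = tiny_pair
        f = tmp_path / "out.tsv"
        write_sumstats(a, f)
        assert len(f.read_text().splitlines()) == len(a) + 1
        back = read_sumstats(f, trait_meta={"trait_name": a.trait_name,
                                            "trait_type": a.trait_type})
        assert list(back.df.index) == list(a.df.index)
        for col in ("effect_allele", "other_allele", "chrom"):
            assert (back.df[col] == a.df[col]).all()
        for col in ("beta", "se", "pvalue", "z", "n"):
            np.testing.assert_allclose(back.df[col], a.df[col],
                                       rtol=0, atol=1e-12)

    def test_empty_write_raises(self, tiny_pair, tmp_path):
        a, _ = tiny_pair
        from crosstrait import SumStats
        empty = SumStats("t", "binary", a.df.iloc[:0])
        with pytest.raises(ValueError):
            write_sumstats(empty, tmp_path / "e.tsv")
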