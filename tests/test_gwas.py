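"""GWAS loading, MAF filtering, BH adjustment, selection, and intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncxtalk import gwas
from ncxtalk.errors import ConfigurationError, DataValidationError, PipelineStateError


def bh_stepup_oracle(pvals):
    """Independent brute-force BH step-up: sort, p(i)*m/i, cumulative min."""
    pvals = np.asarray(pvals, dtype=float)
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    adjusted = np.empty(m)
    current = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        current = min(current, pvals[idx] * m / rank)
        adjusted[idx] = current
    return adjusted


def _write_tsv(path, df):
    df.to_csv(path, sep="\t", index=False)
    return path


class TestLoadGwasTable:
    def test_well_formed_rows_loaded(self, tmp_path):
        df = pd.DataFrame(
            {
                "variant": ["1:100:A:G", "1:200:C:T", "2:300:G:A"],
                "minor_AF": [0.1, 0.2, 0.3],
                "beta": [0.01, -0.02, 0.0],
                "se": [0.005, 0.004, 0.003],
                "pval": [0.5, 0.01, 0.9],
            }
        )
        out = gwas.load_gwas_table(_write_tsv(tmp_path / "a.tsv", df))
        assert len(out) == 3
        assert list(out["chrom"]) == ["1", "1", "2"]
        assert list(out["pos"]) == [100, 200, 300]

    def test_unparseable_pval_dropped_and_counted(self, tmp_path):
        df = pd.DataFrame(
            {
                "variant": ["1:1:A:G", "1:2:A:G"],
                "minor_AF": [0.1, 0.1],
                "beta": [0.0, 0.0],
                "se": [0.01, 0.01],
                "pval": ["NA", 0.3],
            }
        )
        out = gwas.load_gwas_table(_write_tsv(tmp_path / "a.tsv", df))
        assert len(out) == 1
        assert out.attrs["n_dropped"] == 1

    def test_column_map_round_trip(self, tmp_path, rng):
        n = 40
        df = pd.DataFrame(
            {
                "SNP": [f"rs{i}" for i in range(n)],
                "freq": rng.uniform(0.001, 0.5, n).round(6),
                "effect": rng.normal(size=n).round(6),
                "stderr": rng.uniform(0.001, 0.1, n).round(6),
                "p": rng.uniform(1e-10, 1, n),
            }
        )
        out = gwas.load_gwas_table(
            _write_tsv(tmp_path / "m.tsv", df),
            column_map={
                "variant": "SNP",
                "maf": "freq",
                "beta": "effect",
                "se": "stderr",
                "pval": "p",
            },
        )
        assert list(out["variant_id"]) == list(df["SNP"])
        np.testing.assert_allclose(out["maf"], df["freq"])
        np.testing.assert_allclose(out["pval"], df["p"])

    def test_missing_mandatory_column_raises(self, tmp_path):
        df = pd.DataFrame({"variant": ["rs1"], "pval": [0.5]})
        with pytest.raises(ConfigurationError, match="minor_AF"):
            gwas.load_gwas_table(_write_tsv(tmp_path / "bad.tsv", df))

    def test_duplicate_ids_keep_smallest_pvalue(self, tmp_path):
        df = pd.DataFrame(
            {
                "variant": ["rs1", "rs1"],
                "minor_AF": [0.1, 0.1],
                "beta": [0.0, 0.0],
                "se": [0.01, 0.01],
                "pval": [0.8, 0.2],
            }
        )
        out = gwas.load_gwas_table(_write_tsv(tmp_path / "d.tsv", df))
        assert len(out) == 1
        assert out["pval"].iloc[0] == 0.2


class TestMafFilter:
    def test_boundary_kept_below_removed(self):
        df = pd.DataFrame({"maf": [0.0005, 0.001, 0.3], "variant_id": list("abc")})
        kept = gwas.filter_low_confidence(df)
        assert list(kept["variant_id"]) == ["b", "c"]

    def test_identity_when_all_pass(self):
        df = pd.DataFrame({"maf": [0.01, 0.2], "variant_id": list("ab")})
        assert gwas.filter_low_confidence(df).equals(df)

    def test_planted_low_maf_count(self, rng):
        maf = rng.uniform(0.01, 0.5, 1000)
        low = rng.choice(1000, size=100, replace=False)
        maf[low] = rng.uniform(0, 0.0009, 100)
        df = pd.DataFrame({"maf": maf, "variant_id": [str(i) for i in range(1000)]})
        assert len(gwas.filter_low_confidence(df)) == 900

    def test_idempotent(self, rng):
        df = pd.DataFrame(
            {"maf": rng.uniform(0, 0.5, 200), "variant_id": [str(i) for i in range(200)]}
        )
        once = gwas.filter_low_confidence(df)
        assert gwas.filter_low_confidence(once).equals(once)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            gwas.filter_low_confidence(pd.DataFrame({"maf": [0.1]}), maf_threshold=-1)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        adjusted = gwas.adjust_pvalues_bh([0.005, 0.009, 0.05, 0.5])
        np.testing.assert_allclose(adjusted, [0.018, 0.018, 0.05 * 4 / 3, 0.5], atol=1e-12)

    def test_all_equal_stay_equal(self):
        adjusted = gwas.adjust_pvalues_bh([0.03] * 7)
        np.testing.assert_allclose(adjusted, [0.03] * 7)

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(gwas.adjust_pvalues_bh([0.42]), [0.42])

    def test_out_of_range_reports_index(self):
        with pytest.raises(DataValidationError, match="index 1"):
            gwas.adjust_pvalues_bh([0.5, 0.0, 0.1])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=400))
    def test_matches_stepup_oracle(self, pvals):
        np.testing.assert_allclose(
            gwas.adjust_pvalues_bh(pvals), bh_stepup_oracle(pvals), atol=1e-12
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=200))
    def test_adjusted_dominates_raw_and_is_monotone(self, pvals):
        adjusted = gwas.adjust_pvalues_bh(pvals)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-15)
        assert np.all(adjusted <= 1.0)
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)


class TestSelection:
    def test_strict_alpha_boundary(self):
        df = pd.DataFrame(
            {"variant_id": list("abc"), "adj_pval": [0.04, 0.05, 0.06]}
        )
        assert gwas.select_significant(df) == {"a"}

    def test_none_significant(self):
        df = pd.DataFrame({"variant_id": ["a"], "adj_pval": [0.9]})
        assert gwas.select_significant(df) == set()

    def test_requires_adjustment_first(self):
        with pytest.raises(PipelineStateError):
            gwas.select_significant(pd.DataFrame({"variant_id": ["a"], "pval": [0.01]}))

    def test_planted_signals_contained(self, rng):
        n, n_sig = 5000, 50
        pvals = rng.uniform(size=n)
        pvals[:n_sig] = rng.uniform(0, 1e-9, n_sig)
        df = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n)],
                "maf": np.full(n, 0.2),
                "pval": np.clip(pvals, 1e-300, 1),
            }
        )
        selected = gwas.select_significant(gwas.add_adjusted_pvalues(df))
        assert {f"v{i}" for i in range(n_sig)} <= selected


class TestCombineAndIntersect:
    @staticmethod
    def _file(ids, sig_ids):
        return pd.DataFrame(
            {
                "variant_id": ids,
                "maf": [0.2] * len(ids),
                "pval": [1e-12 if v in sig_ids else 0.9 for v in ids],
            }
        )

    def test_union_and_intersection_policies(self):
        f1 = self._file(["a", "b", "c"], {"a", "b"})
        f2 = self._file(["a", "b", "c"], {"b", "c"})
        ds = gwas.TraitDataset("T", [f1, f2], "union")
        assert gwas.combine_trait_files(ds) == {"a", "b", "c"}
        ds.combine_policy = "intersection"
        assert gwas.combine_trait_files(ds) == {"b"}

    def test_single_policy_matches_first_file(self):
        f1 = self._file(["a", "b"], {"a"})
        f2 = self._file(["a", "b"], {"b"})
        ds = gwas.TraitDataset("T", [f1, f2], "single")
        assert gwas.combine_trait_files(ds) == {"a"}

    def test_unknown_policy_rejected(self):
        ds = gwas.TraitDataset("T", [self._file(["a"], set())], "mean")
        with pytest.raises(ConfigurationError):
            gwas.combine_trait_files(ds)

    def test_intersect_sorted_and_symmetric(self):
        assert gwas.intersect_traits({"rs2", "rs1"}, {"rs2", "rs3"}) == ["rs2"]
        assert gwas.intersect_traits({"rs1"}, {"rs9"}) == []
        a, b = {"x", "y", "z"}, {"y", "z", "w"}
        assert gwas.intersect_traits(a, b) == gwas.intersect_traits(b, a)
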