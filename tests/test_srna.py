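import numpy as np
import pandas as pd
import pytest

from ecomethyl.srna import (
    bh_adjust,
    classify_e24src,
    correlate_samples,
    length_5p_profile,
    normalize_counts,
    read_de_table,
    test_differential_expression,
    zscore_standardize,
)


def nb_counts(rng, mu, disp, size):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mu), size=size)


class TestProfile:
    def test_rpm_definition(self):
        df = pd.DataFrame([{"length": 24, "five_prime_nt": "A", "count": 250_000}])
        out = length_5p_profile(df, total_mapped=1_000_000)
        assert out.loc[24, "A"] == pytest.approx(250_000.0)

    def test_absent_class_zero(self):
        df = pd.DataFrame([{"length": 21, "five_prime_nt": "U", "count": 10}])
        out = length_5p_profile(df, total_mapped=100)
        assert out.loc[24, "A"] == 0.0

    def test_hand_normalization_five_classes(self):
        rows = [
            (18, "A", 5), (21, "U", 10), (21, "T", 5), (24, "A", 50), (26, "G", 30),
        ]
        df = pd.DataFrame(rows, columns=["length", "five_prime_nt", "count"])
        out = length_5p_profile(df, total_mapped=1000)
        assert out.loc[18, "A"] == pytest.approx(5000.0)
        assert out.loc[21, "U"] == pytest.approx(15000.0)  # T folded into U
        assert out.loc[24, "A"] == pytest.approx(50000.0)
        assert out.loc[26, "G"] == pytest.approx(30000.0)

    def test_full_library_sums_to_million(self):
        rows = [(l, nt, 7) for l in range(18, 27) for nt in "ACGU"]
        df = pd.DataFrame(rows, columns=["length", "five_prime_nt", "count"])
        out = length_5p_profile(df, total_mapped=int(df["count"].sum()))
        assert out.to_numpy().sum() == pytest.approx(1e6)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            length_5p_profile(pd.DataFrame(columns=["length", "five_prime_nt", "count"]), 0)

    def test_bad_length_errors(self):
        df = pd.DataFrame([{"length": 30, "five_prime_nt": "A", "count": 1}])
        with pytest.raises(ValueError, match="length"):
            length_5p_profile(df, 10)


class TestNormalize:
    def test_single_cluster_whole_library_cp10m(self):
        counts = pd.DataFrame({"s1": [123]}, index=["c1"])
        out = normalize_counts(counts, scale=1e7)
        assert out.loc["c1", "s1"] == pytest.approx(1e7)

    def test_scale_invariance_under_doubling(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, (20, 3)), columns=list("abc"))
        a = normalize_counts(counts)
        b = normalize_counts(counts * 2)
        pd.testing.assert_frame_equal(a, b.astype(a.dtypes))

    def test_hand_computation(self):
        counts = pd.DataFrame({"s1": [10, 90]}, index=["c1", "c2"])
        out = normalize_counts(counts, scale=1e6)
        assert out.loc["c1", "s1"] == pytest.approx(100_000.0)
        assert out.loc["c2", "s1"] == pytest.approx(900_000.0)

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"s1": [0, 0]})
        with pytest.raises(ValueError, match="library"):
            normalize_counts(counts)


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        counts = pd.DataFrame(
            {"a1": [100] * 5, "a2": [100] * 5, "b1": [100] * 5, "b2": [100] * 5},
            index=[f"c{i}" for i in range(5)],
        )
        out = test_differential_expression(counts, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(out["log2fc"], 0.0)
        assert (out["pvalue"] > 0.9).all()

    def test_fourfold_fc_recovered(self):
        # 50 four-fold clusters on a 350-cluster null background, so library
        # sizes stay comparable between groups
        rng = np.random.default_rng(0)
        n_de, n_null = 50, 350
        mu_a = np.concatenate([np.full(n_de, 2000.0), np.full(n_null, 500.0)])
        mu_b = np.full(n_de + n_null, 500.0)
        a = np.column_stack([nb_counts(rng, mu_a, 0.05, len(mu_a)) for _ in range(3)])
        b = np.column_stack([nb_counts(rng, mu_b, 0.05, len(mu_b)) for _ in range(3)])
        counts = pd.DataFrame(
            np.hstack([a, b]), columns=["a1", "a2", "a3", "b1", "b2", "b3"]
        )
        out = test_differential_expression(counts, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        med = float(out["log2fc"].iloc[:n_de].median())
        assert abs(med - 2.0) < 0.3
        assert (out["fdr"].iloc[:n_de] < 0.05).mean() > 0.95

    def test_null_fdr_calibration(self):
        rng = np.random.default_rng(1)
        n = 400
        counts = pd.DataFrame(
            np.column_stack([nb_counts(rng, 300, 0.05, n) for _ in range(6)]),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        out = test_differential_expression(counts, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        # BH at 0.05 on a global null: expected false-discovery count is tiny
        assert (out["fdr"] < 0.05).mean() <= 0.05

    def test_all_zero_cluster_excluded(self):
        counts = pd.DataFrame(
            {"a1": [10, 0], "b1": [12, 0]}, index=["keep", "drop"]
        )
        out = test_differential_expression(counts, ["a1"], ["b1"])
        assert list(out.index) == ["keep"]

    def test_unknown_sample_errors(self):
        counts = pd.DataFrame({"a1": [1]})
        with pytest.raises(ValueError, match="sample"):
            test_differential_expression(counts, ["a1"], ["nope"])

    def test_poisson_fallback_single_replicate(self):
        # equal library sizes so normalization leaves the counts alone
        counts = pd.DataFrame({"a1": [400, 100, 250], "b1": [100, 400, 250]})
        out = test_differential_expression(counts, ["a1"], ["b1"])
        assert out["pvalue"].iloc[0] < 1e-6
        assert out["pvalue"].iloc[1] < 1e-6
        assert out["pvalue"].iloc[2] > 0.5


class TestBH:
    def test_monotone_and_bounded(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert ((q >= p - 1e-12) & (q <= 1.0)).all()

    def test_known_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


class TestClassify:
    def _res(self, lfc, fdr):
        return pd.DataFrame({"log2fc": [lfc], "fdr": [fdr]}, index=["c1"])

    def _stages(self, spec):
        return {s: self._res(l, f) for s, (l, f) in spec.items()}

    def test_consistent_col_up(self):
        res = self._stages({"FH": (np.log2(3), 0.01), "AR": (np.log2(3), 0.01),
                            "GS": (np.log2(3), 0.01)})
        assert classify_e24src(res).loc["c1", "class"] == "e24sRC_Col"

    def test_consistent_cvi_up(self):
        res = self._stages({s: (-2.0, 0.001) for s in ("FH", "AR", "GS")})
        assert classify_e24src(res).loc["c1", "class"] == "e24sRC_Cvi"

    def test_single_stage_significant(self):
        res = self._stages({"FH": (0.1, 0.9), "AR": (2.0, 0.01), "GS": (0.1, 0.9)})
        assert classify_e24src(res).loc["c1", "class"] == "e24sRC_1_2"

    def test_mixed_direction_three_stages(self):
        res = self._stages({"FH": (2.0, 0.01), "AR": (2.0, 0.01), "GS": (-2.0, 0.01)})
        assert classify_e24src(res).loc["c1", "class"] == "e24sRC_1_2"

    def test_never_significant(self):
        res = self._stages({s: (0.1, 0.5) for s in ("FH", "AR", "GS")})
        assert classify_e24src(res).loc["c1", "class"] == "non_e24sRC"

    def test_missing_stage_errors(self):
        res = self._stages({"FH": (1.0, 0.01), "AR": (1.0, 0.01)})
        with pytest.raises(ValueError, match="missing stage"):
            classify_e24src(res)

    def test_classes_partition_and_swap(self, rng):
        n = 300
        ids = [f"c{i}" for i in range(n)]
        res = {
            s: pd.DataFrame(
                {"log2fc": rng.normal(0, 2, n), "fdr": rng.random(n)}, index=ids
            )
            for s in ("FH", "AR", "GS")
        }
        out = classify_e24src(res)
        assert len(out) == n  # partition: every cluster classified once
        flipped = {s: r.assign(log2fc=-r["log2fc"]) for s, r in res.items()}
        rev = classify_e24src(flipped)
        swap = {"e24sRC_Col": "e24sRC_Cvi", "e24sRC_Cvi": "e24sRC_Col"}
        assert list(rev["class"]) == [swap.get(c, c) for c in out["class"]]


class TestCorrelation:
    def test_self_correlation_one(self, rng):
        x = rng.random(30)
        m = pd.DataFrame({"a": x, "b": x})
        assert correlate_samples(m).loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelation(self, rng):
        x = rng.random(30)
        m = pd.DataFrame({"a": x, "b": -x})
        assert correlate_samples(m).loc["a", "b"] == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self, rng):
        m = pd.DataFrame(rng.random((40, 3)), columns=list("abc"))
        out = correlate_samples(m)
        for i in "abc":
            for j in "abc":
                x, y = m[i].to_numpy(), m[j].to_numpy()
                r = np.sum((x - x.mean()) * (y - y.mean())) / (
                    np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
                )
                assert out.loc[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_flagged(self, rng):
        m = pd.DataFrame({"a": rng.random(10), "flat": np.ones(10)})
        out = correlate_samples(m)
        assert np.isnan(out.loc["a", "flat"])
        assert out.loc["flat", "flat"] == 1.0


class TestZscore:
    def test_constant_row_dropped(self, rng):
        m = pd.DataFrame({"s1": [1.0, 5.0], "s2": [1.0, 6.0], "s3": [1.0, 7.0]},
                         index=["flat", "var"])
        out = zscore_standardize(m)
        assert list(out.index) == ["var"]

    def test_hand_example_population_sd(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc"))
        out = zscore_standardize(m)
        np.testing.assert_allclose(
            out.iloc[0].to_numpy(), [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.random((10, 5)))
        once = zscore_standardize(m)
        twice = zscore_standardize(once)
        pd.testing.assert_frame_equal(once, twice)


def test_read_de_table_roundtrip(tmp_path):
    df = pd.DataFrame(
        {"log2fc": [1.0], "pvalue": [0.01], "fdr": [0.02]}, index=pd.Index(["c1"], name="id")
    )
    p = tmp_path / "de.tsv"
    df.to_csv(p, sep="\t")
    got = read_de_table(p)
    assert got.loc["c1", "fdr"] == 0.02
    bad = tmp_path / "bad.tsv"
    df.drop(columns=["fdr"]).to_csv(bad, sep="\t")
    with pytest.raises(ValueError, match="missing columns"):
        read_de_table(bad)
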