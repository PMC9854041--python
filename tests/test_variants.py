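import numpy as np
import pandas as pd
import pytest

from ecomethyl.intervals import IntervalSet
from ecomethyl.variants import (
    count_snps_per_window,
    hot_coverage,
    methylation_by_snp_strata,
    snp_window_percentages,
    substitution_zscore,
    sv_methylation_summary,
)


def windows_frame(n, context="CG", label="CR", fracs=None, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * 50,
            "end": (np.arange(n) + 1) * 50,
            "context": context,
            "n_qual_sites": 5,
            "fraction": fracs if fracs is not None else np.full(n, 0.4),
            "valid": True,
            "label": label,
        }
    )


def snps_frame(positions, code="AG", chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "col_base": code[0],
            "cvi_base": code[1],
            "substitution": code,
        }
    )


class TestSnpCounts:
    def test_empty_snp_table_all_zero(self):
        out = count_snps_per_window(snps_frame([]), windows_frame(5))
        assert (out["snp_count"] == 0).all()

    def test_per_position_scan_oracle(self, rng):
        wins = windows_frame(40)
        positions = sorted(int(p) for p in rng.choice(2000, size=120, replace=False) + 1)
        out = count_snps_per_window(snps_frame(positions), wins)
        for row in out.itertuples():
            want = sum(1 for p in positions if row.start < p <= row.end)
            assert row.snp_count == want

    def test_total_conservation(self, rng):
        wins = windows_frame(40)
        positions = [int(p) + 1 for p in rng.choice(3000, size=150, replace=False)]
        out = count_snps_per_window(snps_frame(positions), wins)
        in_any = sum(1 for p in positions if 0 < p <= 2000)
        assert out["snp_count"].sum() == in_any

    def test_percentage_table(self):
        wins = windows_frame(4)
        out = count_snps_per_window(snps_frame([10, 12, 60]), wins)
        pct = snp_window_percentages(out)
        row = pct[pct["context"] == "CG"].iloc[0]
        assert row["total_windows"] == 4
        assert row["windows_with_snp"] == 2
        assert row["pct_with_snp"] == 50.0
        assert row["pct_without_snp"] == 50.0


class TestStrata:
    def test_uniform_stratum(self):
        wins = windows_frame(10, fracs=np.full(10, 0.4))
        wins["snp_count"] = 0
        out = methylation_by_snp_strata(wins)
        assert len(out) == 1
        assert out.iloc[0]["mean"] == pytest.approx(0.4)
        assert out.iloc[0]["sd"] == 0.0

    def test_hand_grouping(self):
        wins = windows_frame(4, fracs=[0.1, 0.2, 0.3, 0.4])
        wins["snp_count"] = [0, 0, 1, 1]
        out = methylation_by_snp_strata(wins)
        s0 = out[out["stratum"] == 0].iloc[0]
        s1 = out[out["stratum"] == 1].iloc[0]
        assert s0["mean"] == pytest.approx(0.15)
        assert s1["mean"] == pytest.approx(0.35)
        assert s0["sd"] == pytest.approx(0.05)

    def test_cap_pools_high_strata(self):
        wins = windows_frame(3, fracs=[0.1, 0.2, 0.3])
        wins["snp_count"] = [6, 9, 20]
        out = methylation_by_snp_strata(wins, max_stratum=6)
        assert list(out["stratum"]) == [6]
        assert out.iloc[0]["n_windows"] == 3

    def test_planted_monotone_coupling_recovered(self, rng):
        # windows with fraction increasing in snp count plus noise
        n = 3000
        snp = rng.integers(0, 5, n)
        frac = np.clip(0.2 + 0.1 * snp + rng.normal(0, 0.02, n), 0, 1)
        wins = windows_frame(n, fracs=frac)
        wins["snp_count"] = snp
        out = methylation_by_snp_strata(wins).sort_values("stratum")
        means = out["mean"].to_numpy()
        assert (np.diff(means) > 0).all()

    def test_flat_when_uncoupled(self, rng):
        n = 5000
        wins = windows_frame(n, fracs=rng.normal(0.4, 0.05, n).clip(0, 1))
        wins["snp_count"] = rng.integers(0, 4, n)
        out = methylation_by_snp_strata(wins)
        spread = out["mean"].max() - out["mean"].min()
        assert spread < 0.01


class TestSubstitutionZ:
    def test_window_at_global_mean_z_zero(self):
        wins = windows_frame(3, fracs=[0.1, 0.2, 0.3])
        snps = snps_frame([60])  # inside window 2 (fraction 0.2 == mean)
        out = substitution_zscore(wins, snps)
        assert out.iloc[0]["mean_z"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_population_sigma(self):
        # fractions {0.1,0.2,0.3}; window at 0.3 -> z = 0.1/0.081650 = 1.2247
        wins = windows_frame(3, fracs=[0.1, 0.2, 0.3])
        snps = snps_frame([120])  # window 3
        out = substitution_zscore(wins, snps)
        assert out.iloc[0]["mean_z"] == pytest.approx(1.224744871, abs=1e-8)

    def test_order_invariance(self, rng):
        wins = windows_frame(30, fracs=rng.random(30))
        snps = snps_frame(sorted(rng.choice(1500, 40, replace=False) + 1))
        a = substitution_zscore(wins, snps)
        b = substitution_zscore(wins.sample(frac=1, random_state=0), snps)
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )

    def test_multicode_window_contributes_to_each(self):
        wins = windows_frame(3, fracs=[0.1, 0.2, 0.3])
        snps = pd.concat(
            [snps_frame([10], "AG"), snps_frame([20], "TC")], ignore_index=True
        )
        out = substitution_zscore(wins, snps)
        assert set(out["substitution"]) == {"AG", "TC"}

    def test_zero_sigma_errors(self):
        wins = windows_frame(3, fracs=[0.4, 0.4, 0.4])
        with pytest.raises(ValueError, match="variance"):
            substitution_zscore(wins, snps_frame([10]))

    def test_zscores_standardized_by_construction(self, rng):
        n = 500
        wins = windows_frame(n, fracs=rng.random(n))
        vals = wins["fraction"].to_numpy()
        z = (vals - vals.mean()) / vals.std(ddof=0)
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-10)


class TestSvSummary:
    def _svs(self):
        return pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 100, "category": "DUP"},
                {"chrom": "chr1", "start": 500, "end": 600, "category": "DEL"},
            ]
        )

    def test_dup_fully_methylated(self):
        wins = windows_frame(2, fracs=[1.0, 1.0])
        wins["sample"] = "Col_FH"
        out = sv_methylation_summary(self._svs(), wins)
        dup = out[out["category"] == "DUP"].iloc[0]
        assert dup["mean"] == 1.0

    def test_category_without_windows_undefined(self):
        wins = windows_frame(2, fracs=[1.0, 1.0])  # windows end at 100
        wins["sample"] = "Col_FH"
        out = sv_methylation_summary(self._svs(), wins)
        deln = out[out["category"] == "DEL"].iloc[0]
        assert deln["n_windows"] == 0 and np.isnan(deln["mean"])

    def test_brute_force_join_oracle(self, rng):
        n = 60
        wins = windows_frame(n, fracs=rng.random(n))
        wins["sample"] = "s"
        svs = pd.DataFrame(
            [
                {"chrom": "chr1", "start": int(s), "end": int(s) + int(l),
                 "category": rng.choice(["DUP", "DEL", "INS"])}
                for s, l in zip(rng.integers(0, 2900, 12), rng.integers(10, 300, 12))
            ]
        )
        out = sv_methylation_summary(svs, wins)
        for row in out.itertuples():
            cat_iv = svs[svs["category"] == row.category]
            vals = []
            for w in wins.itertuples():
                if any(
                    w.start < e and s < w.end
                    for s, e in zip(cat_iv["start"], cat_iv["end"])
                ):
                    vals.append(w.fraction)
            assert row.n_windows == len(vals)
            if vals:
                assert row.mean == pytest.approx(np.mean(vals), abs=1e-12)

    def test_unknown_category_rejected(self):
        svs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10, "category": "WAT"}])
        wins = windows_frame(1)
        wins["sample"] = "s"
        with pytest.raises(ValueError, match="categories"):
            sv_methylation_summary(svs, wins)


class TestHotCoverage:
    def test_identical_sets_fraction_one(self):
        hot = IntervalSet([("chr1", 0, 500), ("chr1", 1000, 1500)])
        out = hot_coverage(hot, {"self": hot})
        assert out.iloc[0]["fraction"] == 1.0

    def test_disjoint_zero(self):
        hot = IntervalSet([("chr1", 0, 500)])
        out = hot_coverage(hot, {"other": IntervalSet([("chr1", 600, 700)])})
        assert out.iloc[0]["covered_bp"] == 0

    def test_bitmap_oracle(self, rng):
        size = 10_000
        hot_iv = [("chr1", int(s), int(s + l)) for s, l in
                  zip(rng.integers(0, size - 600, 8), rng.integers(50, 600, 8))]
        feats = {}
        for name in ("a", "b"):
            feats[name] = IntervalSet(
                [("chr1", int(s), int(s + l)) for s, l in
                 zip(rng.integers(0, size - 600, 8), rng.integers(50, 600, 8))]
            )
        hot = IntervalSet(hot_iv)
        out = hot_coverage(hot, feats).set_index("feature")
        hmap = np.zeros(size, dtype=bool)
        for _, s, e in hot_iv:
            hmap[s:e] = True
        for name, fs in feats.items():
            fmap = np.zeros(size, dtype=bool)
            for _, s, e in fs:
                fmap[s:e] = True
            assert out.loc[name, "covered_bp"] == int((hmap & fmap).sum())
            assert out.loc[name, "hot_bp"] == int(hmap.sum())

    def test_union_coverage_dominates_parts(self, rng):
        hot = IntervalSet([("chr1", 0, 5000)])
        a = IntervalSet([("chr1", 100, 400)])
        b = IntervalSet([("chr1", 300, 900)])
        out = hot_coverage(hot, {"a": a, "b": b, "ab": a.union(b)}).set_index("feature")
        assert out.loc["ab", "covered_bp"] >= out.loc["a", "covered_bp"]
        assert out.loc["ab", "covered_bp"] >= out.loc["b", "covered_bp"]
        assert (out["fraction"].between(0, 1)).all()
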