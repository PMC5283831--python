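"""Gene stratification, nearest-distance search, matched resampling and the
median-ratio statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proxscreen.proximity import (
    ProximityModel,
    classify_genes,
    cumulative_distance_curve,
    nearest_peak_distance,
    proximity_test,
    sample_matched_control,
    subtract_coregulated,
)
from conftest import simulate_prox


def _tss(positions, chrom="chr1", expression=None):
    n = len(positions)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "chrom": chrom if isinstance(chrom, list) else [chrom] * n,
        "tss": positions,
        "strand": ["+"] * n,
        "expression": expression if expression is not None else [10.0] * n,
    })


def _peaks_at(midpoints, chrom="chr1", width=200):
    mids = np.asarray(midpoints)
    return pd.DataFrame({
        "chrom": chrom if isinstance(chrom, list) else [chrom] * len(mids),
        "start": mids - width // 2,
        "end": mids + width - width // 2,
        "summit_offset": width // 2,
    })


class TestClassifyGenes:
    @pytest.mark.parametrize("lfc,padj,group", [
        (-1.5, 0.01, "down"),
        (2.0, 0.001, "up"),
        (-1.0, 0.01, "unchanged"),   # boundary: strict inequality
        (1.0, 0.01, "unchanged"),
        (-3.0, 0.05, "unchanged"),   # padj boundary also strict
        (0.2, 0.5, "unchanged"),
    ])
    def test_threshold_boundaries(self, lfc, padj, group):
        de = pd.DataFrame({"gene_id": ["a", "dn"], "log2fc": [lfc, -5.0],
                           "padj": [padj, 1e-6]})
        groups = classify_genes(de)
        assert "a" in groups[group]

    def test_groups_disjoint_and_exhaustive(self, null_prox_dataset):
        _, de, _, _ = null_prox_dataset
        g = classify_genes(de)
        ids = pd.concat([g.down.to_series(), g.up.to_series(),
                         g.unchanged.to_series()])
        assert not ids.duplicated().any()
        assert set(ids) == set(de["gene_id"])

    def test_planted_groups_recovered_exactly(self, enriched_prox_dataset):
        _, de, _, _ = enriched_prox_dataset
        g = classify_genes(de)
        for name in ("down", "up", "unchanged"):
            truth = set(de.loc[de["group_true"] == name, "gene_id"])
            assert set(g[name]) == truth

    def test_empty_down_group_is_an_error(self):
        de = pd.DataFrame({"gene_id": ["a", "b"], "log2fc": [0.1, 2.0],
                           "padj": [0.5, 0.01]})
        with pytest.raises(ValueError, match="down-regulated"):
            classify_genes(de)


class TestNearestPeakDistance:
    def test_direct_example(self):
        # TSS at 1000; peak midpoints {900, 5000} -> 100
        d = nearest_peak_distance(_tss([1000]), _peaks_at([900, 5000]),
                                  reference_point="midpoint")
        assert d["distance"].iloc[0] == 100

    def test_tss_on_summit_gives_zero(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1100],
                              "summit_offset": [100]})  # summit at 1000
        d = nearest_peak_distance(_tss([1000]), peaks, reference_point="summit")
        assert d["distance"].iloc[0] == 0

    def test_summit_fallback_to_midpoint(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1100],
                              "summit_offset": [np.nan]})
        d = nearest_peak_distance(_tss([1000]), peaks, reference_point="summit")
        assert d["distance"].iloc[0] == 0

    def test_matches_brute_force_oracle(self, random_tss_peaks):
        """Binary-search distances equal an O(n*m) scan on random instances."""
        tss, peaks = random_tss_peaks
        fast = nearest_peak_distance(tss, peaks, reference_point="summit")
        ref = (peaks["start"] + peaks["summit_offset"]).to_numpy()
        for i, row in tss.iterrows():
            same = (peaks["chrom"] == row["chrom"]).to_numpy()
            expected = np.abs(ref[same] - row["tss"]).min()
            assert fast.loc[i, "distance"] == expected

    def test_peak_free_chromosome_flagged_infinite(self):
        tss = _tss([100, 200], chrom=["chr1", "chrM"])
        d = nearest_peak_distance(tss, _peaks_at([150]))
        assert np.isfinite(d["distance"].iloc[0])
        assert np.isinf(d["distance"].iloc[1])
        assert d["peak_index"].iloc[1] == -1

    def test_chromosome_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="chromosome names"):
            nearest_peak_distance(_tss([100], chrom="1"), _peaks_at([150]))

    def test_shared_nearest_peak_kept_by_both(self):
        """Default rule: each TSS keeps its nearest peak even when shared."""
        d = nearest_peak_distance(_tss([990, 1010]), _peaks_at([1000, 900_000]),
                                  reference_point="midpoint")
        assert list(d["peak_index"]) == [0, 0]
        assert list(d["distance"]) == [10, 10]

    def test_one_to_one_mode_steals_greedily(self):
        d = nearest_peak_distance(_tss([995, 1010]), _peaks_at([1000]),
                                  reference_point="midpoint", one_to_one=True)
        assert d["distance"].iloc[0] == 5
        assert np.isinf(d["distance"].iloc[1])


class TestMatchedControl:
    @pytest.fixture
    def pool(self, rng):
        n = 1000
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": "chr1", "tss": rng.integers(0, 10**7, n), "strand": "+",
            "expression": 10.0 ** rng.normal(1.5, 0.75, n),
        })

    def test_size_and_decile_histogram_match(self, pool):
        # expression-biased target: matching has to work for it
        target = pd.Index(pool.nlargest(300, "expression")["gene_id"].iloc[::3])
        draws = sample_matched_control(pool, target, n_resamples=20, seed=1)
        rest = pool[~pool["gene_id"].isin(target)]
        edges = np.quantile(rest["expression"], np.linspace(0, 1, 11))
        tgt_expr = np.clip(pool.set_index("gene_id").loc[target, "expression"],
                           edges[0], edges[-1])
        want, _ = np.histogram(tgt_expr, bins=edges)
        emap = pool.set_index("gene_id")["expression"]
        for ctrl in draws:
            assert len(ctrl) == 100
            assert not ctrl.isin(target).any()
            got, _ = np.histogram(np.clip(emap.loc[ctrl], edges[0], edges[-1]),
                                  bins=edges)
            assert (got == want).all()

    def test_matching_beats_unmatched_draws(self, pool, rng):
        """Matched controls track the target's expression distribution better
        than plain random draws in >= 95% of resamples (KS distance)."""
        target = pd.Index(pool.nlargest(450, "expression")["gene_id"].iloc[::3])
        tgt = pool.set_index("gene_id").loc[target, "expression"]
        emap = pool.set_index("gene_id")["expression"]
        rest_ids = pool.loc[~pool["gene_id"].isin(target), "gene_id"].to_numpy()
        draws = sample_matched_control(pool, target, n_resamples=100, seed=5)
        wins = 0
        for ctrl in draws:
            ks_m = stats.ks_2samp(tgt, emap.loc[ctrl]).statistic
            rand = rng.choice(rest_ids, size=len(target), replace=False)
            ks_u = stats.ks_2samp(tgt, emap.loc[rand]).statistic
            wins += ks_m < ks_u
        assert wins >= 95

    def test_deterministic_given_seed(self, pool):
        target = pd.Index(pool["gene_id"].iloc[:50])
        a = sample_matched_control(pool, target, n_resamples=5, seed=9)
        b = sample_matched_control(pool, target, n_resamples=5, seed=9)
        assert all(x.equals(y) for x, y in zip(a, b))

    def test_insufficient_bin_raises_with_bin_named(self, pool):
        # demand more top-decile genes than the pool holds
        top = pool.nlargest(120, "expression")["gene_id"]
        small_pool = pd.concat([pool[pool["gene_id"].isin(top)],
                                pool[~pool["gene_id"].isin(top)].head(100)])
        with pytest.raises(ValueError, match="bin"):
            sample_matched_control(small_pool, pd.Index(top), n_resamples=2, seed=0)


class TestProximityTest:
    def test_null_target_ratio_near_one(self, null_prox_dataset):
        tss, de, peaks, _ = null_prox_dataset
        res = ProximityModel(tss, peaks, de).fit("down", n_resamples=500, seed=1)
        assert 0.6 < res.median_ratio < 1.6
        assert res.p_empirical > 0.001

    def test_enriched_target_detected(self, enriched_prox_dataset):
        tss, de, peaks, _ = enriched_prox_dataset
        res = ProximityModel(tss, peaks, de).fit("down", n_resamples=500, seed=1)
        assert res.median_ratio == pytest.approx(2.0, rel=0.35)
        assert res.p_empirical < 0.05

    def test_too_few_resamples_refused(self, null_prox_dataset):
        tss, de, peaks, _ = null_prox_dataset
        with pytest.raises(ValueError, match="n_resamples"):
            ProximityModel(tss, peaks, de).fit("down", n_resamples=50)

    def test_pseudocount_keeps_p_positive(self, enriched_prox_dataset):
        tss, de, peaks, _ = enriched_prox_dataset
        res = ProximityModel(tss, peaks, de).fit("down", n_resamples=200, seed=0)
        assert res.p_empirical >= 1.0 / 201

    def test_median_ratio_definition(self, enriched_prox_dataset):
        tss, de, peaks, _ = enriched_prox_dataset
        res = ProximityModel(tss, peaks, de).fit("down", n_resamples=150, seed=3)
        assert res.median_ratio == pytest.approx(
            np.median(res.control_medians) / res.median_distance)

    def test_scale_equivariance(self, enriched_prox_dataset):
        """Multiplying coordinates by k scales distances by k and leaves the
        ratio and p-value unchanged."""
        tss, de, peaks, _ = enriched_prox_dataset
        k = 7
        tss2 = tss.assign(tss=tss["tss"] * k)
        peaks2 = peaks.assign(start=peaks["start"] * k,
                              end=peaks["end"] * k,
                              summit_offset=peaks["summit_offset"] * k)
        a = ProximityModel(tss, peaks, de).fit("down", n_resamples=200, seed=5)
        b = ProximityModel(tss2, peaks2, de).fit("down", n_resamples=200, seed=5)
        assert b.median_distance == pytest.approx(a.median_distance * k)
        assert b.median_ratio == pytest.approx(a.median_ratio, rel=1e-9)
        assert b.p_empirical == a.p_empirical

    def test_result_summary_and_serialisation(self, enriched_prox_dataset):
        tss, de, peaks, _ = enriched_prox_dataset
        res = ProximityModel(tss, peaks, de).fit("down", n_resamples=120, seed=2)
        assert "median ratio" in res.summary()
        d = res.to_dict()
        assert d["n_resamples"] == 120 and len(d["control_medians"]) == 120


class TestSubtractCoregulated:
    def test_gene_near_other_factor_excluded(self):
        tss = _tss([10_000])
        other = _peaks_at([12_000])  # 2 kb away, window 10 kb
        kept, excl = subtract_coregulated(pd.Index(["g0"]), tss, other,
                                          assignment_window=10_000)
        assert list(excl) == ["g0"] and len(kept) == 0

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            subtract_coregulated(pd.Index(["g0"]), _tss([10]), _peaks_at([20]),
                                 assignment_window=0)

    def test_noop_when_factors_share_no_targets(self, enriched_prox_dataset):
        """With the other factor's peaks far from every TSS, subtraction
        changes nothing and the test result is identical."""
        tss, de, peaks, _ = enriched_prox_dataset
        # the other factor's only peak sits far beyond every TSS
        far = _peaks_at([50_000_000])
        base = ProximityModel(tss, peaks, de).fit("down", n_resamples=150, seed=8)
        with_other = ProximityModel(tss, peaks, de, other_peaks=far,
                                    assignment_window=10_000).fit(
            "down", n_resamples=150, seed=8)
        assert len(with_other.excluded_genes) == 0
        assert with_other.median_ratio == pytest.approx(base.median_ratio)
        assert with_other.p_empirical == base.p_empirical


class TestCumulativeCurve:
    def test_small_example(self):
        cdf = cumulative_distance_curve([30, 10, 20])
        assert list(cdf["distance"]) == [10, 20, 30]
        assert list(cdf["cum_fraction"]) == pytest.approx([1/3, 2/3, 1.0])

    def test_monotone_nondecreasing(self, rng):
        cdf = cumulative_distance_curve(rng.exponential(1000, size=500))
        assert (np.diff(cdf["distance"]) >= 0).all()
        assert (np.diff(cdf["cum_fraction"]) >= 0).all()
        assert cdf["cum_fraction"].iloc[-1] == 1.0

    def test_matches_sort_and_rank_oracle(self, rng):
        x = rng.normal(5000, 1000, size=1000)
        cdf = cumulative_distance_curve(x)
        xs = np.sort(x)
        for i in [0, 1, 499, 998, 999]:
            assert cdf["distance"].iloc[i] == xs[i]
            assert cdf["cum_fraction"].iloc[i] == pytest.approx((i + 1) / 1000)

    def test_rejects_empty_or_infinite(self):
        with pytest.raises(ValueError):
            cumulative_distance_curve([])
        with pytest.raises(ValueError):
            cumulative_distance_curve([1.0, np.inf])
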