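"""Midparent contrasts, the mode decision table, and mode summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from heterospot.modes import (
    ALL_MODES,
    MODE_LABELS,
    ModeSummary,
    NONADDITIVE_CODES,
    classify_mode,
    classify_table,
    midparent_profile,
    pairwise_contrast,
    summarize_modes,
)

from conftest import triplicate_table


class TestMidparent:
    def test_constant_vectors(self):
        assert midparent_profile([2, 2, 2], [4, 4, 4]) == pytest.approx([3, 3, 3])

    def test_identical_parents(self):
        p = np.array([1.5, 2.5, 3.5])
        assert midparent_profile(p, p) == pytest.approx(p)

    @given(
        st.lists(st.floats(0.01, 1e6), min_size=2, max_size=6),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_elementwise_mean_oracle(self, p1, data):
        p2 = data.draw(
            st.lists(st.floats(0.01, 1e6), min_size=len(p1), max_size=len(p1))
        )
        mp = midparent_profile(p1, p2)
        for i in range(len(p1)):
            assert mp[i] == pytest.approx((p1[i] + p2[i]) / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            midparent_profile([1, 2], [1, 2, 3])


class TestPairwiseContrast:
    def test_identical_vectors_not_significant(self):
        c = pairwise_contrast([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert c.fold_change == pytest.approx(1.0)
        assert not c.significant

    def test_fold_below_threshold_never_significant(self):
        a = np.array([1.0, 1.001, 0.999])
        b = 1.4 * a
        c = pairwise_contrast(a, b)
        assert c.fold_change < 1.5
        assert c.p_value < 0.05  # strongly separated, yet...
        assert not c.significant  # ...the fold criterion blocks the call

    def test_zero_variance_equal_means_sentinel(self):
        c = pairwise_contrast([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert c.p_value == 1.0 and not c.significant

    def test_zero_variance_unequal_means_sentinel(self):
        c = pairwise_contrast([2.0, 2.0, 2.0], [4.0, 4.0, 4.0])
        assert c.p_value == 0.0 and c.significant

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.lognormal(0, 0.3, 3), rng.lognormal(1, 0.3, 3)
        c = pairwise_contrast(a, b)
        assert c.p_value == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue
        )
        cp = pairwise_contrast(a, b, ttest="pooled")
        assert cp.p_value == pytest.approx(
            stats.ttest_ind(a, b, equal_var=True).pvalue
        )

    def test_welch_small_sample_is_conservative(self):
        # at n=3 Welch's test rejects a true null at below the nominal rate
        rng = np.random.default_rng(12)
        a = np.exp(rng.normal(0, 0.1, size=(4000, 3)))
        b = np.exp(rng.normal(0, 0.1, size=(4000, 3)))
        rate = np.mean(
            [pairwise_contrast(x, y).p_value < 0.05 for x, y in zip(a, b)]
        )
        assert rate <= 0.055

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            pairwise_contrast([1.0], [2.0, 3.0])


def _jitter(mean, sd, rng, n=3):
    return mean + sd * rng.standard_normal(n)


class TestClassifyMode:
    def test_above_high_parent(self):
        # oracle: direct t-tests confirm every contrast is significant
        rng = np.random.default_rng(1)
        p1 = _jitter(1.0, 0.05, rng)
        p2 = _jitter(2.0, 0.05, rng)
        h = _jitter(3.0, 0.05, rng)
        for a, b in ((h, p1), (h, p2), (h, (p1 + p2) / 2)):
            assert stats.ttest_ind(a, b, equal_var=False).pvalue < 0.05
        assert classify_mode(h, p1, p2).mode == "++"

    def test_hybrid_at_midparent_is_additive(self):
        rng = np.random.default_rng(2)
        p1 = _jitter(1.0, 0.03, rng)
        p2 = _jitter(2.0, 0.03, rng)
        h = (p1 + p2) / 2  # exactly the midparent replicates
        res = classify_mode(h, p1, p2)
        assert res.contrasts["H_vs_MP"].fold_change == pytest.approx(1.0)
        assert res.mode == "additive"

    def test_mode_code_labels(self):
        assert MODE_LABELS["++"] == "above high parent expression"
        assert set(MODE_LABELS) == set(ALL_MODES)

    @pytest.mark.parametrize(
        "h_mean,expected",
        [
            (27.0, "++"),   # above both parents
            (1.0 / 3, "--"),  # below both parents
            (9.0, "+"),     # at the high parent
            (1.0, "-"),     # at the low parent
            (3.0, "+/-"),   # between, distinct from both
        ],
    )
    def test_nonadditive_branches(self, h_mean, expected):
        rng = np.random.default_rng(7)
        p1 = _jitter(1.0, 0.02, rng)
        p2 = _jitter(9.0, 0.15, rng)
        h = _jitter(h_mean, h_mean * 0.02, rng)
        assert classify_mode(h, p1, p2).mode == expected

    def test_no_significant_contrast_is_not_differential(self):
        rng = np.random.default_rng(3)
        p1 = _jitter(1.0, 0.02, rng)
        p2 = _jitter(1.0, 0.02, rng)
        h = _jitter(1.0, 0.02, rng)
        assert classify_mode(h, p1, p2).mode == "not_differential"

    def test_parent_swap_leaves_mode_unchanged(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p1 = rng.lognormal(0, 0.1, 3)
            p2 = 3 * rng.lognormal(0, 0.1, 3)
            h = 9 * rng.lognormal(0, 0.1, 3)
            assert classify_mode(h, p1, p2).mode == classify_mode(h, p2, p1).mode

    @given(st.floats(1e-6, 1e6))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(5)
        p1 = rng.lognormal(0, 0.1, 3)
        p2 = 4 * rng.lognormal(0, 0.1, 3)
        h = 10 * rng.lognormal(0, 0.1, 3)
        base = classify_mode(h, p1, p2).mode
        assert classify_mode(scale * h, scale * p1, scale * p2).mode == base

    def test_replicate_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal replicate"):
            classify_mode([1, 2, 3], [1, 2], [1, 2])


class TestClassifyTable:
    def test_matches_per_spot_classification(self, sim_normalized):
        table = classify_table(sim_normalized)
        det = sim_normalized[sim_normalized["detected"]]
        rng_rows = table.sample(n=25, random_state=0)
        for _, row in rng_rows.iterrows():
            sub = det[(det["spot_id"] == row.spot_id) & (det["stage"] == row.stage)]
            groups = {
                g: sub[sub["genotype"] == g].sort_values("replicate")["volume"].to_numpy()
                for g in ("P1", "P2", "H")
            }
            res = classify_mode(groups["H"], groups["P1"], groups["P2"])
            assert res.mode == row["mode"]

    def test_partition_every_spot_one_mode(self, sim_normalized):
        from heterospot.quant import reproducibility_filter

        table = classify_table(sim_normalized)
        assert table["mode"].isin(ALL_MODES).all()
        assert not table.duplicated(subset=["spot_id", "stage"]).any()
        retained = reproducibility_filter(sim_normalized)
        for stage in ("DS", "24HAI"):
            fully = {
                s
                for (s, st_, g) in retained
                if st_ == stage and all((s, stage, gg) in retained for gg in ("P1", "P2", "H"))
            }
            assert set(table[table["stage"] == stage]["spot_id"]) == fully


class TestModeSummary:
    def test_counting_oracle_on_random_modes(self):
        rng = np.random.default_rng(9)
        modes = rng.choice(list(ALL_MODES), size=300)
        results = __import__("pandas").DataFrame(
            {"spot_id": [f"S{i}" for i in range(300)], "stage": "DS", "mode": modes}
        )
        summary = summarize_modes(results, "DS")
        tally = {m: int((modes == m).sum()) for m in ALL_MODES}
        assert summary.additive == tally["additive"]
        for code in NONADDITIVE_CODES:
            assert summary.counts[code] == tally[code]
        assert summary.nonadditive_sum == sum(tally[c] for c in NONADDITIVE_CODES)
        assert summary.differential_total == summary.additive + summary.nonadditive_sum

    def test_empty_results_all_zero(self):
        summary = summarize_modes([], "DS")
        assert summary.differential_total == 0
        assert summary.pct_nonadditive == 0.0
        assert summary.pct_differential == 0.0

    def test_percentages_rederive_from_counts(self):
        s = ModeSummary.from_counts(
            "DS", 1000, 50, above_high=5, high=10, partial=2,
            different=1, low=7, below_low=25,
        )
        assert s.nonadditive_sum == 50
        assert s.differential_total == 100
        assert s.pct_nonadditive == pytest.approx(
            round(100 * s.nonadditive_sum / s.differential_total, 2)
        )
        assert s.pct_differential == pytest.approx(
            round(100 * s.differential_total / s.displayed_spots, 2)
        )
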