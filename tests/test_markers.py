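import numpy as np
import pandas as pd
import pytest

import wheatqg as w
from wheatqg.snp import SnpMatrix


def matrix_from_calls(calls, samples=None):
    calls = np.asarray(calls, dtype=float)
    n_m, n_s = calls.shape
    return SnpMatrix(
        marker_ids=[f"M{i}" for i in range(n_m)],
        chrom=["1A"] * n_m,
        pos=np.arange(1, n_m + 1),
        samples=samples or [f"S{j}" for j in range(n_s)],
        calls=calls,
    )


def brute_force_screen(snp, group_a, group_b, missing_policy="strict"):
    """Exhaustive restatement of the distinct-marker definition."""
    a_idx = [snp.samples.index(s) for s in group_a]
    b_idx = [snp.samples.index(s) for s in group_b]
    hits = []
    for i, marker in enumerate(snp.marker_ids):
        a = [snp.calls[i, j] for j in a_idx]
        b = [snp.calls[i, j] for j in b_idx]
        if missing_policy == "strict" and any(
            np.isnan(v) for v in a + b
        ):
            continue
        a = [v for v in a if not np.isnan(v)]
        b = [v for v in b if not np.isnan(v)]
        if not a or not b:
            continue
        for a_state, b_state in ((0.0, 2.0), (2.0, 0.0)):
            if all(v == a_state for v in a) and all(v == b_state for v in b):
                hits.append((marker, a_state, b_state))
    return hits


class TestFilterMarkers:
    def _panel(self):
        # 4 markers x 10 samples designed around the thresholds
        calls = np.full((4, 10), 0.0)
        calls[0, :3] = np.nan            # 30% missing -> dropped
        calls[1, 0] = 2.0                # maf = 0.10 -> kept
        calls[2, :] = 0.0
        calls[2, 0] = 1.0                # het only; masked -> maf 0 -> dropped
        calls[3, :2] = 2.0               # maf = 0.20 -> kept
        return matrix_from_calls(calls)

    def test_threshold_rules_applied_in_order(self):
        filtered, summary = w.filter_markers(self._panel(), min_maf=0.05)
        assert filtered.marker_ids == ["M1", "M3"]
        assert summary.n_markers_dropped_missing == 1
        assert summary.n_markers_dropped_maf == 1
        assert summary.n_het_calls_masked == 1

    def test_maf_exactly_at_floor_is_retained(self):
        # one alt-hom among 20 samples: maf = 2/40 = 0.05 exactly
        calls = np.zeros((2, 20))
        calls[0, 0] = 2.0
        calls[1, 0] = 1.0  # het masked -> maf 0 -> dropped
        filtered, _ = w.filter_markers(matrix_from_calls(calls), min_maf=0.05)
        assert filtered.marker_ids == ["M0"]

    def test_high_missing_sample_dropped(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0.0, 2.0], size=(20, 5))
        calls[: 8, 0] = np.nan  # sample 0: 40% missing
        filtered, summary = w.filter_markers(
            matrix_from_calls(calls), min_maf=0.0, max_marker_missing=0.5
        )
        assert "S0" not in filtered.samples
        assert summary.n_samples_dropped_missing == 1

    def test_idempotent_on_random_panels(self):
        for seed in range(10):
            panel = w.simulate_snp_panel(
                200,
                [f"S{j}" for j in range(30)],
                het_rate=0.05,
                missing_rate=0.05,
                seed=seed,
            )
            once, _ = w.filter_markers(panel.matrix)
            twice, summary2 = w.filter_markers(once)
            assert twice.marker_ids == once.marker_ids
            assert twice.samples == once.samples
            assert np.array_equal(twice.calls, once.calls, equal_nan=True)

    def test_everything_removed_is_valid_empty_result(self):
        calls = np.zeros((3, 4))  # all monomorphic -> maf 0
        filtered, _ = w.filter_markers(matrix_from_calls(calls))
        assert filtered.n_markers == 0


class TestDistinctSnpScreen:
    def test_planted_perfect_marker_reported_discordant_not(self):
        calls = np.array(
            [
                [2, 2, 2, 0, 0],   # perfect
                [2, 0, 2, 0, 0],   # discordant in A
                [2, 2, 2, 2, 0],   # discordant in B
                [1, 1, 1, 0, 0],   # het states never qualify
            ]
        )
        snp = matrix_from_calls(calls)
        res = w.distinct_snp_screen(snp, ["S0", "S1", "S2"], ["S3", "S4"])
        assert res.records == [("M0", 2.0, 0.0)]
        assert res.n_tested == 4 and res.n_reported == 1

    @pytest.mark.parametrize("policy", ["strict", "ignore_missing"])
    def test_matches_brute_force_on_random_panels(self, policy):
        rng = np.random.default_rng(42)
        samples = [f"S{j:02d}" for j in range(17)]
        a, b = samples[:7], samples[7:]
        for seed in range(25):
            panel = w.simulate_snp_panel(
                100, samples, maf_low=0.05, maf_high=0.5,
                het_rate=0.02, missing_rate=0.05, seed=seed,
            )
            got = w.distinct_snp_screen(panel.matrix, a, b, missing_policy=policy)
            assert got.records == brute_force_screen(panel.matrix, a, b, policy)

    def test_invariant_to_sample_order_and_allele_swap(self):
        samples = [f"S{j:02d}" for j in range(17)]
        a, b = samples[:7], samples[7:]
        panel = w.simulate_snp_panel(
            300, samples, planted_distinct=4, group_a=a, group_b=b, seed=9
        )
        base = w.distinct_snp_screen(panel.matrix, a, b)
        perm = np.random.default_rng(0).permutation(17)
        shuffled = panel.matrix.subset(sample_idx=perm)
        assert w.distinct_snp_screen(shuffled, a, b).records == base.records
        swapped = panel.matrix.subset()
        swapped.calls = 2.0 - swapped.calls
        res_swap = w.distinct_snp_screen(swapped, a, b)
        assert res_swap.marker_ids == base.marker_ids
        assert [(m, bs, as_) for m, as_, bs in base.records] == res_swap.records

    def test_group_swap_exchanges_allele_states(self):
        calls = np.array([[2, 2, 0, 0]])
        snp = matrix_from_calls(calls)
        fwd = w.distinct_snp_screen(snp, ["S0", "S1"], ["S2", "S3"])
        rev = w.distinct_snp_screen(snp, ["S2", "S3"], ["S0", "S1"])
        assert fwd.records == [("M0", 2.0, 0.0)]
        assert rev.records == [("M0", 0.0, 2.0)]

    def test_invalid_groups_rejected(self):
        snp = matrix_from_calls(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="disjoint"):
            w.distinct_snp_screen(snp, ["S0"], ["S0", "S1"])
        with pytest.raises(KeyError, match="S9"):
            w.distinct_snp_screen(snp, ["S0"], ["S9"])


class TestSingleMarkerAssoc:
    def test_constructed_separation_recovered(self):
        rng = np.random.default_rng(1)
        calls = np.array([[0.0] * 30 + [2.0] * 30])
        snp = matrix_from_calls(calls)
        values = pd.Series(
            np.r_[np.full(30, 1.0), np.full(30, 5.0)] + 0.01 * rng.standard_normal(60),
            index=snp.samples,
            name="DI",
        )
        res = w.single_marker_assoc(snp, "M0", values)
        assert res.testable
        assert res.effect == pytest.approx(4.0, abs=0.05)
        assert res.target_state == 2.0
        assert res.p_value < 1e-6

    def test_monomorphic_and_tiny_class_flagged(self):
        snp = matrix_from_calls(np.array([[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 2.0]]))
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=snp.samples)
        mono = w.single_marker_assoc(snp, "M0", values)
        assert not mono.testable and mono.flag == "monomorphic"
        tiny = w.single_marker_assoc(snp, "M1", values)
        assert not tiny.testable and tiny.flag == "class_too_small"
        assert tiny.p_value is None

    def test_null_rejection_rate_is_calibrated(self):
        """Type-I error at alpha = 0.05 on independent null markers."""
        rng = np.random.default_rng(7)
        n_samples, n_markers = 200, 400
        samples = [f"S{j:03d}" for j in range(n_samples)]
        panel = w.simulate_snp_panel(
            n_markers, samples, maf_low=0.2, maf_high=0.5, seed=3
        )
        values = pd.Series(rng.standard_normal(n_samples), index=samples)
        pvals = [
            w.single_marker_assoc(panel.matrix, m, values).p_value
            for m in panel.matrix.marker_ids
        ]
        rate = np.mean(np.asarray(pvals) < 0.05)
        # binomial 99% band around 0.05 at n=400
        assert abs(rate - 0.05) < 2.58 * np.sqrt(0.05 * 0.95 / n_markers)


class TestAlleleEffectStability:
    def test_identical_and_negated_effect_vectors(self):
        e = pd.Series([0.5, 1.2, -0.3, 2.0], index=list("abcd"))
        r, p, n = w.allele_effect_stability(e, e)
        assert r == pytest.approx(1.0)
        assert n == 4
        r_neg, _, _ = w.allele_effect_stability(e, -e)
        assert r_neg == pytest.approx(-1.0)

    def test_matches_pearson_oracle_with_noise(self):
        rng = np.random.default_rng(5)
        e1 = pd.Series(rng.standard_normal(40))
        e2 = e1 + 0.3 * rng.standard_normal(40)
        r, p, n = w.allele_effect_stability(e1, e2)
        assert r == pytest.approx(np.corrcoef(e1, e2)[0, 1], abs=1e-12)

    def test_too_few_shared_markers(self):
        e1 = pd.Series([1.0, 2.0], index=["a", "b"])
        e2 = pd.Series([1.0, 2.0], index=["b", "c"])
        with pytest.raises(ValueError, match="shared"):
            w.allele_effect_stability(e1, e2)


class TestLdR2:
    def test_identical_and_allele_swapped_columns(self):
        calls = np.array([[0, 2, 2, 0, 2]], dtype=float)
        snp = matrix_from_calls(np.vstack([calls, calls, 2.0 - calls]))
        assert w.ld_r2(snp, "M0", "M1") == pytest.approx(1.0)
        assert w.ld_r2(snp, "M0", "M2") == pytest.approx(1.0)

    def test_independent_markers_near_zero(self):
        vals = []
        for seed in range(10):
            panel = w.simulate_snp_panel(
                2, [f"S{j:03d}" for j in range(200)], maf_low=0.3, maf_high=0.5,
                seed=seed,
            )
            vals.append(w.ld_r2(panel.matrix, "M00001", "M00002"))
        assert np.mean(vals) < 0.05

    def test_correlated_pair_generator_produces_high_ld(self):
        snp = w.simulate_ld_pair(500, r=0.9, seed=1)
        assert w.ld_r2(snp, "L1", "L2") > 0.5

    def test_degenerate_inputs_raise(self):
        snp = matrix_from_calls(np.array([[0.0, 0.0, 0.0], [0.0, 2.0, 2.0]]))
        with pytest.raises(ValueError, match="variance"):
            w.ld_r2(snp, "M0", "M1")


class TestTargetAllelesAndThresholds:
    def test_target_allele_counting_with_missing(self):
        calls = np.array([[2.0], [2.0], [0.0], [np.nan], [2.0]])
        snp = matrix_from_calls(calls, samples=["S0"])
        targets = {f"M{i}": 2.0 for i in range(5)}
        assert w.count_target_alleles(snp, "S0", targets) == 3
        assert w.count_target_alleles(snp, "S0", {"M2": 0.0}) == 1
        with pytest.raises(KeyError):
            w.count_target_alleles(snp, "S9", targets)

    def test_significance_thresholds(self):
        thr = w.significance_thresholds(21093)
        assert thr.fixed == 0.001
        assert thr.suggestive == pytest.approx(1.0 / 21093)
        assert w.significance_thresholds(1000).suggestive == pytest.approx(0.001)
        assert w.significance_thresholds(1).suggestive == 1.0
        with pytest.raises(ValueError):
            w.significance_thresholds(0)
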