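"""SD-WEAT: attribute pooling, resampling, the SD score, the negative
control, and z-based significance."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

import sdweat as sw
from sdweat.sdweat import _batch_effect_sizes, _draw_indices


class TestPooling:
    def test_pool_keeps_order_a_then_b(self, tiny_benchmark):
        assert sw.pool_attributes(tiny_benchmark) == [
            "echo", "foxtrot", "golf", "hotel"
        ]

    def test_weat7_pool_contains_gender_terms(self, weat7):
        pool = sw.pool_attributes(weat7)
        assert {"male", "female", "woman", "boy"} <= set(pool)
        assert len(pool) == 16


class TestResampling:
    def test_pairs_are_disjoint_m_term_sets(self):
        pool = [f"w{i}" for i in range(12)]
        pairs = sw.resample_attribute_sets(pool, m=3, K=50, seed=0)
        assert len(pairs) == 50
        for a, b in pairs:
            assert len(a) == len(b) == 3
            assert len(set(a) | set(b)) == 6

    def test_four_term_pool_uses_every_term(self):
        pairs = sw.resample_attribute_sets(["p", "q", "r", "s"], m=2, K=20, seed=1)
        for a, b in pairs:
            assert set(a) | set(b) == {"p", "q", "r", "s"}

    def test_small_pool_error_names_size(self):
        with pytest.raises(ValueError, match="3 terms"):
            sw.resample_attribute_sets(["a", "b", "c"], m=2, K=10, seed=0)

    def test_determinism(self):
        pool = [f"w{i}" for i in range(9)]
        assert sw.resample_attribute_sets(pool, 2, 30, seed=5) == \
            sw.resample_attribute_sets(pool, 2, 30, seed=5)

    def test_draws_uniform_over_enumerated_support(self):
        # pool of 5, m=2: C(5,4)=5 subsets x 3 unordered pairings x 2
        # orientations = 30 equally likely ordered (A', B') outcomes
        pool = list("abcde")
        K = 6000
        pairs = sw.resample_attribute_sets(pool, m=2, K=K, seed=7)
        counts = Counter((frozenset(a), frozenset(b)) for a, b in pairs)
        assert len(counts) == 30
        expected = K / 30
        se = np.sqrt(expected * (1 - 1 / 30))
        for c in counts.values():
            assert abs(c - expected) < 4 * se


class TestSdScore:
    def test_sd_score_matches_declared_convention(self, weat7, synth_store_factory):
        store = synth_store_factory(1.0, seed=4)
        res = sw.SDWeat(weat7, store, K=80).fit(seed=9)
        assert res.K == 80 and len(res.effect_sizes) == 80
        assert res.sd_score == pytest.approx(
            np.std(res.effect_sizes, ddof=1), abs=1e-12
        )
        pop = sw.SDWeat(weat7, store, K=80, score_sd_convention="population").fit(seed=9)
        assert pop.sd_score == pytest.approx(
            np.std(res.effect_sizes, ddof=0), abs=1e-12
        )

    def test_identical_attribute_vectors_give_zero_score(self, weat7):
        rng = np.random.default_rng(0)
        shared = rng.normal(size=20)
        entries = {}
        for t in list(weat7.target_x) + list(weat7.target_y):
            entries[t] = rng.normal(size=20)
        for t in sw.pool_attributes(weat7):
            entries[t] = shared
        store = sw.EmbeddingStore(entries)
        res = sw.SDWeat(weat7, store).fit(seed=0)
        assert res.sd_score == 0.0
        assert all(d == 0.0 for d in res.effect_sizes)

    def test_relabeling_halves_negates_effects_not_score(self, weat7, synth_store_factory):
        store = synth_store_factory(1.0, seed=2)
        model = sw.SDWeat(weat7, store, K=40)
        rng = np.random.default_rng(3)
        idx = _draw_indices(len(model.pool), 4, 40, rng)
        swapped = np.hstack([idx[:, 2:], idx[:, :2]])
        d = _batch_effect_sizes(model._cos, model.n_x, idx, 2, "population")
        d_sw = _batch_effect_sizes(model._cos, model.n_x, swapped, 2, "population")
        np.testing.assert_allclose(d_sw, -d, atol=1e-12)
        assert np.std(d_sw, ddof=1) == pytest.approx(np.std(d, ddof=1), abs=1e-12)

    def test_determinism_of_full_result(self, weat7, synth_store_factory):
        store = synth_store_factory(0.7, seed=6)
        r1 = sw.SDWeat(weat7, store).fit(seed=11)
        r2 = sw.SDWeat(weat7, store).fit(seed=11)
        assert r1 == r2

    def test_score_nonnegative_and_bounded(self, weat7, synth_store_factory):
        for beta in (0.0, 1.0, 5.0):
            store = synth_store_factory(beta, seed=8)
            res = sw.SDWeat(weat7, store).fit(seed=1)
            assert 0.0 <= res.sd_score <= 2.0

    def test_null_store_mean_effect_near_zero(self, weat7, synth_store_factory):
        store = synth_store_factory(0.0, seed=13)
        res = sw.SDWeat(weat7, store, K=200).fit(seed=5)
        se = np.std(res.effect_sizes, ddof=1) / np.sqrt(res.K)
        assert abs(res.mean_effect) <= 3 * se

    def test_unresolvable_pool_beyond_budget_aborts(self, weat7, synth_store_factory):
        store = synth_store_factory(1.0, seed=0)
        pool = sw.pool_attributes(weat7)
        # drop 5 of 16 pool terms (>20%)
        keep = {t: v for t, v in store.items() if t not in pool[:5]}
        with pytest.raises(sw.TermLookupError, match="budget"):
            sw.SDWeat(weat7, sw.EmbeddingStore(keep))

    def test_small_losses_shrink_pool_but_run(self, weat7, synth_store_factory):
        store = synth_store_factory(1.0, seed=0)
        pool = sw.pool_attributes(weat7)
        keep = {t: v for t, v in store.items() if t not in pool[:2]}
        model = sw.SDWeat(weat7, sw.EmbeddingStore(keep))
        assert len(model.pool) == 14
        res = model.fit(seed=0)
        assert res.resolution["pool"].missing == tuple(pool[:2])


class TestNegativeControlAndSignificance:
    def test_group_structure_defaults(self, weat7, synth_store_factory):
        store = synth_store_factory(0.0, seed=1, n_filler=200)
        vocab = sw.sample_vocabulary(store, 150, seed=0)
        cal = sw.negative_control(weat7, store, vocab, n_tests=1000,
                                  group_size=100, seed=3)
        assert cal.n_groups == 10
        assert cal.n_groups * cal.group_size == cal.n_tests
        assert cal.mu == pytest.approx(np.mean(cal.group_sds), abs=1e-12)
        assert cal.sigma == pytest.approx(np.std(cal.group_sds, ddof=1), abs=1e-12)

    def test_divisibility_enforced(self, weat7, synth_store_factory):
        store = synth_store_factory(0.0, seed=1, n_filler=50)
        with pytest.raises(ValueError, match="divisible"):
            sw.negative_control(weat7, store, sw.filler_terms(50),
                                n_tests=1001, group_size=100)

    def test_single_group_rejected(self, weat7, synth_store_factory):
        store = synth_store_factory(0.0, seed=1, n_filler=50)
        with pytest.raises(ValueError, match="at least 2 groups"):
            sw.negative_control(weat7, store, sw.filler_terms(50),
                                n_tests=500, group_size=500)

    def test_mu_estimates_null_effect_spread_invariant_to_noise_scale(self, weat7):
        mus = []
        for noise in (1.0, 2.0):
            cfg = sw.SyntheticConfig(bias_strength=0.0, noise_scale=noise, seed=4)
            store = sw.generate_synthetic_embeddings(cfg, weat7, n_filler=200)
            cal = sw.negative_control(weat7, store, sw.filler_terms(200),
                                      n_tests=3000, group_size=100, seed=9)
            mus.append(cal.mu)
        # cosine statistics are scale-free: doubling the noise scale leaves
        # the null dispersion unchanged up to sampling error
        assert mus[0] == pytest.approx(mus[1], rel=0.1)

    def test_significance_closed_form_points(self):
        cal = sw.NullCalibration(
            group_sds=(0.4, 0.6), mu=0.5, sigma=0.1, n_tests=200,
            group_size=100, m=2, vocab_source="v", target_spec="t",
        )
        z, p = sw.significance(0.5, cal)
        assert (z, p) == (0.0, 0.5)
        z, p = sw.significance(0.6, cal)
        assert z == pytest.approx(1.0)
        assert p == pytest.approx(sps.norm.sf(1.0), abs=1e-12)
        assert p == pytest.approx(0.1587, abs=5e-4)

    def test_zero_sigma_is_an_error(self):
        with pytest.raises(ValueError, match="group SDs have zero spread"):
            sw.NullCalibration(
                group_sds=(0.5, 0.5), mu=0.5, sigma=0.0, n_tests=200,
                group_size=100, m=2, vocab_source="v", target_spec="t",
            )
        with pytest.raises(ValueError, match="sigma"):
            sw.NullCalibration(
                group_sds=(0.4, 0.6), mu=0.5, sigma=-1.0, n_tests=200,
                group_size=100, m=2, vocab_source="v", target_spec="t",
            )


class TestSuite:
    def test_graded_bias_family_yields_positive_correlation(self, bundled):
        stores = {}
        for j, bench in enumerate(bundled):
            cfg = sw.SyntheticConfig(bias_strength=0.2 * j, seed=100 + j)
            stores[bench.id] = sw.generate_synthetic_embeddings(
                cfg, bench, n_filler=120
            )
        suite = sw.run_sdweat_suite(
            bundled, stores, seed=0,
            control_vocab=sw.filler_terms(120),
            n_control_tests=1000, group_size=100,
        )
        assert suite.effect_correlation is not None
        assert suite.effect_correlation > 0.5
        assert suite.p_correlation is not None
        frame = suite.to_frame()
        assert list(frame["benchmark_id"]) == [b.id for b in bundled]
        assert frame["p_right"].notna().all()

    def test_single_benchmark_correlation_absent(self, weat7, synth_store_factory):
        store = synth_store_factory(1.0, seed=0)
        suite = sw.run_sdweat_suite([weat7], store, seed=0)
        assert suite.effect_correlation is None
        assert suite.p_correlation is None

    def test_attribute_sizes_give_consistent_scores(self, bundled):
        stores = {}
        for j, bench in enumerate(bundled):
            cfg = sw.SyntheticConfig(bias_strength=0.2 * j, seed=300 + j)
            stores[bench.id] = sw.generate_synthetic_embeddings(cfg, bench)
        scores = {
            m: [
                sw.SDWeat(b, stores[b.id], m=m).fit(seed=m).sd_score
                for b in bundled
            ]
            for m in (2, 3, 5)
        }
        for m1, m2 in ((2, 3), (2, 5), (3, 5)):
            r = sps.pearsonr(scores[m1], scores[m2]).statistic
            assert r > 0.9

    def test_shared_controls_reuse_calibration_for_identical_targets(self, bundled):
        by_id = {b.id: b for b in bundled}
        pair = [by_id["WEAT-4"], by_id["WEAT-5"]]
        cfg = sw.SyntheticConfig(bias_strength=0.5, seed=9)
        store = sw.generate_synthetic_embeddings(cfg, pair, n_filler=100)
        suite = sw.run_sdweat_suite(
            pair, store, seed=0, control_vocab=sw.filler_terms(100),
            n_control_tests=600, group_size=100, share_controls=True,
        )
        assert suite.calibrations[0] is suite.calibrations[1]
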