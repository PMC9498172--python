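"""GloT / LocT / LocAT permutation tests and their neighbourhood machinery."""

import numpy as np
import pytest

from mixedcmi import (
    MixedSample,
    TestConfig,
    build_neighborhoods,
    draw_local_permutation,
    run_test,
)
from tests.conftest import random_mixed_sample


class TestBuildNeighborhoods:
    def test_qualitative_class_smaller_than_k(self):
        # a class of 3 members with k_perm = 5: adaptive k_i = 3, neighbourhood = class
        z = np.array([0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        sample = MixedSample(z[:, None], [True])
        nb = build_neighborhoods(sample, [0], k_perm=5, adaptive=True)
        assert nb.k[0] == 3 and nb.n_class[0] == 3
        assert sorted(nb.neighborhoods[0]) == [0, 1, 2]
        assert nb.d[0] == 0.0
        assert nb.k[3] == 5
        assert sorted(nb.neighborhoods[3]) == [3, 4, 5, 6, 7]

    def test_fixed_k_escapes_small_class(self):
        # LocT: class of 3 with k_perm = 5 -> k-th distance infinite -> whole sample
        z = np.array([0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        sample = MixedSample(z[:, None], [True])
        nb = build_neighborhoods(sample, [0], k_perm=5, adaptive=False)
        assert len(nb.neighborhoods[0]) == 8
        assert np.isinf(nb.d[0])

    def test_quantitative_matches_brute_force_sort(self, rng):
        pts = rng.normal(size=(30, 2))
        sample = MixedSample(pts, [False, False])
        k = 5
        nb = build_neighborhoods(sample, [0, 1], k_perm=k, adaptive=True)
        for i in range(30):
            dist = np.max(np.abs(pts - pts[i]), axis=1)
            d_k = np.sort(dist)[k - 1]  # the point itself ranks first
            expected = set(np.flatnonzero(dist <= d_k))
            assert set(nb.neighborhoods[i]) == expected
            assert i in expected
            assert len(nb.neighborhoods[i]) >= k

    def test_adaptive_equals_fixed_for_quantitative_z(self, rng):
        pts = rng.normal(size=(25, 1))
        sample = MixedSample(pts, [False])
        a = build_neighborhoods(sample, [0], 5, adaptive=True)
        b = build_neighborhoods(sample, [0], 5, adaptive=False)
        for na, nb_ in zip(a.neighborhoods, b.neighborhoods):
            assert np.array_equal(na, nb_)

    def test_mixed_z_confined_to_class(self, rng):
        quant = rng.normal(size=20)
        qual = np.repeat([0.0, 1.0], 10)
        sample = MixedSample(np.column_stack([quant, qual]), [False, True])
        nb = build_neighborhoods(sample, [0, 1], k_perm=4, adaptive=True)
        for i in range(20):
            assert all(qual[j] == qual[i] for j in nb.neighborhoods[i])

    def test_empty_z_full_neighbourhoods(self, rng):
        sample = MixedSample(rng.normal(size=(7, 1)), [False])
        nb = build_neighborhoods(sample, [], k_perm=5)
        for i in range(7):
            assert len(nb.neighborhoods[i]) == 7


class TestDrawLocalPermutation:
    def test_singleton_neighbourhoods_force_identity(self):
        z = np.arange(6, dtype=float)  # six singleton classes
        sample = MixedSample(z[:, None], [True])
        nb = build_neighborhoods(sample, [0], k_perm=5, adaptive=True)
        rng = np.random.default_rng(0)
        pi = draw_local_permutation(nb, rng)
        assert np.array_equal(pi, np.arange(6))

    def test_draws_stay_in_class(self, rng):
        z = np.repeat([0.0, 1.0, 2.0], 5)
        sample = MixedSample(z[:, None], [True])
        nb = build_neighborhoods(sample, [0], k_perm=5, adaptive=True)
        for _ in range(50):
            pi = draw_local_permutation(nb, rng)
            assert np.all(z[pi] == z)

    def test_uniform_over_neighbourhood(self):
        z = np.zeros(4, dtype=float)
        sample = MixedSample(z[:, None], [True])
        nb = build_neighborhoods(sample, [0], k_perm=5, adaptive=True)
        rng = np.random.default_rng(7)
        draws = np.array([draw_local_permutation(nb, rng)[0] for _ in range(20000)])
        freq = np.bincount(draws, minlength=4) / 20000
        assert np.allclose(freq, 0.25, atol=0.02)


class TestRunTest:
    def test_p_value_definition_and_granularity(self, rng):
        sample = random_mixed_sample(rng, n=40)
        config = TestConfig(B=37, seed=3)
        res = run_test(sample, [0, 2], [1, 3], estimator="cmih", config=config)
        assert res.p_value == np.count_nonzero(res.permuted >= res.statistic) / 37
        assert 0.0 <= res.p_value <= 1.0
        assert (res.p_value * 37) == pytest.approx(round(res.p_value * 37))

    def test_constant_statistic_gives_p_one(self, rng):
        sample = random_mixed_sample(rng, n=20)
        res = run_test(
            sample, [0], [1], estimator=lambda s, x, y, z: 1.0,
            config=TestConfig(B=10, seed=0),
        )
        assert res.p_value == 1.0

    def test_permutations_never_touch_y_or_z(self, rng):
        sample = random_mixed_sample(rng, n=30)
        baseline = {}

        def spy(s, x, y, z):
            key = "obs" if not baseline else "perm"
            if "obs" not in baseline:
                baseline["obs"] = s.data.copy()
            else:
                ref = baseline["obs"]
                assert np.array_equal(s.data[:, [1, 3]], ref[:, [1, 3]])
            return 0.0

        run_test(sample, [0, 2], [1], [3], estimator=spy, config=TestConfig(B=8, seed=1))

    def test_seed_reproducibility(self, rng):
        sample = random_mixed_sample(rng, n=40)
        cfg = TestConfig(B=25, seed=11)
        r1 = run_test(sample, [0, 2], [1, 3], estimator="cmih", config=cfg)
        r2 = run_test(sample, [0, 2], [1, 3], estimator="cmih", config=cfg)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.permuted, r2.permuted)

    def test_locat_equals_glot_for_empty_z(self, rng):
        sample = random_mixed_sample(rng, n=40)
        pa = run_test(
            sample, [0, 2], [1, 3], estimator="cmih", config=TestConfig(B=20, seed=5, scheme="locat")
        )
        pb = run_test(
            sample, [0, 2], [1, 3], estimator="cmih", config=TestConfig(B=20, seed=5, scheme="glot")
        )
        assert np.array_equal(pa.permuted, pb.permuted)

    def test_locat_equals_loct_for_quantitative_z(self, rng):
        n = 40
        data = np.column_stack([rng.normal(size=(n, 3))])
        sample = MixedSample(data, [False] * 3)
        pa = run_test(
            sample, [0], [1], [2], estimator="cmih", config=TestConfig(B=20, seed=9, scheme="locat")
        )
        pb = run_test(
            sample, [0], [1], [2], estimator="cmih", config=TestConfig(B=20, seed=9, scheme="loct")
        )
        assert np.array_equal(pa.permuted, pb.permuted)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TestConfig(B=0)
        with pytest.raises(ValueError):
            TestConfig(scheme="nope")


class TestLevel:
    def test_rejection_rate_near_nominal_under_null(self):
        """CMIh-LocAT level on the conditionally independent mixed setting."""
        from mixedcmi import generate

        reps, alpha = 60, 0.05
        rejections = 0
        for r in range(reps):
            gd = generate("cmi_mixed_indep", 300, seed=40_000 + r)
            res = run_test(
                gd.sample, gd.x, gd.y, gd.z, estimator="cmih",
                config=TestConfig(B=200, seed=r, scheme="locat"),
            )
            rejections += res.p_value < alpha
        # binomial(60, 0.05) has mean 3, sd 1.7; stay within ~3 sd of nominal
        assert rejections / reps <= 0.14
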