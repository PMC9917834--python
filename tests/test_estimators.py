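import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabomr.errors import EstimationError
from metabomr.estimators import (
    _mode_bandwidth,
    _weighted_median_point,
    ivw_random_effects,
    kernel_mode_point,
    mr_egger,
    run_all_estimators,
    simple_mode,
    wald_ratio,
    wald_ratio_second_order,
    weighted_median,
    weighted_mode,
)
from tests.helpers import make_ivs, random_ivs


class TestWald:
    def test_arithmetic(self):
        row = {"beta_exposure": 0.1, "beta_outcome": 0.2,
               "se_exposure": 0.01, "se_outcome": 0.05}
        res = wald_ratio(row)
        assert res.beta == pytest.approx(2.0)
        assert res.se == pytest.approx(0.5)

    def test_zero_outcome(self):
        row = {"beta_exposure": 0.1, "beta_outcome": 0.0,
               "se_exposure": 0.01, "se_outcome": 0.05}
        assert wald_ratio(row).beta == 0.0

    def test_zero_exposure_raises(self):
        row = {"beta_exposure": 0.0, "beta_outcome": 0.1,
               "se_exposure": 0.01, "se_outcome": 0.05}
        with pytest.raises(EstimationError):
            wald_ratio(row)

    def test_second_order_matches_numeric_differentiation(self):
        # delta method vs numeric gradient of f(bx, by) = by/bx
        rng = np.random.default_rng(0)
        for _ in range(20):
            bx = rng.uniform(0.1, 0.5)
            by = rng.uniform(-0.3, 0.3)
            se_x = rng.uniform(0.005, 0.05)
            se_y = rng.uniform(0.005, 0.05)
            row = {"beta_exposure": bx, "beta_outcome": by,
                   "se_exposure": se_x, "se_outcome": se_y}
            res = wald_ratio_second_order(row)
            h = 1e-6
            dfdby = ((by + h) / bx - (by - h) / bx) / (2 * h)
            dfdbx = (by / (bx + h) - by / (bx - h)) / (2 * h)
            se_num = np.sqrt((dfdby * se_y) ** 2 + (dfdbx * se_x) ** 2)
            assert res.se == pytest.approx(se_num, rel=1e-5)


class TestIVW:
    def test_k1_fallback_equals_wald(self):
        ivs = make_ivs([0.2], [0.01], [0.05], [0.02])
        with pytest.warns(UserWarning, match="Wald"):
            res = ivw_random_effects(ivs)
        wald = wald_ratio(ivs.df.iloc[0])
        assert res.beta == wald.beta
        assert res.se == wald.se

    def test_identical_ratios_q_zero(self):
        bx = np.array([0.1, 0.2, 0.3])
        ivs = make_ivs(bx, [0.01] * 3, 0.5 * bx, [0.05] * 3)
        res = ivw_random_effects(ivs)
        assert res.beta == pytest.approx(0.5)
        assert res.extra["q"] == pytest.approx(0.0, abs=1e-20)
        assert res.extra["re_scale"] == 1.0

    def test_or_and_ci_consistent(self):
        ivs = random_ivs(1, k=8)
        res = ivw_random_effects(ivs)
        assert res.or_value == pytest.approx(np.exp(res.beta))
        assert res.ci_low < res.or_value < res.ci_high


class TestEgger:
    def test_exact_proportional_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        ivs = make_ivs(bx, [0.01] * 4, 0.5 * bx, [0.05] * 4)
        res = mr_egger(ivs)
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.extra["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        ivs = make_ivs(bx, [0.01] * 4, 0.5 * bx + 0.1, [0.05] * 4)
        res = mr_egger(ivs)
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.extra["intercept"] == pytest.approx(0.1, abs=1e-12)

    def test_k2_unavailable(self):
        ivs = make_ivs([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.05] * 2)
        with pytest.raises(EstimationError, match="k >= 3"):
            mr_egger(ivs)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        # ratios {1, 2, 9} with equal weights -> 2
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.1, 0.2, 0.9])
        ivs = make_ivs(bx, [0.01] * 3, by, [0.05] * 3)
        res = weighted_median(ivs, n_boot=50, seed=0)
        assert res.beta == pytest.approx(2.0)

    def test_symmetric_dominant_instrument(self):
        # symmetric flanking weights, middle instrument holds half the weight
        r = np.array([1.0, 2.0, 3.0])
        w = np.array([0.25, 0.5, 0.25])
        assert _weighted_median_point(r, w) == pytest.approx(2.0)

    def test_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(3, 12))
            r = rng.standard_normal(k)
            w = rng.uniform(0.1, 2.0, k)
            got = _weighted_median_point(r, w)
            # oracle: explicit cumulative-weight walk with interpolation
            order = np.argsort(r)
            rs, ws = r[order], w[order] / w.sum()
            cum = 0.0
            points = []
            for i in range(k):
                points.append((cum + 0.5 * ws[i], rs[i]))
                cum += ws[i]
            xs = [p[0] for p in points]
            ys = [p[1] for p in points]
            expect = float(np.interp(0.5, xs, ys))
            assert got == pytest.approx(expect, abs=1e-12)


class TestModes:
    def test_majority_cluster(self):
        bx = np.full(4, 0.1)
        by = np.array([0.1, 0.1, 0.1, 0.5])  # ratios {1,1,1,5}
        ivs = make_ivs(bx, [0.01] * 4, by + [0.0005, -0.0005, 0.001, 0.0] * 1,
                       [0.05] * 4)
        res = simple_mode(ivs, n_boot=50, seed=0)
        assert res.beta == pytest.approx(1.0, abs=0.15)

    def test_weighted_mode_follows_heavier_cluster(self):
        # bimodal ratios at 1 and 3; the cluster at 3 carries tiny SEs
        bx = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        by = np.array([0.1, 0.105, 0.095, 0.3, 0.301, 0.299])
        se_y = np.array([0.05, 0.05, 0.05, 0.002, 0.002, 0.002])
        ivs = make_ivs(bx, [0.01] * 6, by, se_y)
        res = weighted_mode(ivs, n_boot=50, seed=0)
        assert res.beta == pytest.approx(3.0, abs=0.2)

    def test_grid_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = int(rng.integers(4, 12))
            r = rng.standard_normal(k)
            w = rng.uniform(0.5, 2.0, k)
            h = _mode_bandwidth(r, 1.0)
            got = kernel_mode_point(r, w, h)
            grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 200_001)
            dens = np.exp(
                -0.5 * ((grid[:, None] - r[None, :]) / h) ** 2
            ) @ (w / w.sum())
            oracle = grid[int(np.argmax(dens))]
            coarse_step = (r.max() - r.min() + 6 * h) / 511
            assert abs(got - oracle) <= coarse_step


class TestCrossEstimatorProperties:
    def test_all_agree_when_ratios_identical(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        ivs = make_ivs(bx, [0.01] * 5, 0.7 * bx, [0.05] * 5)
        results = run_all_estimators(ivs, n_boot=50, seed=0)
        for res in results.values():
            assert res.beta == pytest.approx(0.7, abs=1e-6)

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_orientation_invariance(self, seed):
        ivs = random_ivs(seed, k=8)
        flipped = make_ivs(
            -ivs.df["beta_exposure"].to_numpy(),
            ivs.df["se_exposure"].to_numpy(),
            -ivs.df["beta_outcome"].to_numpy(),
            ivs.df["se_outcome"].to_numpy(),
        )
        a = run_all_estimators(ivs, n_boot=30, seed=1)
        b = run_all_estimators(flipped, n_boot=30, seed=1)
        for m in ("ivw_re", "egger"):
            assert a[m].beta == pytest.approx(b[m].beta, abs=1e-12)
        assert a["weighted_median"].beta == pytest.approx(
            b["weighted_median"].beta, abs=1e-12
        )

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_row_order_invariance(self, seed):
        ivs = random_ivs(seed, k=8)
        rng = np.random.default_rng(seed + 1)
        perm = rng.permutation(8)
        shuffled = make_ivs(
            ivs.df["beta_exposure"].to_numpy()[perm],
            ivs.df["se_exposure"].to_numpy()[perm],
            ivs.df["beta_outcome"].to_numpy()[perm],
            ivs.df["se_outcome"].to_numpy()[perm],
            snp_ids=[ivs.snp_ids[i] for i in perm],
        )
        a = ivw_random_effects(ivs)
        b = ivw_random_effects(shuffled)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        ae, be = mr_egger(ivs), mr_egger(shuffled)
        assert ae.beta == pytest.approx(be.beta, abs=1e-12)
        am = weighted_median(ivs, n_boot=10, seed=3)
        bm = weighted_median(shuffled, n_boot=10, seed=3)
        assert am.beta == pytest.approx(bm.beta, abs=1e-12)
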