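"""The five causal-effect estimators and the OR translation."""
import numpy as np
import pytest

from bodymr.estimators import (Z95, egger, estimate_all, from_frame, ivw,
                               to_odds_ratio, wald_ratio, weighted_median,
                               weighted_mode, _mode_bandwidth,
                               _weighted_median_point)
from bodymr.exceptions import (InputError, InsufficientInstrumentsError,
                               UndefinedRatioError)


class TestWaldRatio:
    def test_closed_form(self):
        e = wald_ratio(0.2, 0.04, 0.01)
        assert e.beta == pytest.approx(0.2)
        assert e.se == pytest.approx(0.05)
        assert e.ci_low == pytest.approx(0.2 - 1.959964 * 0.05)

    def test_zero_outcome_effect_gives_or_one(self):
        e = wald_ratio(0.2, 0.0, 0.01)
        assert e.beta == 0.0 and e.odds_ratio == 1.0

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.04, 0.01)


class TestIVW:
    def test_worked_three_instrument_instance(self, worked_instruments):
        bx, _, by, byse = from_frame(worked_instruments)
        assert ivw(bx, by, byse).beta == pytest.approx(1 / 6, abs=1e-6)

    def test_single_instrument_equals_wald(self):
        w = wald_ratio(0.2, 0.04, 0.01)
        i = ivw([0.2], [0.04], [0.01])
        assert (i.beta, i.se) == (w.beta, w.se)

    def test_homogeneous_ratios_fixed_equals_random(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.4 * bx
        byse = np.array([0.01, 0.02, 0.01])
        fx = ivw(bx, by, byse, model="fixed")
        rn = ivw(bx, by, byse, model="random")
        assert fx.beta == pytest.approx(0.4) and fx.q == pytest.approx(0.0, abs=1e-20)
        assert fx.se == rn.se  # Q = 0 => no inflation

    def test_random_effects_never_narrower_than_fixed(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.05, 0.3, 20)
        by = 0.1 * bx + rng.normal(0, 0.05, 20)
        byse = np.full(20, 0.01)
        assert ivw(bx, by, byse, model="random").se >= ivw(bx, by, byse, model="fixed").se

    def test_empty_set_is_error(self):
        with pytest.raises(InputError):
            ivw([], [], [])


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.03 + 0.5 * bx
        fit = egger(bx, by, np.full(4, 0.01))
        assert fit.beta == pytest.approx(0.5, abs=1e-10)
        assert fit.intercept == pytest.approx(0.03, abs=1e-10)

    def test_balanced_pleiotropy_zero_intercept(self):
        # paired SNPs with equal bx and +/- delta on by: WLS intercept is 0
        bx = np.array([0.1, 0.1, 0.2, 0.2, 0.3, 0.3])
        by = 0.4 * bx + np.array([+0.02, -0.02, +0.02, -0.02, +0.02, -0.02])
        fit = egger(bx, by, np.full(6, 0.01))
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.beta == pytest.approx(0.4, abs=1e-10)

    def test_orientation_makes_fit_sign_invariant(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.3, 10)
        by = 0.01 + 0.3 * bx + rng.normal(0, 0.01, 10)
        byse = np.full(10, 0.01)
        flip = rng.choice([-1, 1], 10)
        a = egger(bx, by, byse)
        b = egger(bx * flip, by * flip, byse)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_two_instruments_is_error(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger([0.1, 0.2], [0.01, 0.02], [0.01, 0.01])


class TestWeightedMedian:
    def test_equal_weights_is_middle_ratio(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.3])
        est = weighted_median(bx, by, np.ones(3), n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_interpolation_with_unequal_weights(self):
        # normalized weights (4/9, 4/9, 1/9) on ratios (0.1, 0.2, 0.3)
        assert _weighted_median_point(
            np.array([0.1, 0.2, 0.3]),
            np.array([4 / 9, 4 / 9, 1 / 9])) == pytest.approx(0.1625)

    def test_identical_ratios_with_tiny_noise(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.25 * bx
        est = weighted_median(bx, by, np.full(3, 1e-8), n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.25)
        assert est.se < 1e-6  # bootstrap collapses as sigma -> 0

    def test_estimate_within_ratio_range(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.3, 15)
        by = 0.1 * bx + rng.normal(0, 0.02, 15)
        byse = np.full(15, 0.02)
        est = weighted_median(bx, by, byse, n_boot=20, seed=0)
        r = by / bx
        assert r.min() <= est.beta <= r.max()

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median([0.1, 0.2], [0.01, 0.02], [0.01, 0.01])


class TestWeightedMode:
    def test_cluster_beats_outliers(self):
        """7 ratios at 0.2 and 2 at 1.0 with equal weights: the mode sits at
        the cluster, cross-checked against a fine-grid density oracle."""
        ratios = np.array([0.2] * 7 + [1.0] * 2)
        bx = np.ones(9)
        est = weighted_mode(bx, ratios, np.ones(9), n_boot=20, seed=0)
        w = np.ones(9) / 9
        h = _mode_bandwidth(ratios, w, 1.0)
        fine = np.linspace(-0.5, 1.5, 20001)
        dens = np.exp(-0.5 * ((fine[:, None] - ratios[None, :]) / h) ** 2) @ w
        oracle = fine[np.argmax(dens)]
        assert est.beta == pytest.approx(oracle, abs=2e-3)
        assert abs(est.beta - 0.2) < h

    def test_identical_ratios_returned_exactly(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 0.3 * bx
        est = weighted_mode(bx, by, np.full(3, 0.01), n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.3, abs=1e-9)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_mode([0.1, 0.2], [0.01, 0.02], [0.01, 0.01])


class TestOddsRatioScale:
    def test_null_beta_with_se(self):
        e = to_odds_ratio(ivw([0.1], [0.0], [0.01]))
        se = e.se
        assert e.odds_ratio == 1.0
        assert e.or_ci_low == pytest.approx(np.exp(-Z95 * se))

    def test_round_trip_printed_values(self):
        from bodymr.estimators import MREstimate
        e = to_odds_ratio(MREstimate("ivw", 0.0, 0.1, -0.196, 0.196, 1.0, 3))
        assert round(e.or_ci_low, 2) == 0.82 and round(e.or_ci_high, 2) == 1.22

    def test_zero_se_degenerate_ci(self):
        from bodymr.estimators import MREstimate
        e = to_odds_ratio(MREstimate("ivw", np.log(2), 0.0, np.log(2), np.log(2), 0.0, 1))
        assert e.odds_ratio == pytest.approx(2.0)
        assert e.or_ci_low == e.or_ci_high == pytest.approx(2.0)

    def test_monotone_in_beta(self):
        from bodymr.estimators import MREstimate
        ors = [to_odds_ratio(MREstimate("ivw", b, 0.1, 0, 0, 1, 1)).odds_ratio
               for b in (-0.5, 0.0, 0.5, 1.0)]
        assert ors == sorted(ors)


class TestJointInvariances:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_order_and_sign_invariance_all_methods(self, seed):
        """All multi-SNP estimators are invariant to instrument ordering and
        to jointly negating (beta_x, beta_y) of any instrument."""
        rng = np.random.default_rng(seed)
        k = 12
        bx = rng.uniform(0.05, 0.3, k)
        bxse = np.full(k, 0.005)
        by = 0.2 * bx + rng.normal(0, 0.02, k)
        byse = rng.uniform(0.01, 0.03, k)
        perm = rng.permutation(k)
        flip = rng.choice([-1.0, 1.0], k)

        import pandas as pd
        base = pd.DataFrame({"snp_id": [f"rs{i}" for i in range(k)],
                             "beta_exposure": bx, "se_exposure": bxse,
                             "beta_outcome": by, "se_outcome": byse,
                             "eaf": 0.5, "proxy_of": None})
        tran = base.iloc[perm].reset_index(drop=True)
        tran["beta_exposure"] *= flip[perm]
        tran["beta_outcome"] *= flip[perm]

        # bootstrap SEs are seed-path dependent under permutation; compare
        # point estimates (exact) and bootstrap SEs loosely
        a = estimate_all(base, n_boot=300, seed=7)
        b = estimate_all(tran, n_boot=300, seed=7)
        for m in ("ivw", "egger"):
            assert a[m].beta == pytest.approx(b[m].beta, rel=1e-9)
            assert a[m].se == pytest.approx(b[m].se, rel=1e-9)
        for m in ("weighted_median", "weighted_mode"):
            assert a[m].beta == pytest.approx(b[m].beta, rel=1e-9)
            assert a[m].se == pytest.approx(b[m].se, rel=0.3)
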