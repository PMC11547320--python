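"""Estimator suite: closed-form oracles, simulation oracles and invariances."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrpipe.estimators import (InsufficientInstrumentsError, egger, ivw,
                               leave_one_out, mr_presso, pivw, wald_ratio,
                               weighted_median, weighted_mode,
                               _weighted_median_point, _weighted_mode_point)
from mrpipe.summary_stats import harmonize
from mrpipe.synthetic_data import SimConfig, generate_mr_dataset

from conftest import make_harmonized


def _harmonized_from_sim(cfg):
    exposure, outcome, truth = generate_mr_dataset(cfg)
    return harmonize(exposure, outcome, [r.rsid for r in exposure.records]), truth


@pytest.fixture(scope="module")
def fixture_9snp():
    rng = np.random.default_rng(2024)
    bx = rng.uniform(0.02, 0.08, 9) * rng.choice([-1, 1], 9)
    sx = rng.uniform(0.002, 0.006, 9)
    by = 0.4 * bx + rng.normal(0, 0.01, 9)
    sy = rng.uniform(0.008, 0.02, 9)
    return make_harmonized(bx, sx, by, sy)


class TestWaldRatio:
    def test_arithmetic(self):
        assert wald_ratio(0.1, 0.01, 0.05, 0.01) == pytest.approx((0.5, 0.1))
        assert wald_ratio(0.1, 0.01, 0.0, 0.01)[0] == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)

    def test_first_order_se_matches_monte_carlo(self, rng):
        # se_exp << |beta_exp| so the first-order approximation is tight
        beta_exp, se_exp, beta_out, se_out = 0.1, 0.001, 0.05, 0.01
        _, ratio_se = wald_ratio(beta_exp, se_exp, beta_out, se_out)
        draws = (rng.normal(beta_out, se_out, 1_000_000)
                 / rng.normal(beta_exp, se_exp, 1_000_000))
        assert ratio_se == pytest.approx(np.std(draws), rel=0.02)


class TestIvw:
    def test_homogeneous_ratios(self):
        h = make_harmonized([0.1, 0.2, 0.4], 0.001, [0.05, 0.10, 0.20], 0.01)
        est, het = ivw(h)
        assert est.beta == pytest.approx(0.5)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert est.extras["overdispersion_scale"] == 1.0

    def test_two_snp_weighted_mean(self):
        # ratios 0.4 (se 0.1) and 0.8 (se 0.2): beta = (0.4*100 + 0.8*25)/125
        h = make_harmonized([1.0, 1.0], 0.001, [0.4, 0.8], [0.1, 0.2])
        est, _ = ivw(h)
        assert est.beta == pytest.approx(0.48)

    def test_equals_wls_closed_form(self, fixture_9snp):
        est, _ = ivw(fixture_9snp)
        df = fixture_9snp.snps
        w = 1.0 / df.se_out.to_numpy() ** 2
        fit = sm.WLS(df.beta_out, df.beta_exp, weights=w).fit()
        assert est.beta == pytest.approx(fit.params.iloc[0], abs=1e-10)
        # multiplicative random-effects se: unscaled WLS se times sqrt(phi)
        se_fixed = math.sqrt(fit.cov_params(scale=1.0).iloc[0, 0])
        phi = est.extras["overdispersion_scale"]
        assert est.se == pytest.approx(se_fixed * math.sqrt(phi), abs=1e-10)

    def test_insufficient_instruments(self):
        h = make_harmonized([0.1], 0.001, [0.05], 0.01)
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)


class TestEgger:
    def test_exact_fit_recovers_slope_and_zero_intercept(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.001, 0.3 * bx, 0.01)
        est, _ = egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.extras["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_pleiotropy_lands_in_intercept(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.001, 0.3 * bx + 0.01, 0.01)
        est, _ = egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.extras["intercept"] == pytest.approx(0.01, abs=1e-12)

    def test_equals_wls_closed_form(self, fixture_9snp):
        est, _ = egger(fixture_9snp)
        df = fixture_9snp.snps
        bx = df.beta_exp.to_numpy().copy()
        by = df.beta_out.to_numpy().copy()
        flip = bx < 0
        bx[flip] *= -1
        by[flip] *= -1
        w = 1.0 / df.se_out.to_numpy() ** 2
        fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels always scales by sigma; ours floors sigma at 1
        sigma = math.sqrt(fit.scale)
        expected_se = fit.bse[1] / sigma * max(1.0, sigma)
        assert est.se == pytest.approx(expected_se, abs=1e-10)

    def test_orientation_invariance(self, fixture_9snp):
        df = fixture_9snp.snps.copy()
        df["beta_exp"] *= -1
        df["beta_out"] *= -1
        flipped = make_harmonized(df.beta_exp, df.se_exp, df.beta_out, df.se_out)
        assert egger(flipped)[0].beta == pytest.approx(egger(fixture_9snp)[0].beta)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = make_harmonized([1.0, 1.0, 1.0], 0.001, [0.1, 0.5, 0.9], 0.01)
        est = weighted_median(h, boot_reps=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_degenerate_all_equal(self):
        h = make_harmonized([0.1, 0.2, 0.4], 1e-6, [0.05, 0.1, 0.2], 1e-5)
        est = weighted_median(h, boot_reps=200, seed=1)
        assert est.beta == pytest.approx(0.5)
        assert est.se < 0.01

    def test_matches_percentile_scan_oracle(self):
        ratio = np.array([0.2, 0.5, 0.9, 1.4])
        w = np.array([4.0, 1.0, 2.0, 0.5])
        # brute-force scan of the weighted-percentile interpolation point
        order = np.argsort(ratio)
        r, wn = ratio[order], w[order] / w.sum()
        cum = np.cumsum(wn) - wn / 2
        grid = np.linspace(r[0], r[-1], 200_001)
        interp = np.interp(grid, r, r)  # identity on ratio scale
        pct = np.interp(grid, r, cum)
        expected = grid[np.argmin(np.abs(pct - 0.5))]
        assert _weighted_median_point(ratio, w) == pytest.approx(expected, abs=1e-4)

    def test_bootstrap_seed_recorded_and_reproducible(self):
        h = make_harmonized([0.1, 0.12, 0.2, 0.3], 0.01, [0.05, 0.07, 0.1, 0.14], 0.01)
        e1 = weighted_median(h, boot_reps=100, seed=42)
        e2 = weighted_median(h, boot_reps=100, seed=42)
        assert e1.se == e2.se and e1.extras["seed"] == 42


class TestWeightedMode:
    def test_point_mass(self):
        h = make_harmonized([0.1, 0.2, 0.4], 1e-6, [0.07, 0.14, 0.28], 1e-5)
        est = weighted_mode(h, boot_reps=50, seed=1)
        assert est.beta == pytest.approx(0.7, abs=1e-6)

    def test_majority_cluster_wins(self, rng):
        ratio = np.concatenate([0.5 + 0.02 * rng.standard_normal(6),
                                2.0 + 0.02 * rng.standard_normal(3)])
        h = make_harmonized(np.ones(9), 0.001, ratio, 0.01)
        est = weighted_mode(h, boot_reps=50, seed=1)
        mad = np.median(np.abs(ratio - np.median(ratio)))
        bandwidth = 0.9 * min(np.std(ratio, ddof=1), 1.4826 * mad) * 9 ** -0.2
        assert abs(est.beta - 0.5) < bandwidth

    def test_weight_scale_invariance(self, rng):
        ratio = rng.normal(0.5, 0.1, 7)
        w = rng.uniform(0.5, 4.0, 7)
        assert _weighted_mode_point(ratio, w) == _weighted_mode_point(ratio, 2 * w)


class TestPivw:
    def test_no_measurement_error_limit_equals_ratio_of_sums(self):
        bx = np.array([0.1, 0.2, 0.15, 0.08])
        by = np.array([0.04, 0.09, 0.05, 0.03])
        sy = np.array([0.01, 0.02, 0.015, 0.01])
        h = make_harmonized(bx, 0.0, by, sy)
        est = pivw(h, penalty=0.0)
        expected = np.sum(bx * by / sy ** 2) / np.sum(bx ** 2 / sy ** 2)
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_close_to_ivw_with_strong_instruments(self):
        # mean F > 100: r2 chosen so n*r2/k >> 100
        cfg = SimConfig(k=9, n_exp=121_577, r2_total=0.02, true_beta=0.3,
                        trait_type_out="quantitative", seed=8)
        h, _ = _harmonized_from_sim(cfg)
        assert abs(pivw(h).beta - ivw(h)[0].beta) / abs(ivw(h)[0].beta) < 0.01

    def test_less_biased_than_ivw_with_weak_instruments(self):
        # mean F ~ 5 via r2_total = k*(F-1)/n; moderate replicate count here
        true_beta = 0.4
        k, n_exp = 20, 50_000
        r2 = k * 4.0 / n_exp
        bias_ivw, bias_pivw = [], []
        for s in range(300):
            cfg = SimConfig(k=k, n_exp=n_exp, n_out=200_000, r2_total=r2,
                            true_beta=true_beta, trait_type_out="quantitative",
                            seed=20_000 + s)
            h, _ = _harmonized_from_sim(cfg)
            bias_ivw.append(ivw(h)[0].beta - true_beta)
            bias_pivw.append(pivw(h).beta - true_beta)
        assert abs(np.mean(bias_pivw)) < abs(np.mean(bias_ivw))


class TestMrPresso:
    def test_clean_data_fixed_seed_finds_no_outliers(self):
        cfg = SimConfig(k=9, true_beta=0.2, seed=31)
        h, _ = _harmonized_from_sim(cfg)
        raw, corrected, outliers = mr_presso(h, n_sim=500, seed=11)
        assert outliers == []
        assert corrected.beta == raw.beta

    def test_shifted_snp_detected(self):
        cfg = SimConfig(k=9, true_beta=0.2, n_outliers=1, outlier_shift_sds=10,
                        seed=32)
        h, truth = _harmonized_from_sim(cfg)
        raw, corrected, outliers = mr_presso(h, n_sim=1000, seed=12)
        assert outliers == truth.outlier_rsids
        assert raw.extras["global_pval"] < 0.05

    def test_corrected_equals_ivw_on_remaining_subset(self):
        cfg = SimConfig(k=9, true_beta=0.2, n_outliers=1, outlier_shift_sds=10,
                        seed=33)
        h, _ = _harmonized_from_sim(cfg)
        _, corrected, outliers = mr_presso(h, n_sim=1000, seed=13)
        assert outliers
        keep = [r for r in h.snps.rsid if r not in outliers]
        est, _ = ivw(h.subset(keep))
        assert corrected.beta == pytest.approx(est.beta, abs=0)
        assert corrected.se == pytest.approx(est.se, abs=0)

    def test_too_few_instruments(self):
        h = make_harmonized([0.1, 0.2, 0.3], 0.001, [0.05, 0.1, 0.15], 0.01)
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(h)


class TestLeaveOneOut:
    def test_homogeneous_rows_equal_full_estimate(self):
        h = make_harmonized([0.1, 0.2, 0.4, 0.5], 0.001,
                            [0.05, 0.1, 0.2, 0.25], 0.01)
        full, _ = ivw(h)
        tab = leave_one_out(h)
        assert len(tab) == 4
        assert np.allclose(tab.beta, full.beta)

    def test_extreme_snp_row_deviates_most(self):
        bx = np.array([0.1, 0.2, 0.4, 0.5, 0.3])
        by = 0.5 * bx
        by[2] += 0.3  # rs3 is extreme
        h = make_harmonized(bx, 0.001, by, 0.01)
        full, _ = ivw(h)
        tab = leave_one_out(h)
        dev = np.abs(tab.beta - full.beta)
        assert tab.omitted_rsid[int(np.argmax(dev))] == "rs3"

    def test_row_count_matches_instruments(self):
        cfg = SimConfig(k=9, seed=40)
        h, _ = _harmonized_from_sim(cfg)
        assert len(leave_one_out(h)) == 9


class TestEquivariance:
    METHODS = [
        ("ivw", lambda h: ivw(h)[0]),
        ("egger", lambda h: egger(h)[0]),
        ("pivw", lambda h: pivw(h)),
        ("weighted_median", lambda h: weighted_median(h, 100, 5)),
        ("weighted_mode", lambda h: weighted_mode(h, 1.0, 100, 5)),
    ]

    @pytest.mark.parametrize("name,fn", METHODS, ids=[m[0] for m in METHODS])
    def test_negating_outcome_flips_beta_keeps_se(self, name, fn):
        cfg = SimConfig(k=9, true_beta=0.3, trait_type_out="quantitative", seed=50)
        h, _ = _harmonized_from_sim(cfg)
        df = h.snps.copy()
        df["beta_out"] *= -1
        h_neg = make_harmonized(df.beta_exp, df.se_exp, df.beta_out, df.se_out)
        e, e_neg = fn(h), fn(h_neg)
        assert e_neg.beta == pytest.approx(-e.beta, rel=1e-9, abs=1e-12)
        # bootstrap SEs are equal in distribution, not bitwise
        tol = 0.3 if name.startswith("weighted") else 1e-6
        assert e_neg.se == pytest.approx(e.se, rel=tol)

    @pytest.mark.parametrize("name,fn", METHODS, ids=[m[0] for m in METHODS])
    def test_rescaling_exposure_divides_estimate(self, name, fn):
        c = 2.5
        cfg = SimConfig(k=9, true_beta=0.3, trait_type_out="quantitative", seed=51)
        h, _ = _harmonized_from_sim(cfg)
        df = h.snps.copy()
        h_scaled = make_harmonized(c * df.beta_exp, c * df.se_exp,
                                   df.beta_out, df.se_out)
        e, e_scaled = fn(h), fn(h_scaled)
        assert e_scaled.beta == pytest.approx(e.beta / c, rel=1e-6)


def test_estimators_agree_without_pleiotropy():
    """With strong instruments and no pleiotropy, all estimators center on the
    same causal effect (means within 2 Monte-Carlo SEs of each other)."""
    true_beta = 0.3
    reps = 400
    results = {name: [] for name, _ in TestEquivariance.METHODS}
    results["presso_corrected"] = []
    for s in range(reps):
        cfg = SimConfig(k=9, r2_total=0.005, true_beta=true_beta,
                        trait_type_out="quantitative", seed=60_000 + s)
        h, _ = _harmonized_from_sim(cfg)
        for name, fn in TestEquivariance.METHODS:
            if name in ("weighted_median", "weighted_mode"):
                # point estimates only: bootstrap SEs are irrelevant here
                ratio = (h.snps.beta_out / h.snps.beta_exp).to_numpy()
                w = (h.snps.beta_exp / h.snps.se_out).to_numpy() ** 2
                point = (_weighted_median_point(ratio, w)
                         if name == "weighted_median"
                         else _weighted_mode_point(ratio, w))
                results[name].append(point)
            else:
                results[name].append(fn(h).beta)
        _, corr, _ = mr_presso(h, n_sim=100, seed=s)
        results["presso_corrected"].append(corr.beta)
    means = {k: np.mean(v) for k, v in results.items()}
    ses = {k: np.std(v, ddof=1) / np.sqrt(reps) for k, v in results.items()}
    for a in means:
        for b in means:
            assert abs(means[a] - means[b]) < 2 * (ses[a] + ses[b]), (a, b, means)


def test_ivw_binary_outcome_reports_odds_ratios():
    cfg = SimConfig(k=9, true_beta=math.log(0.62), seed=70)
    h, _ = _harmonized_from_sim(cfg)
    est, _ = ivw(h)
    assert est.or_scale is not None
    or_val, lo, hi = est.or_scale
    assert or_val == pytest.approx(math.exp(est.beta))
    assert lo < or_val < hi
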