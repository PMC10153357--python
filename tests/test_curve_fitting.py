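import math

import numpy as np
import pytest

from redtia.curve_fitting import (
    AIC_RSS_FLOOR,
    fit_bi_lsq,
    fit_mono_2tp,
    fit_mono_batch,
    fit_mono_lsq,
    select_model_aic,
)
from redtia.tac_models import ExponentialModel, TimeActivitySample

REF_TIMES = (4.0, 24.0, 96.0, 168.0)


def samples_from(model, times):
    return [TimeActivitySample(t, model.activity(t)) for t in times]


class TestTwoPointFit:
    def test_halflife_24h_exact_inversion(self):
        fit = fit_mono_2tp(TimeActivitySample(24, 50), TimeActivitySample(48, 25))
        assert fit.valid
        assert fit.model.lambda1 == pytest.approx(math.log(2) / 24, rel=1e-12)
        assert fit.model.C == pytest.approx(100.0, rel=1e-12)
        assert fit.tia == pytest.approx(2400 / math.log(2), rel=1e-12)

    @pytest.mark.parametrize("a2", [40.0, 50.0])  # flat and rising
    def test_nonpositive_decay_flagged_invalid(self, a2):
        fit = fit_mono_2tp(TimeActivitySample(24, 40), TimeActivitySample(48, a2))
        assert not fit.valid
        assert fit.model is None
        assert math.isnan(fit.tia)

    def test_nonpositive_activity_is_domain_error(self):
        with pytest.raises(ValueError):
            fit_mono_2tp(TimeActivitySample(24, 0.0), TimeActivitySample(48, 5.0))

    def test_agrees_with_least_squares_on_two_points(self, rng):
        for _ in range(20):
            lam = rng.uniform(0.003, 0.05)
            m = ExponentialModel("mono", float(rng.uniform(10, 300)), float(lam))
            pts = samples_from(m, sorted(rng.uniform(4, 200, size=2)))
            exact = fit_mono_2tp(*pts)
            lsq = fit_mono_lsq(pts)
            assert lsq.model.lambda1 == pytest.approx(exact.model.lambda1, rel=1e-9)
            assert lsq.model.C == pytest.approx(exact.model.C, rel=1e-9)
            assert lsq.rss == pytest.approx(0.0, abs=1e-12)


class TestMonoLeastSquares:
    def test_noiseless_recovery(self):
        truth = ExponentialModel("mono", 100, 0.02)
        fit = fit_mono_lsq(samples_from(truth, REF_TIMES))
        assert fit.valid
        assert fit.model.C == pytest.approx(100, rel=1e-6)
        assert fit.model.lambda1 == pytest.approx(0.02, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-10)
        assert fit.tia == pytest.approx(truth.tia(), rel=1e-6)

    def test_log_collinear_points_match_independent_regression_oracle(self):
        # independent oracle: closed-form OLS of ln(A) on t
        pts = [TimeActivitySample(24, 80), TimeActivitySample(48, 40),
               TimeActivitySample(72, 20)]
        t = np.array([p.time for p in pts])
        y = np.log([p.activity for p in pts])
        slope = ((t - t.mean()) * (y - y.mean())).sum() / ((t - t.mean()) ** 2).sum()
        lam_oracle = -slope
        C_oracle = math.exp(y.mean() - slope * t.mean())
        assert lam_oracle == pytest.approx(math.log(2) / 24, rel=1e-12)
        assert C_oracle == pytest.approx(160.0, rel=1e-12)
        fit = fit_mono_lsq(pts)
        assert fit.model.lambda1 == pytest.approx(lam_oracle, rel=1e-8)
        assert fit.model.C == pytest.approx(C_oracle, rel=1e-8)

    def test_rising_activity_flagged_by_lambda_sign(self):
        fit = fit_mono_lsq([TimeActivitySample(24, 10), TimeActivitySample(28, 200)])
        assert not fit.valid
        assert "non-positive" in fit.message

    def test_too_few_positive_activities_is_domain_error(self):
        with pytest.raises(ValueError):
            fit_mono_lsq([TimeActivitySample(24, 0.0), TimeActivitySample(48, 0.0),
                          TimeActivitySample(72, 5.0)])


class TestBiexponentialFit:
    def test_noiseless_recovery(self):
        truth = ExponentialModel("bi", 100, 0.01, 0.1)
        fit = fit_bi_lsq(samples_from(truth, REF_TIMES))
        assert fit.valid
        assert fit.model.C == pytest.approx(100, rel=1e-4)
        assert fit.model.lambda1 == pytest.approx(0.01, rel=1e-4)
        assert fit.model.lambda2 == pytest.approx(0.1, rel=1e-4)
        assert fit.tia == pytest.approx(truth.tia(), rel=1e-4)

    def test_nested_model_property_on_mono_data(self, rng):
        for _ in range(5):
            truth = ExponentialModel("mono", float(rng.uniform(50, 200)),
                                     float(rng.uniform(0.005, 0.03)))
            noisy = [
                TimeActivitySample(t, truth.activity(t) * (1 + 0.03 * rng.standard_normal()))
                for t in REF_TIMES
            ]
            mono = fit_mono_lsq(noisy)
            bi = fit_bi_lsq(noisy)
            assert bi.rss <= mono.rss + 1e-6 * max(mono.rss, 1.0)

    def test_order_invariance(self):
        truth = ExponentialModel("bi", 80, 0.008, 0.2)
        pts = samples_from(truth, REF_TIMES)
        a = fit_bi_lsq(pts)
        b = fit_bi_lsq(list(reversed(pts)))
        assert b.model.C == pytest.approx(a.model.C, rel=1e-9)
        assert b.model.lambda1 == pytest.approx(a.model.lambda1, rel=1e-9)
        assert b.model.lambda2 == pytest.approx(a.model.lambda2, rel=1e-9)
        assert b.rss == pytest.approx(a.rss, abs=1e-12)

    def test_needs_four_points(self):
        truth = ExponentialModel("bi", 80, 0.008, 0.2)
        with pytest.raises(ValueError):
            fit_bi_lsq(samples_from(truth, (4, 24, 96)))


class TestAicSelection:
    def test_mono_data_selects_mono(self):
        truth = ExponentialModel("mono", 100, 0.02)
        fit = select_model_aic(samples_from(truth, REF_TIMES))
        assert fit.model.kind == "mono"

    def test_biphasic_data_selects_bi_and_matches_aic_oracle(self):
        truth = ExponentialModel("bi", 100, 0.005, 0.15)
        pts = samples_from(truth, REF_TIMES)
        mono, bi = fit_mono_lsq(pts), fit_bi_lsq(pts)
        # direct AIC formula as the selection oracle
        aic_mono = 4 * math.log(max(mono.rss, AIC_RSS_FLOOR) / 4) + 2 * 2
        aic_bi = 4 * math.log(max(bi.rss, AIC_RSS_FLOOR) / 4) + 2 * 3
        assert mono.aic == pytest.approx(aic_mono)
        assert bi.aic == pytest.approx(aic_bi)
        assert aic_bi < aic_mono
        assert select_model_aic(pts).model.kind == "bi"

    def test_shared_noise_keeps_oracle_and_selection_consistent(self, rng):
        truth = ExponentialModel("bi", 100, 0.005, 0.15)
        noise = rng.normal(0, 0.5, size=4)
        pts = [
            TimeActivitySample(t, max(truth.activity(t) + e, 0.1))
            for t, e in zip(REF_TIMES, noise)
        ]
        mono, bi = fit_mono_lsq(pts), fit_bi_lsq(pts)
        expected_kind = "bi" if bi.aic < mono.aic else "mono"
        assert select_model_aic(pts).model.kind == expected_kind

    def test_requires_exactly_four(self):
        truth = ExponentialModel("mono", 100, 0.02)
        with pytest.raises(ValueError):
            select_model_aic(samples_from(truth, (4, 24, 96)))


class TestBatchFitter:
    def test_matches_scipy_reference_on_noisy_triples(self, rng):
        m = 200
        lam = rng.uniform(0.004, 0.04, size=m)
        C = rng.uniform(20, 300, size=m)
        t = np.sort(rng.uniform(4, 230, size=(m, 3)), axis=1)
        a = C[:, None] * np.exp(-lam[:, None] * t)
        a *= 1 + 0.05 * rng.standard_normal(a.shape)
        a = np.maximum(a, 0.01)
        batch = fit_mono_batch(t, a)
        for i in range(0, m, 7):
            pts = [TimeActivitySample(ti, ai) for ti, ai in zip(t[i], a[i])]
            ref = fit_mono_lsq(pts)
            if ref.valid and batch["valid"][i]:
                assert batch["rss"][i] == pytest.approx(ref.rss, rel=1e-5, abs=1e-7)
                assert batch["tia"][i] == pytest.approx(ref.tia, rel=1e-4)
            else:
                assert batch["valid"][i] == ref.valid

    def test_exact_on_noiseless_rows(self, rng):
        lam = rng.uniform(0.004, 0.04, size=50)
        C = rng.uniform(20, 300, size=50)
        t = np.sort(rng.uniform(4, 230, size=(50, 3)), axis=1)
        a = C[:, None] * np.exp(-lam[:, None] * t)
        batch = fit_mono_batch(t, a)
        assert batch["valid"].all()
        np.testing.assert_allclose(batch["lam"], lam, rtol=1e-8)
        np.testing.assert_allclose(batch["tia"], C / lam, rtol=1e-8)

    def test_rows_without_two_positive_points_invalid(self):
        t = np.array([[24.0, 48.0, 72.0]])
        a = np.array([[0.0, 0.0, 5.0]])
        batch = fit_mono_batch(t, a)
        assert not batch["valid"][0]
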