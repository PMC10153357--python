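import math

import numpy as np
import pytest

from redtia.cohort_simulation import (
    CohortDistribution,
    LognormalSpec,
    derive_distribution,
    run_simulation_study,
    sample_tac,
)
from redtia.curve_fitting import FitResult
from redtia.tac_models import ExponentialModel

from conftest import make_dist


def fit_of(model):
    return FitResult(model=model, rss=0.0, aic=0.0, n_points=4,
                     tia=model.tia(), valid=True)


class TestDeriveDistribution:
    def test_two_value_log_mean_and_sd_by_hand(self):
        lams = [math.log(2) / 50, math.log(2) / 100]
        fits = [fit_of(ExponentialModel("mono", 100.0, lam)) for lam in lams]
        dist = derive_distribution(fits, "kidney")
        spec = dist.mono["lambda1"]
        assert spec.mu == pytest.approx(math.log(2) / math.sqrt(5000), rel=1e-9)
        assert spec.mu == pytest.approx(0.009802, abs=1e-6)
        assert spec.s == pytest.approx(math.log(2) / math.sqrt(2), rel=1e-9)
        assert spec.s == pytest.approx(0.4901, abs=1e-4)
        assert (spec.lower, spec.upper) == (min(lams), max(lams))

    def test_identical_values_degenerate_to_constant(self, rng):
        fits = [fit_of(ExponentialModel("mono", 100.0, 0.01)) for _ in range(5)]
        dist = derive_distribution(fits, "spleen")
        assert dist.mono["lambda1"].s == 0.0
        for _ in range(10):
            m = sample_tac(dist, rng)
            assert m.lambda1 == 0.01 and m.C == 100.0

    def test_literature_halflife_range_widens_lambda_bounds(self):
        lams = [math.log(2) / 50, math.log(2) / 100]
        fits = [fit_of(ExponentialModel("mono", 100.0, lam)) for lam in lams]
        dist = derive_distribution(fits, "kidney", halflife_cutoffs=(20.0, 200.0))
        spec = dist.mono["lambda1"]
        assert spec.lower == pytest.approx(math.log(2) / 200)
        assert spec.upper == pytest.approx(math.log(2) / 20)
        # amplitude bounds stay at the cohort range
        assert dist.mono["C"].lower == dist.mono["C"].upper == 100.0

    def test_single_fit_of_a_type_drops_that_label(self):
        fits = [fit_of(ExponentialModel("mono", 100.0, 0.01)),
                fit_of(ExponentialModel("mono", 120.0, 0.012)),
                fit_of(ExponentialModel("bi", 100.0, 0.01, 0.2))]
        with pytest.warns(UserWarning, match="dropped from bootstrap"):
            dist = derive_distribution(fits, "tumor")
        assert set(dist.fit_type_labels) == {"mono"}

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError):
            derive_distribution([], "tumor")


class TestSampleTac:
    def test_truncation_contract(self, rng):
        dist = make_dist("kidney", 50, 90, bi_fraction=0.0)
        spec = dist.mono["lambda1"]
        draws = [sample_tac(dist, rng).lambda1 for _ in range(2000)]
        assert all(spec.lower <= lam <= spec.upper for lam in draws)

    def test_bootstrap_fraction_matches_source(self, rng):
        dist = make_dist("tumor", 90, 60, bi_fraction=0.3)
        kinds = [sample_tac(dist, rng).kind for _ in range(10_000)]
        assert np.mean([k == "bi" for k in kinds]) == pytest.approx(0.3, abs=0.02)

    def test_bi_rate_ordering_enforced(self, rng):
        dist = make_dist("tumor", 90, 60, bi_fraction=1.0)
        for _ in range(200):
            m = sample_tac(dist, rng)
            assert m.lambda2 > m.lambda1

    def test_inconsistent_bounds_raise(self, rng):
        spec = LognormalSpec(s=0.001, mu=1.0, lower=1.0, upper=1.0 + 1e-15)
        with pytest.raises(RuntimeError):
            spec.sample(rng)


class TestSimulationStudy:
    def test_zero_noise_mono_cohort_refits_exactly(self, mono_only_dists, pop_kinetics):
        res = run_simulation_study(
            mono_only_dists, pop_kinetics, noise=None, n_curves=5, seed=3,
            families=("2tp", "3tp"),
        )
        for structure in res.structures:
            for fam in ("2tp", "3tp"):
                est = res.est[(structure, fam)]
                true = res.true_tia[structure][:, None]
                assert res.valid[(structure, fam)].all()
                np.testing.assert_allclose(est, np.broadcast_to(true, est.shape),
                                           rtol=1e-6)

    def test_zero_noise_madsen_exact_at_population_halflife(self, mono_only_dists):
        from redtia.config import population_kinetics_from_mapping
        pop = population_kinetics_from_mapping({"kidney": 50.0, "tumor": 90.0})
        res = run_simulation_study(
            mono_only_dists, pop, noise=None, n_curves=3, seed=3, families=("madsen",),
        )
        for structure in res.structures:
            est = res.est[(structure, "madsen")]
            true = res.true_tia[structure][:, None]
            np.testing.assert_allclose(est, np.broadcast_to(true, est.shape),
                                       rtol=1e-10)

    def test_same_seed_bitwise_identical(self, default_dists, pop_kinetics):
        kw = dict(population_kinetics=pop_kinetics, n_curves=4, seed=11,
                  families=("hanscheid", "2tp"))
        from redtia.synthetic_data import DEFAULT_NOISE_MODEL
        r1 = run_simulation_study(default_dists, noise=DEFAULT_NOISE_MODEL, **kw)
        r2 = run_simulation_study(default_dists, noise=DEFAULT_NOISE_MODEL, **kw)
        for key in r1.est:
            np.testing.assert_array_equal(r1.est[key], r2.est[key])
        for s in r1.structures:
            np.testing.assert_array_equal(r1.true_tia[s], r2.true_tia[s])

    def test_adding_families_does_not_perturb_curves(self, default_dists, pop_kinetics):
        from redtia.synthetic_data import DEFAULT_NOISE_MODEL
        r1 = run_simulation_study(default_dists, pop_kinetics, DEFAULT_NOISE_MODEL,
                                  n_curves=4, seed=11, families=("2tp",))
        r2 = run_simulation_study(default_dists, pop_kinetics, DEFAULT_NOISE_MODEL,
                                  n_curves=4, seed=11, families=("2tp", "3tp", "madsen"))
        np.testing.assert_array_equal(r1.est[("kidney", "2tp")], r2.est[("kidney", "2tp")])

    def test_mpe_standard_error_shrinks_with_cohort_size(self, pop_kinetics):
        from redtia.synthetic_data import DEFAULT_NOISE_MODEL
        dists = {"kidney": make_dist("kidney", 50, 90)}
        summaries = {}
        for n in (50, 200):
            res = run_simulation_study(dists, pop_kinetics, DEFAULT_NOISE_MODEL,
                                       n_curves=n, seed=5, families=("2tp",))
            df = res.summaries()
            row = df[(df.t1_h == 24) & (df.t2_h == 96)].iloc[0]
            summaries[n] = row
        hw50 = summaries[50].ci95_high - summaries[50].ci95_low
        hw200 = summaries[200].ci95_high - summaries[200].ci95_low
        # dispersion is a population property; the CI halfwidth scales ~1/sqrt(n)
        sd_ratio = summaries[50].sd / summaries[200].sd
        assert 0.5 < sd_ratio < 2.0
        assert hw50 / hw200 == pytest.approx(2.0 * sd_ratio, rel=0.05)

    def test_madsen_requires_population_kinetics(self, default_dists):
        with pytest.raises(ValueError):
            run_simulation_study(default_dists, None, None, n_curves=2, seed=1,
                                 families=("madsen",))


def test_distribution_json_round_trip():
    dist = make_dist("spleen", 70, 120, bi_fraction=0.3)
    back = CohortDistribution.from_json(dist.to_json())
    assert back == dist
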