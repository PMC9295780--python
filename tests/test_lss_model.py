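import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import lssfind as lf
from lssfind.lss_model import BasicInteraction


def eq9_model():
    """E[Y|X1,X2] = 1(X1<=0.5) 1(X2<=0.5)."""
    return lf.LSSModel(
        p=2,
        interactions=[
            BasicInteraction(
                features={lf.SignedFeature(1, -1), lf.SignedFeature(2, -1)},
                thresholds={1: 0.5, 2: 0.5},
                coefficient=1.0,
            )
        ],
    )


class TestRegressionFunction:
    @pytest.mark.parametrize(
        "x,expected",
        [((0.3, 0.4), 1.0), ((0.6, 0.4), 0.0), ((0.3, 0.6), 0.0), ((0.5, 0.5), 1.0)],
    )
    def test_conjunction_model(self, x, expected):
        assert lf.regression_function(eq9_model(), x) == expected

    def test_intercept_only(self):
        m = lf.LSSModel(p=3, intercept=0.7)
        assert lf.regression_function(m, (0.1, 0.9, 0.5)) == 0.7

    def test_dimension_mismatch_names_p(self):
        with pytest.raises(ValueError, match="2"):
            lf.regression_function(eq9_model(), (0.1, 0.2, 0.3))

    def test_vectorized_matches_scalar(self):
        m = eq9_model()
        X = np.random.default_rng(0).random((50, 2))
        vec = lf.regression_function(m, X)
        assert vec.tolist() == [lf.regression_function(m, x) for x in X]

    def test_positive_sign_uses_strict_greater(self):
        m = lf.LSSModel(
            p=1,
            interactions=[
                BasicInteraction(
                    features={lf.SignedFeature(1, +1)}, thresholds={1: 0.5}
                )
            ],
        )
        assert lf.regression_function(m, (0.5,)) == 0.0
        assert lf.regression_function(m, (0.51,)) == 1.0

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_monotone_transform_invariance(self, a, b):
        """The mean function only depends on feature ranks: transforming
        features and thresholds by the same increasing map changes nothing."""
        m = eq9_model()
        g = lambda v: v**3 + 2 * v  # strictly increasing
        mt = lf.LSSModel(
            p=2,
            interactions=[
                BasicInteraction(
                    features=ia.features,
                    thresholds={k: g(v) for k, v in ia.thresholds.items()},
                    coefficient=ia.coefficient,
                )
                for ia in m.interactions
            ],
        )
        x = (a, b)
        assert lf.regression_function(m, x) == lf.regression_function(
            mt, tuple(g(v) for v in x)
        )


class TestCalibration:
    @pytest.mark.parametrize(
        "J,L,tau",
        [
            (1, 1, 0.5),
            (1, 2, 0.7071067811865476),  # sqrt(1/2)
            (2, 2, 0.5411961001461970),  # sqrt(1 - sqrt(1/2))
        ],
    )
    def test_closed_form(self, J, L, tau):
        assert lf.calibrate_threshold(J, L, 0.5) == pytest.approx(tau, abs=1e-12)

    @pytest.mark.parametrize("J,L", [(1, 2), (2, 2), (2, 3), (1, 4)])
    def test_monte_carlo_coverage(self, J, L):
        """Fraction of uniform samples in the union of hyper-rectangles is the
        requested coverage, within 3 binomial standard errors."""
        n = 20_000
        model = lf.build_simulation_model(J, L, p=J * L)
        X = lf.sample_features(n, J * L, seed=7)
        frac = np.mean(lf.regression_function(model, X) > 0)
        se = math.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se

    def test_coverage_out_of_range(self):
        with pytest.raises(ValueError):
            lf.calibrate_threshold(1, 2, 1.0)


class TestBuildSimulationModel:
    def test_block_index_pattern(self):
        m = lf.build_simulation_model(2, 3, 20)
        assert [sorted(f.index for f in ia.features) for ia in m.interactions] == [
            [1, 2, 3],
            [4, 5, 6],
        ]
        assert all(f.sign == -1 for ia in m.interactions for f in ia.features)
        assert all(ia.coefficient == 1.0 for ia in m.interactions)
        assert m.intercept == 0.0

    def test_single_feature_minimal(self):
        m = lf.build_simulation_model(1, 1, 1)
        (ia,) = m.interactions
        assert ia.thresholds == {1: 0.5}

    def test_too_many_signal_features(self):
        with pytest.raises(ValueError):
            lf.build_simulation_model(3, 4, 10)


class TestSampleFeatures:
    def test_independent_case(self):
        X = lf.sample_features(1000, 5, seed=0)
        corr = np.corrcoef(X, rowvar=False)
        assert np.abs(corr - np.eye(5)).max() < 0.1
        for j in range(5):
            assert stats.kstest(X[:, j], "uniform").statistic < 0.05

    def test_latent_ar1_correlation(self):
        X = lf.sample_features(100_000, 2, corr=0.8, seed=1)
        z = stats.norm.ppf(X)
        assert np.corrcoef(z[:, 0], z[:, 1])[0, 1] == pytest.approx(0.8, abs=0.02)

    def test_correlated_marginals_stay_uniform(self):
        X = lf.sample_features(20_000, 3, corr=0.9, seed=2)
        for j in range(3):
            assert stats.kstest(X[:, j], "uniform").statistic < 0.02

    def test_determinism(self):
        a = lf.sample_features(100, 4, corr=0.5, seed=42)
        b = lf.sample_features(100, 4, corr=0.5, seed=42)
        assert np.array_equal(a, b)

    def test_alpha_one_rejected(self):
        with pytest.raises(ValueError):
            lf.sample_features(10, 2, corr=1.0)


class TestSignalVariance:
    def test_single_pair_at_half_coverage(self):
        m = lf.build_simulation_model(1, 2, 20)
        assert lf.signal_variance(m) == pytest.approx(0.25, abs=1e-12)

    def test_two_pairs(self):
        m = lf.build_simulation_model(2, 2, 20)
        q = (1 - math.sqrt(0.5))  # tau^2 per interaction
        assert lf.signal_variance(m) == pytest.approx(2 * q * (1 - q), abs=1e-12)

    def test_constant_model(self):
        assert lf.signal_variance(lf.LSSModel(p=4, intercept=1.0)) == 0.0

    @pytest.mark.parametrize("J,L", [(1, 2), (2, 3)])
    def test_matches_monte_carlo(self, J, L):
        m = lf.build_simulation_model(J, L, 10)
        X = lf.sample_features(200_000, 10, seed=5)
        mc = np.var(lf.regression_function(m, X))
        assert lf.signal_variance(m) == pytest.approx(mc, abs=0.003)

    def test_overlap_falls_back_to_monte_carlo(self):
        m = lf.build_overlap_model(2, 5, overlap=1)
        v = lf.signal_variance(m, mc_samples=100_000, seed=3)
        X = lf.sample_features(100_000, 5, seed=9)
        assert v == pytest.approx(np.var(lf.regression_function(m, X)), abs=0.01)


class TestSampleDataset:
    def test_noise_variance_matches_snr(self):
        m = lf.build_simulation_model(1, 2, 20)
        d = lf.sample_dataset(m, 100_000, snr=5.0, seed=0)
        resid = d.y - lf.regression_function(m, d.X)
        assert np.var(resid) == pytest.approx(0.05, rel=0.05)

    def test_laplace_variance_matches_gaussian_recipe(self):
        m = lf.build_simulation_model(1, 2, 20)
        d = lf.sample_dataset(m, 100_000, snr=2.0, noise_family="laplace", seed=1)
        resid = d.y - lf.regression_function(m, d.X)
        assert np.var(resid) == pytest.approx(0.125, rel=0.05)

    def test_infinite_snr_is_noiseless(self):
        m = lf.build_simulation_model(1, 2, 5)
        d = lf.sample_dataset(m, 200, snr=math.inf, seed=2)
        assert np.array_equal(d.y, lf.regression_function(m, d.X))

    def test_determinism(self):
        m = lf.build_simulation_model(1, 2, 5)
        d1 = lf.sample_dataset(m, 50, snr=1.0, seed=7)
        d2 = lf.sample_dataset(m, 50, snr=1.0, seed=7)
        assert np.array_equal(d1.X, d2.X) and np.array_equal(d1.y, d2.y)

    def test_invalid_snr(self):
        m = lf.build_simulation_model(1, 2, 5)
        with pytest.raises(ValueError):
            lf.sample_dataset(m, 10, snr=0.0)

    def test_cauchy_runs_with_nominal_scale(self):
        m = lf.build_simulation_model(1, 2, 5)
        d = lf.sample_dataset(m, 100, snr=5.0, noise_family="cauchy", seed=3)
        assert d.provenance["sigma"] == pytest.approx(math.sqrt(0.05))


class TestUnionSignedInteractions:
    def test_definition_example(self, S):
        """One singleton plus one pair yields exactly five union interactions,
        the singleton contributing either sign."""
        m = lf.LSSModel(
            p=3,
            interactions=[
                BasicInteraction(features={S(1, -1)}, thresholds={1: 0.5}),
                BasicInteraction(
                    features={S(2, -1), S(3, -1)}, thresholds={2: 0.5, 3: 0.5}
                ),
            ],
        )
        got = set(lf.union_signed_interactions(m, smax=3))
        expected = {
            frozenset({S(1, -1)}),
            frozenset({S(1, +1)}),
            frozenset({S(2, -1), S(3, -1)}),
            frozenset({S(1, -1), S(2, -1), S(3, -1)}),
            frozenset({S(1, +1), S(2, -1), S(3, -1)}),
        }
        assert got == expected

    def test_single_interaction(self):
        m = lf.build_simulation_model(1, 2, 4)
        assert lf.union_signed_interactions(m, smax=2) == [m.interactions[0].features]

    def test_two_pairs_give_three_sets(self):
        m = lf.build_simulation_model(2, 2, 6)
        got = lf.union_signed_interactions(m, smax=4)
        a, b = (ia.features for ia in m.interactions)
        assert set(got) == {a, b, a | b}

    def test_smax_truncates(self):
        m = lf.build_simulation_model(2, 2, 6)
        assert len(lf.union_signed_interactions(m, smax=2)) == 2


class TestValidationAndSerialization:
    def test_strict_mode_rejects_overlap(self, S):
        m = lf.build_overlap_model(2, 5, overlap=1)
        with pytest.raises(ValueError, match="overlap"):
            m.validate(strict=True)
        m.validate(strict=True, allow_overlap=True)

    def test_strict_mode_rejects_out_of_bound_threshold(self, S):
        m = lf.LSSModel(
            p=2,
            c_gamma=0.2,
            interactions=[
                BasicInteraction(features={S(1, -1)}, thresholds={1: 0.1})
            ],
        )
        with pytest.raises(ValueError, match="threshold"):
            m.validate(strict=True)

    def test_strict_mode_rejects_small_coefficient(self, S):
        m = lf.LSSModel(
            p=2,
            c_beta=0.5,
            interactions=[
                BasicInteraction(features={S(1, -1)}, thresholds={1: 0.5}, coefficient=0.3)
            ],
        )
        with pytest.raises(ValueError, match="C_beta"):
            m.validate(strict=True)

    def test_model_json_roundtrip(self, tmp_path):
        m = lf.build_simulation_model(2, 3, 20)
        path = tmp_path / "model.json"
        m.save(path)
        m2 = lf.LSSModel.load(path)
        assert m2.p == m.p
        assert [ia.features for ia in m2.interactions] == [
            ia.features for ia in m.interactions
        ]
        assert m2.interactions[0].thresholds == m.interactions[0].thresholds

    def test_dataset_csv_roundtrip(self, tmp_path):
        m = lf.build_simulation_model(1, 2, 3)
        d = lf.sample_dataset(m, 20, snr=1.0, seed=0)
        path = tmp_path / "data.csv"
        d.save(path)
        assert path.read_text().splitlines()[0] == "x1,x2,x3,y"
        d2 = lf.Dataset.load(path, strict=True)
        np.testing.assert_allclose(d2.X, d.X, rtol=0, atol=0)
        np.testing.assert_allclose(d2.y, d.y, rtol=0, atol=0)
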