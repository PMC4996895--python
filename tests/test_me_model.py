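import numpy as np
import pytest

from canopybench import (
    InvalidInputError,
    InvalidParameterError,
    MaxEntRegressor,
    MEModel,
    SampleSet,
    fit_me,
    make_binning,
    posterior_probabilities,
    power_expectation,
    predict_me,
)


class TestMakeBinning:
    def test_single_class(self):
        b = make_binning([5.0, 5.0, 5.0], bin_width=2.0)
        assert b.n_classes == 1
        assert b.centers[0] == 5.0

    def test_hand_enumeration(self):
        b = make_binning([3.0, 4.0, 11.0], bin_width=10.0)
        assert b.n_classes == 2
        np.testing.assert_allclose(b.centers, [3.5, 11.0])
        # classes are (0, 10] and (10, 20]
        np.testing.assert_array_equal(b.assign([3.0, 4.0, 11.0]), [0, 0, 1])
        np.testing.assert_array_equal(b.assign([10.0, 10.5]), [0, 1])

    def test_counts_partition_sample(self, rng):
        y = rng.uniform(0.5, 40, 500)
        b = make_binning(y, bin_width=2.0)
        assert b.counts.sum() == 500
        assert (b.assign(y) >= 0).all()

    def test_centers_lie_within_bins(self, rng):
        y = rng.uniform(0.5, 40, 300)
        b = make_binning(y, 5.0)
        lo = b.edges[b.bin_of_class]
        hi = b.edges[b.bin_of_class + 1]
        assert ((b.centers > lo) & (b.centers <= hi)).all()

    def test_invalid_width(self):
        with pytest.raises(InvalidParameterError):
            make_binning([1.0], bin_width=0.0)


class TestPowerExpectation:
    def test_plain_expectation_worked_example(self):
        # raw (0.2, 0.8), priors (0.5, 0.5), centers (10, 30), m = 1:
        # (0.2*0.5*10 + 0.8*0.5*30) / (0.2*0.5 + 0.8*0.5) = 26
        out = power_expectation([0.2, 0.8], [0.5, 0.5], [10.0, 30.0], m=1)
        assert out[0] == pytest.approx(26.0, abs=1e-12)

    def test_power_three_worked_example(self):
        # (0.008*10 + 0.512*30) / (0.008 + 0.512) ~= 29.69
        out = power_expectation([0.2, 0.8], [0.5, 0.5], [10.0, 30.0], m=3)
        assert out[0] == pytest.approx((0.008 * 10 + 0.512 * 30) / 0.520,
                                       abs=1e-12)
        assert out[0] == pytest.approx(29.6923, abs=1e-4)

    def test_uniform_raw_gives_prior_weighted_mean(self):
        priors = np.array([0.2, 0.3, 0.5])
        centers = np.array([5.0, 15.0, 30.0])
        out = power_expectation(np.ones(3), priors, centers, m=1)
        assert out[0] == pytest.approx(priors @ centers)

    def test_power_must_be_at_least_one(self):
        with pytest.raises(InvalidParameterError):
            power_expectation([0.5, 0.5], [0.5, 0.5], [1.0, 2.0], m=0.5)


def _separated_data(rng, n=300):
    """Two well-separated 1-D classes around -3 and +3."""
    xa = rng.normal(-3.0, 0.3, n)
    xb = rng.normal(3.0, 0.3, n)
    X = np.concatenate([xa, xb])[:, None]
    y = np.concatenate([np.full(n, 5.0), np.full(n, 15.0)])
    bg = rng.uniform(-5, 5, (4000, 1))
    return SampleSet(X, y), bg


class TestFitME:
    def test_single_class_posterior_one(self, rng):
        train = SampleSet(rng.normal(size=(50, 2)), np.full(50, 12.0))
        model = fit_me(train, rng.normal(size=(500, 2)), bin_width=2.0)
        post = posterior_probabilities(model, rng.normal(size=(20, 2)))
        np.testing.assert_allclose(post, 1.0)
        np.testing.assert_allclose(predict_me(model, rng.normal(size=(9, 2)),
                                              m=3), 12.0)

    def test_separated_classes_vs_histogram_oracle(self, rng):
        train, bg = _separated_data(rng)
        model = fit_me(train, bg, bin_width=10.0)
        assert model.binning.n_classes == 2
        post = posterior_probabilities(model, np.array([[-3.0], [3.0]]))
        assert post[0, 0] > 0.9 and post[1, 1] > 0.9
        # independent oracle: histogram density ratio + Bayes
        edges = np.linspace(-5, 5, 41)
        p_bg = 1.0 / 10.0  # uniform background density
        labels = model.binning.assign(train.y)
        for q, expect_class in ((-3.0, 0), (3.0, 1)):
            b = np.digitize(q, edges) - 1
            raws = []
            for k in range(2):
                xk = train.X[labels == k, 0]
                dens = (np.histogram(xk, edges)[0][b] / len(xk)
                        / (edges[1] - edges[0]))
                raws.append(dens / p_bg)
            oracle = np.array(raws) * model.priors
            assert oracle.argmax() == expect_class
            assert post[expect_class].argmax() == oracle.argmax()

    def test_duplicated_training_set_gives_identical_model(self, rng):
        train, bg = _separated_data(rng, n=100)
        doubled = SampleSet(np.vstack([train.X, train.X]),
                            np.concatenate([train.y, train.y]))
        a = fit_me(train, bg, bin_width=10.0)
        b = fit_me(doubled, bg, bin_width=10.0)
        np.testing.assert_allclose(a.class_weights, b.class_weights,
                                   atol=1e-6)
        np.testing.assert_allclose(a.priors, b.priors)

    def test_background_dimension_mismatch(self, rng):
        train = SampleSet(rng.normal(size=(30, 2)), rng.uniform(1, 10, 30))
        with pytest.raises(InvalidInputError):
            fit_me(train, rng.normal(size=(100, 3)))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(77)
    x = rng.uniform(0, 40, 600)
    y = x + rng.normal(0, 2.0, 600)
    train = SampleSet(x[:, None], np.clip(y, 0.1, None))
    bg = rng.uniform(0, 40, (3000, 1))
    return fit_me(train, bg, bin_width=5.0), train, bg


class TestPredictME:

    def test_posteriors_sum_to_one(self, fitted, rng):
        model, _, _ = fitted
        post = posterior_probabilities(model, rng.uniform(0, 40, (50, 1)))
        assert (post >= 0).all()
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_prediction_is_convex_combination_of_centers(self, fitted, rng):
        model, _, _ = fitted
        for m in (1.0, 3.0):
            pred = predict_me(model, rng.uniform(-10, 60, (200, 1)), m=m)
            assert (pred >= model.binning.centers.min() - 1e-9).all()
            assert (pred <= model.binning.centers.max() + 1e-9).all()

    def test_power_weighting_moves_top_class_toward_center(self, fitted):
        """Raising m from 1 to 3 pulls predictions over top-class samples
        toward the top class center (the bias-correction direction)."""
        model, train, _ = fitted
        top = train.y > np.quantile(train.y, 0.9)
        X_top = train.X[top]
        p1 = predict_me(model, X_top, m=1).mean()
        p3 = predict_me(model, X_top, m=3).mean()
        top_center = model.binning.centers.max()
        assert abs(top_center - p3) < abs(top_center - p1)

    def test_m_one_matches_direct_eq7_evaluation(self, fitted, rng):
        model, _, _ = fitted
        X = rng.uniform(0, 40, (30, 1))
        raw = np.exp(model.log_raw(X))
        direct = power_expectation(raw, model.priors,
                                   model.binning.centers, m=1)
        np.testing.assert_allclose(predict_me(model, X, m=1), direct,
                                   rtol=1e-10)

    def test_json_roundtrip_preserves_predictions(self, fitted, rng):
        model, _, _ = fitted
        X = rng.uniform(0, 40, (40, 1))
        back = MEModel.from_json(model.to_json())
        np.testing.assert_allclose(predict_me(back, X),
                                   predict_me(model, X), rtol=1e-12)


class TestMaxEntRegressor:
    def test_fit_predict_interface_learns_signal(self, rng):
        x = rng.uniform(0, 40, 500)
        y = np.clip(x + rng.normal(0, 3, 500), 0.1, None)
        reg = MaxEntRegressor(bin_width=5.0, power_m=1).fit(x[:, None], y)
        pred = reg.predict(x[:400, None])
        assert np.corrcoef(pred, y[:400])[0, 1] > 0.8

    def test_background_cap_subsamples_reproducibly(self, rng):
        x = rng.uniform(0, 40, 300)
        y = np.clip(x + rng.normal(0, 3, 300), 0.1, None)
        bg = rng.uniform(0, 40, (5000, 1))
        a = MaxEntRegressor(bin_width=5.0, background=bg,
                            background_cap=1000, seed=4).fit(x[:, None], y)
        b = MaxEntRegressor(bin_width=5.0, background=bg,
                            background_cap=1000, seed=4).fit(x[:, None], y)
        np.testing.assert_array_equal(a.predict(x[:50, None]),
                                      b.predict(x[:50, None]))

    def test_predict_before_fit(self):
        with pytest.raises(InvalidInputError):
            MaxEntRegressor().predict(np.ones((2, 1)))
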