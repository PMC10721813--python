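"""Lag embedding, activations, parameter accounting and the six learners."""

import math

import numpy as np
import pytest

from hybridts.nonlinear_learners import (
    CNNSpec,
    LSTMSpec,
    NLSVRSpec,
    RNNSpec,
    TDNNSpec,
    TrainingConfig,
    WNNSpec,
    count_parameters,
    embed_lags,
    fit_learner,
    fit_series_learner,
    grid_search,
    morlet,
    recursive_forecast,
    relu,
)
from hybridts._nets import LSTMNet


class TestEmbedLags:
    def test_small_example(self):
        emb = embed_lags([1.0, 2.0, 3.0, 4.0], 2)
        np.testing.assert_array_equal(emb.X, [[2.0, 1.0], [3.0, 2.0]])
        np.testing.assert_array_equal(emb.targets, [3.0, 4.0])

    def test_single_row_boundary(self):
        emb = embed_lags([1.0, 2.0, 3.0], 2)
        assert emb.X.shape == (1, 2)

    def test_targets_are_series_tail(self):
        s = np.arange(20.0)
        emb = embed_lags(s, 5)
        np.testing.assert_array_equal(emb.targets, s[5:])

    def test_p_too_large(self):
        with pytest.raises(ValueError):
            embed_lags([1.0, 2.0], 2)


class TestActivations:
    @pytest.mark.parametrize("y,expected", [(-2.0, 0.0), (3.0, 3.0), (0.0, 0.0)])
    def test_relu(self, y, expected):
        assert relu(y) == expected

    def test_morlet_values(self):
        assert morlet(0.0) == pytest.approx(1.0)
        assert morlet(math.pi / 10.0) == pytest.approx(0.0, abs=1e-12)
        # oracle: independent high-precision evaluation of exp(-1)*cos(5)
        assert morlet(1.0) == pytest.approx(math.exp(-1.0) * math.cos(5.0), abs=1e-12)
        assert morlet(1.0) == pytest.approx(0.10435, abs=5e-5)


class TestParameterCounts:
    # the full set of published architecture sizes, three series each for
    # level-series and residual-series variants
    @pytest.mark.parametrize(
        "spec,expected",
        [
            (TDNNSpec(3, 6), 31), (TDNNSpec(3, 7), 36), (TDNNSpec(4, 4), 25),
            (TDNNSpec(4, 1), 7), (TDNNSpec(1, 2), 7), (TDNNSpec(5, 1), 8),
            (WNNSpec(6, 9), 73), (WNNSpec(1, 10), 31), (WNNSpec(6, 2), 17),
            (WNNSpec(2, 4), 17), (WNNSpec(4, 9), 55), (WNNSpec(2, 6), 25),
            (CNNSpec(3, 6, 2, 2), 25), (CNNSpec(2, 8, 2, 1), 33),
            (CNNSpec(3, 7, 2, 2), 29), (CNNSpec(2, 6, 2, 1), 25),
            (CNNSpec(4, 3, 2, 3), 13), (CNNSpec(3, 4, 2, 2), 17),
            (RNNSpec(1, 10), 131), (RNNSpec(2, 5), 41), (RNNSpec(4, 7), 71),
            (RNNSpec(5, 2), 11), (RNNSpec(1, 6), 55), (RNNSpec(1, 1), 5),
            (LSTMSpec(5, 10), 491), (LSTMSpec(2, 7), 260), (LSTMSpec(4, 3), 64),
            (LSTMSpec(1, 1), 14), (LSTMSpec(1, 8), 329), (LSTMSpec(6, 10), 491),
            (TDNNSpec(1, 1), 4),
        ],
    )
    def test_published_counts(self, spec, expected):
        assert count_parameters(spec) == expected

    def test_count_matches_actual_weights(self):
        # the closed-form count equals the length of the flattened
        # parameter vector of the materialized network
        from hybridts.nonlinear_learners import _build_net

        for spec in (TDNNSpec(3, 6), WNNSpec(4, 9), CNNSpec(4, 3, 2, 3),
                     RNNSpec(2, 5), LSTMSpec(2, 7)):
            net = _build_net(spec)
            net._init(np.random.default_rng(0))
            assert net._get_theta().size == count_parameters(spec)

    def test_wnn_counts_like_tdnn(self):
        assert count_parameters(WNNSpec(4, 7)) == count_parameters(TDNNSpec(4, 7))

    def test_nlsvr_has_no_count(self):
        with pytest.raises(ValueError):
            count_parameters(NLSVRSpec(lags=2))


class TestFitLearner:
    def test_nlsvr_interpolates_with_large_C(self):
        s = np.linspace(0.0, 10.0, 21)  # y_t = y_{t-1} + 0.5, near-linear map
        spec = NLSVRSpec(lags=1, C=1e4, gamma=1.0, epsilon=1e-4)
        fitted = fit_series_learner(spec, s)
        emb = embed_lags(s, 1)
        pred = fitted.predict(emb.X)
        # epsilon-tube contract: within eps + small slack, original units
        assert np.max(np.abs(pred - emb.targets)) < (1e-4 * 10.0) + 0.01

    def test_lstm_all_zero_weights_outputs_zero(self):
        net = LSTMNet(p=3, n_hidden=4)
        net._init(np.random.default_rng(0))
        net._set_theta(np.zeros(net.n_params))
        X = np.random.default_rng(1).normal(size=(5, 3))
        np.testing.assert_allclose(net.predict(X), 0.0, atol=1e-15)

    def test_tdnn_capacity_on_noiseless_ar(self):
        series = 10.0 * 0.8 ** np.arange(40)
        fitted = fit_series_learner(TDNNSpec(lags=1, hidden=3), series,
                                    TrainingConfig(seed=0, epochs=300))
        emb = embed_lags(series, 1)
        rmse = float(np.sqrt(np.mean((fitted.predict(emb.X) - emb.targets) ** 2)))
        assert rmse < 0.01 * np.std(series)

    def test_seeded_reproducibility_bitwise(self):
        rng = np.random.default_rng(4)
        s = np.cumsum(rng.normal(size=50)) + 20
        cfg = TrainingConfig(seed=7, epochs=50)
        a = fit_series_learner(RNNSpec(lags=2, hidden=3), s, cfg)
        b = fit_series_learner(RNNSpec(lags=2, hidden=3), s, cfg)
        emb = embed_lags(s, 2)
        np.testing.assert_array_equal(a.predict(emb.X), b.predict(emb.X))

    def test_shift_invariance_of_scaled_losses(self):
        # min-max scaling makes training invariant to a +1000 level shift
        rng = np.random.default_rng(5)
        s = np.cumsum(rng.normal(size=50)) + 20
        cfg = TrainingConfig(seed=3, epochs=40)
        a = fit_series_learner(TDNNSpec(lags=2, hidden=3), s, cfg)
        b = fit_series_learner(TDNNSpec(lags=2, hidden=3), s + 1000.0, cfg)
        np.testing.assert_allclose(a.loss_history, b.loss_history, rtol=0, atol=1e-12)

    def test_constant_series_degenerate_scaler(self):
        with pytest.raises(ValueError, match="scaler"):
            fit_series_learner(TDNNSpec(lags=1, hidden=1), np.ones(20))

    def test_spec_embedding_lag_mismatch(self):
        emb = embed_lags(np.arange(20.0), 3)
        with pytest.raises(ValueError, match="lags"):
            fit_learner(TDNNSpec(lags=2, hidden=2), emb)


class _EchoModel:
    """Stub: prediction equals the most recent lag (first input column)."""

    def predict(self, X):
        return X[:, 0]


class _LinearModel:
    def __init__(self, w, b):
        self.w, self.b = np.asarray(w), b

    def predict(self, X):
        return X @ self.w + self.b


class TestRecursiveForecast:
    def _wrap(self, model, p, lo=0.0, hi=1.0):
        from hybridts.nonlinear_learners import FittedLearner, _MinMaxScaler

        return FittedLearner(spec=TDNNSpec(lags=p, hidden=1),
                             scaler=_MinMaxScaler(lo=lo, hi=hi),
                             model=model, config=None)

    def test_echo_learner_constant_forecast(self):
        fitted = self._wrap(_EchoModel(), p=2, lo=0.0, hi=10.0)
        fc = recursive_forecast(fitted, [3.0, 7.0], 5)
        np.testing.assert_allclose(fc, 7.0)

    def test_h1_equals_single_predict(self):
        fitted = self._wrap(_LinearModel([0.5, 0.2], 0.1), p=2, lo=0.0, hi=10.0)
        fc = recursive_forecast(fitted, [2.0, 4.0], 1)
        one = fitted.predict(np.array([[4.0, 2.0]]))[0]
        assert fc[0] == pytest.approx(one)

    def test_matches_hand_recursion(self):
        w, b, lo, hi = np.array([0.6, -0.3]), 0.05, 0.0, 10.0
        fitted = self._wrap(_LinearModel(w, b), p=2, lo=lo, hi=hi)
        hist = [2.0, 4.0]
        fc = recursive_forecast(fitted, hist, 6)
        buf = list(hist)
        for step in range(6):
            row = np.array([buf[-1], buf[-2]])
            scaled = (row - lo) / (hi - lo)
            pred = (scaled @ w + b) * (hi - lo) + lo
            buf.append(pred)
        np.testing.assert_allclose(fc, buf[2:], rtol=0, atol=1e-10)

    def test_history_length_enforced(self):
        fitted = self._wrap(_EchoModel(), p=3)
        with pytest.raises(ValueError):
            recursive_forecast(fitted, [1.0, 2.0], 3)


class TestGridSearch:
    def test_single_cell(self):
        rng = np.random.default_rng(0)
        s = np.cumsum(rng.normal(size=60)) + 10
        res = grid_search(lambda p, q: NLSVRSpec(lags=p),
                          s[:-6], s[-6:], lags_range=[2], hidden_range=[1])
        assert res.best.lags == 2
        assert len(res.scores) == 1

    def test_score_table_covers_grid(self):
        rng = np.random.default_rng(1)
        s = np.cumsum(rng.normal(size=60)) + 10
        res = grid_search(lambda p, q: NLSVRSpec(lags=p, C=float(q)),
                          s[:-6], s[-6:], lags_range=[1, 2], hidden_range=[1, 2, 3])
        assert len(res.scores) == 6

    def test_oscillatory_ar2_needs_two_lags(self):
        # an AR(2) with complex roots cannot be forecast from one lag
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(500 + s)
            z = np.zeros(440)
            e = rng.normal(size=440)
            for i in range(2, 440):
                z[i] = 1.4 * z[i - 1] - 0.8 * z[i - 2] + e[i]
            z = z[40:]
            res = grid_search(
                lambda p, q: NLSVRSpec(lags=p, C=10.0, gamma=0.5, epsilon=0.05),
                z[:-6], z[-6:], lags_range=range(1, 4), hidden_range=[1],
            )
            hits += res.best.lags >= 2
        assert hits >= 16  # >= 80% of the seeded replicates
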