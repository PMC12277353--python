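import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from kalium.chemometrics import (
    bandwise_correlation,
    correlation_surface,
    extract_latents_by_variance,
    fit_plsr,
    select_components_cv,
)
from kalium.errors import AlignmentError, DegenerateTargetError, RankError
from kalium.fractional_diff import sweep_orders


def pearson_two_pass(x, y):
    """Direct two-pass Pearson formula, used as the oracle."""
    mx, my = np.mean(x), np.mean(y)
    num = np.sum((x - mx) * (y - my))
    den = np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
    return num / den


class TestBandwiseCorrelation:
    def test_identical_band(self):
        y = np.array([1.0, 2.0, 3.0, 5.0])
        X = np.column_stack([y, np.ones(4)])
        r = bandwise_correlation(X, y)
        assert r[0] == pytest.approx(1.0)

    def test_affine_anticorrelation(self):
        y = np.array([1.0, 2.0, 3.0, 5.0])
        X = (-2 * y + 5)[:, None]
        assert bandwise_correlation(X, y)[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([2.0, 2.0, 4.0])
        r = bandwise_correlation(X, y)[0]
        assert r == pytest.approx(np.sqrt(3) / 2)  # 0.8660...
        assert r == pytest.approx(0.866, abs=5e-4)

    def test_matches_two_pass_oracle(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        r = bandwise_correlation(X, y)
        for j in range(8):
            assert abs(r[j] - pearson_two_pass(X[:, j], y)) < 1e-12

    def test_zero_variance_band_is_nan(self, rng):
        X = np.column_stack([np.full(10, 0.3), rng.normal(size=10)])
        r = bandwise_correlation(X, rng.normal(size=10))
        assert np.isnan(r[0]) and np.isfinite(r[1])

    def test_constant_target_rejected(self, rng):
        with pytest.raises(DegenerateTargetError):
            bandwise_correlation(rng.normal(size=(10, 3)), np.full(10, 2.0))


class TestCorrelationSurface:
    def test_single_order_consistency(self, small_set):
        sw = sweep_orders(small_set, [0.0])
        surf = correlation_surface(sw)
        direct = np.abs(
            bandwise_correlation(small_set.reflectance, small_set.potassium)
        )
        assert surf.abs_r[0] == pytest.approx(direct, nan_ok=True)

    def test_values_in_unit_interval(self, small_set):
        surf = correlation_surface(sweep_orders(small_set, [0.0, 0.5, 1.0]))
        finite = surf.abs_r[np.isfinite(surf.abs_r)]
        assert np.all((finite >= 0) & (finite <= 1))

    def test_per_order_max_consistent(self, small_set):
        surf = correlation_surface(sweep_orders(small_set, [0.0, 1.5]))
        assert surf.per_order_max == pytest.approx(np.nanmax(surf.abs_r, axis=1))

    def test_mismatched_sets_rejected(self, small_set):
        sw = dict(sweep_orders(small_set, [0.0, 1.0]))
        sw[1.0] = sw[1.0].subset(range(10))
        with pytest.raises(AlignmentError):
            correlation_surface(sw)


class TestFitPLSR:
    def test_first_direction_proportional_to_xty(self, rng):
        X = rng.normal(size=(50, 10))
        y = rng.normal(size=50)
        model = fit_plsr(X, y, 1)
        xty = (X - X.mean(0)).T @ (y - y.mean())
        cos = xty @ model.x_weights[:, 0] / np.linalg.norm(xty)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_limit_matches_ols(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            X = rng.normal(size=(20, 5))
            y = rng.normal(size=20)
            model = fit_plsr(X, y, 5)
            Xc = X - X.mean(0)
            beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
            ols_pred = y.mean() + Xc @ beta
            assert np.max(np.abs(model.predict(X) - ols_pred)) < 1e-8

    def test_noiseless_linear_r2_one(self, rng):
        X = rng.normal(size=(40, 6))
        beta = rng.normal(size=6)
        y = X @ beta + 2.0
        model = fit_plsr(X, y, 6)
        resid = y - model.predict(X)
        assert np.sum(resid ** 2) < 1e-16 * np.sum((y - y.mean()) ** 2)

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(60, 20))
        y = rng.normal(size=60)
        model = fit_plsr(X, y, 10)
        G = model.x_scores.T @ model.x_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) <= 1e-8 * np.max(np.diag(G))

    def test_projection_reproduces_training_scores(self, rng):
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        model = fit_plsr(X, y, 5)
        T = model.transform(X)
        assert np.max(np.abs(T - model.x_scores)) < 1e-10

    def test_cum_variance_monotone_bounded(self, rng):
        X = rng.normal(size=(40, 15))
        model = fit_plsr(X, rng.normal(size=40), 8)
        cv = model.cum_x_variance
        assert np.all(np.diff(cv) >= -1e-12) and cv[-1] <= 1 + 1e-12

    def test_matches_sklearn_predictions(self, rng):
        """Independent cross-check against an established PLS implementation."""
        X = rng.normal(size=(50, 20))
        y = X @ rng.normal(size=20) + rng.normal(size=50)
        ours = fit_plsr(X, y, 4)
        ref = PLSRegression(n_components=4, scale=False).fit(X, y)
        assert ours.predict(X) == pytest.approx(
            ref.predict(X).ravel(), abs=1e-8
        )

    def test_rank_error(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(RankError):
            fit_plsr(X, rng.normal(size=10), 5)

    def test_serialization_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(25, 9))
        y = rng.normal(size=25)
        model = fit_plsr(X, y, 3)
        path = tmp_path / "plsr.json"
        model.to_json(path)
        back = type(model).from_json(path)
        Xnew = rng.normal(size=(5, 9))
        assert back.predict(Xnew) == pytest.approx(model.predict(Xnew), abs=1e-12)


class TestSelectComponentsCV:
    def test_single_dominant_direction_selects_one(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=(80, 1))
        P = rng.normal(size=(1, 12))
        X = t @ P
        y = 2.5 * t[:, 0]
        assert select_components_cv(X, y, max_components=5, folds=5, seed=0) == 1

    def test_max_components_one(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        assert select_components_cv(X, y, max_components=1, folds=5) == 1

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 10))
        y = X @ rng.normal(size=10) + 0.5 * rng.normal(size=60)
        a = select_components_cv(X, y, 8, folds=10, seed=42)
        b = select_components_cv(X, y, 8, folds=10, seed=42)
        assert a == b

    def test_range_defaults(self, rng):
        import inspect

        sig = inspect.signature(select_components_cv)
        assert sig.parameters["max_components"].default == 20
        assert sig.parameters["folds"].default == 10


class TestExtractLatentsByVariance:
    def test_dominant_direction_stops_at_one(self):
        rng = np.random.default_rng(11)
        t = rng.normal(size=(100, 1)) * 10.0
        noise_dirs = rng.normal(size=(100, 5)) * 0.5
        X = np.column_stack([t + 0.01 * rng.normal(size=(100, 1)), noise_dirs])
        # rotate the dominant direction across columns
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        X = X @ Q
        y = t[:, 0] + 0.01 * rng.normal(size=100)
        scores, model = extract_latents_by_variance(X, y, threshold=0.75)
        assert model.cum_x_variance[0] >= 0.75
        assert model.n_components == 1
        assert scores.shape == (100, 1)

    def test_tiny_threshold_floors_at_one(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        _, model = extract_latents_by_variance(X, y, threshold=1e-9)
        assert model.n_components == 1

    def test_default_threshold(self):
        import inspect

        sig = inspect.signature(extract_latents_by_variance)
        assert sig.parameters["threshold"].default == 0.75

    def test_unreachable_threshold_warns_and_caps(self, rng):
        X = rng.normal(size=(20, 50))
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="below"):
            _, model = extract_latents_by_variance(X, y, threshold=0.999, cap=3)
        assert model.n_components == 3
        assert not model.threshold_reached

    def test_projection_consistency(self, rng):
        X = rng.normal(size=(40, 12))
        y = X @ rng.normal(size=12)
        scores, model = extract_latents_by_variance(X, y, threshold=0.6)
        assert np.max(np.abs(model.transform(X) - scores)) < 1e-10
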