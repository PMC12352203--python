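import numpy as np
import pytest

from disomap import correlation as corr

from conftest import make_track


# ----------------------------------------------------------------- moving mean

def test_moving_mean_constant_track_unchanged():
    track = make_track([0.3] * 50)
    assert np.allclose(corr.moving_mean(track, 10).values, 0.3)


def test_moving_mean_even_window_hand_case():
    # window 2 covers offsets {0, +1}: means of (1,2), (2,3), (3,4), (4)
    got = corr.moving_mean(make_track([1, 2, 3, 4]), 2).values
    assert np.allclose(got, [1.5, 2.5, 3.5, 4.0])


def test_moving_mean_odd_window_hand_case():
    got = corr.moving_mean(make_track([1, 2, 3, 4]), 3).values
    assert np.allclose(got, [1.5, 2.0, 3.0, 3.5])


def moving_mean_oracle(values, window):
    lo_off = -((window + 1) // 2 - 1)
    hi_off = window // 2
    out = []
    for i in range(len(values)):
        acc, n = 0.0, 0
        for j in range(i + lo_off, i + hi_off + 1):
            if 0 <= j < len(values) and not np.isnan(values[j]):
                acc += values[j]
                n += 1
        out.append(acc / n if n else np.nan)
    return np.array(out)


def test_moving_mean_matches_windowed_oracle(rng):
    values = rng.uniform(0, 1, 137)
    values[rng.integers(0, 137, 6)] = np.nan
    for window in (1, 2, 5, 10):
        got = corr.moving_mean(make_track(values), window).values
        expected = moving_mean_oracle(values, window)
        assert np.allclose(got, expected, equal_nan=True)


def test_moving_mean_nearly_preserves_global_mean(rng):
    values = rng.uniform(0, 1, 543)
    smoothed = corr.moving_mean(make_track(values), 10).values
    assert abs(smoothed.mean() - values.mean()) < 10 / 543


def test_moving_mean_window_bounds():
    with pytest.raises(ValueError):
        corr.moving_mean(make_track([1, 2]), 3)
    with pytest.raises(ValueError):
        corr.moving_mean(make_track([1, 2]), 0)


# ------------------------------------------------------------------ R squared

def test_r_squared_hand_cases():
    y = np.array([1.0, 2.0, 3.0])
    assert corr.r_squared(y, y) == pytest.approx(1.0)
    assert corr.r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
    assert corr.r_squared(y, np.array([1.0, 2.0, 2.0])) == pytest.approx(0.5)


def test_r_squared_errors():
    with pytest.raises(ValueError):
        corr.r_squared(np.ones(3), np.ones(3))  # zero total variance
    with pytest.raises(ValueError):
        corr.r_squared(np.array([1.0]), np.array([1.0]))


def test_r_squared_at_most_one_and_one_iff_exact(rng):
    y = rng.uniform(0, 1, 50)
    for _ in range(20):
        y_hat = y + rng.normal(0, 0.1, 50)
        value = corr.r_squared(y, y_hat)
        assert value <= 1.0
        assert (value == 1.0) == bool(np.all(y_hat == y))


# ----------------------------------------------------------------- exponential

def test_noiseless_recovery_single_case():
    x = np.linspace(0, 1, 100)
    y = 0.8 * np.exp(-3.0 * x) + 0.1
    fit = corr.fit_exponential_decay(x, y)
    assert fit.converged
    assert fit.a == pytest.approx(0.8, abs=1e-6)
    assert fit.b == pytest.approx(3.0, abs=1e-6)
    assert fit.c == pytest.approx(0.1, abs=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_constant_response_degenerates_gracefully():
    x = np.linspace(0, 1, 20)
    fit = corr.fit_exponential_decay(x, np.full(20, 0.5))
    assert (fit.a, fit.b, fit.c) == (0.0, 0.0, 0.5)
    assert fit.r_squared == 0.0


def test_two_parameter_form():
    x = np.linspace(0, 1, 60)
    y = 0.7 * np.exp(-2.0 * x)
    fit = corr.fit_exponential_decay(x, y, with_offset=False)
    assert fit.c == 0.0
    assert fit.a == pytest.approx(0.7, abs=1e-6)
    assert fit.b == pytest.approx(2.0, abs=1e-6)


def test_fit_is_deterministic(rng):
    x = rng.uniform(0, 1, 200)
    y = 0.5 * np.exp(-4 * x) + 0.2 + rng.normal(0, 0.05, 200)
    fit1 = corr.fit_exponential_decay(x, y)
    fit2 = corr.fit_exponential_decay(x, y)
    assert fit1 == fit2


def test_fit_ignores_missing_pairs(rng):
    x = np.linspace(0, 1, 50)
    y = 0.6 * np.exp(-3 * x) + 0.1
    x2, y2 = x.copy(), y.copy()
    x2[5] = np.nan
    y2[10] = np.nan
    fit = corr.fit_exponential_decay(x2, y2)
    assert fit.n == 48
    assert fit.b == pytest.approx(3.0, abs=1e-6)
    with pytest.raises(ValueError):
        corr.fit_exponential_decay(np.array([0.1, 0.2]), np.array([1.0, 2.0]))


def test_noisy_fit_approaches_analytic_noise_limit(rng):
    # mean R^2 over seeds should sit near Var(signal)/(Var(signal)+sigma^2)
    x = rng.uniform(0, 1, 543)
    signal = 0.6 * np.exp(-4.0 * x) + 0.2
    sigma = 0.05
    r2s, biases = [], []
    for _ in range(30):
        y = signal + rng.normal(0, sigma, x.size)
        fit = corr.fit_exponential_decay(x, y)
        r2s.append(fit.r_squared)
        biases.append(fit.b - 4.0)
    expected = signal.var() / (signal.var() + sigma ** 2)
    assert np.mean(r2s) == pytest.approx(expected, abs=0.05)
    assert abs(np.mean(biases)) < 0.1


# --------------------------------------------------------------- orchestration

def test_correlate_pairs_smoothed_y_with_raw_x(rng):
    x = rng.uniform(0, 1, 200)
    y = 0.6 * np.exp(-4 * x) + 0.2
    mdp = make_track(x, name="MDP")
    path_mean = make_track(y, name="mean_pathogenicity")
    fit, paired = corr.correlate_disorder_pathogenicity(mdp, path_mean,
                                                        window=1)
    assert fit.b == pytest.approx(4.0, abs=1e-6)
    assert list(paired.columns) == ["res_index", "mdp", "path_mean",
                                    "path_smoothed", "class"]
    assert np.allclose(paired["mdp"], x)          # x enters unsmoothed
    assert np.allclose(paired["path_smoothed"], y)


def test_correlate_joint_shuffle_invariance_at_window_one(rng):
    x = rng.uniform(0, 1, 150)
    y = 0.5 * np.exp(-3 * x) + 0.1 + rng.normal(0, 0.02, 150)
    perm = rng.permutation(150)
    fit1, _ = corr.correlate_disorder_pathogenicity(
        make_track(x), make_track(y), window=1)
    fit2, _ = corr.correlate_disorder_pathogenicity(
        make_track(x[perm]), make_track(y[perm]), window=1)
    assert fit1.b == pytest.approx(fit2.b, rel=1e-6)
    assert fit1.r_squared == pytest.approx(fit2.r_squared, rel=1e-9)


def test_correlate_constant_pathogenicity_degenerates(rng):
    mdp = make_track(rng.uniform(0, 1, 60), name="MDP")
    flat = make_track(np.full(60, 0.4), name="mean_pathogenicity")
    fit, _ = corr.correlate_disorder_pathogenicity(mdp, flat)
    assert fit.a == 0.0 and fit.b == 0.0 and fit.r_squared == 0.0
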