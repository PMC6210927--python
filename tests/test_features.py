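"""Window geometry and the per-window feature definitions.

Every feature is checked against an independently coded brute-force loop on
random windows, plus its hand-computable special cases and the gain/shift
invariance properties.
"""

import math

import numpy as np
import pytest

import tugsense as ts
from tugsense.features import (
    FeatureSpec,
    WindowSpec,
    extract_features,
    feature_autocorrelation,
    feature_correlation,
    feature_mean,
    feature_pitch,
    feature_rms,
    feature_sd,
    feature_signal_energy,
    feature_sma,
    feature_spectral_entropy,
    feature_svm,
    make_windows,
)
from tugsense.recording import ImuRecording

# ---------------------------------------------------------------------------
# independent brute-force oracles (plain Python loops, math.fsum)
# ---------------------------------------------------------------------------


def bf_mean(x):
    return math.fsum(x) / len(x)


def bf_sd(x):
    m = bf_mean(x)
    return math.sqrt(math.fsum((v - m) ** 2 for v in x) / len(x))


def bf_rms(x):
    return math.sqrt(math.fsum(v * v for v in x) / len(x))


def bf_energy(x):
    return math.fsum(v * v for v in x)


def bf_sma(block):
    return math.fsum(abs(v) + abs(ml) + abs(ap) for v, ml, ap in block) / len(block)


def bf_svm(block):
    return math.fsum(math.sqrt(v * v + ml * ml + ap * ap) for v, ml, ap in block) / len(block)


def bf_autocorr(x, lag):
    n = len(x)
    m = bf_mean(x)
    var = math.fsum((v - m) ** 2 for v in x) / n
    if var == 0 or lag >= n:
        return 1.0 if (lag == 0 and var > 0) else 0.0
    if lag == 0:
        return 1.0
    num = math.fsum((x[i] - m) * (x[i + lag] - m) for i in range(n - lag)) / (n - lag)
    return num / var


def bf_corr(a, b):
    ma, mb = bf_mean(a), bf_mean(b)
    sa = math.sqrt(math.fsum((v - ma) ** 2 for v in a))
    sb = math.sqrt(math.fsum((v - mb) ** 2 for v in b))
    if sa == 0 or sb == 0:
        return 0.0
    return math.fsum((a[i] - ma) * (b[i] - mb) for i in range(len(a))) / (sa * sb)


def bf_pitch(block):
    v = bf_mean([r[0] for r in block])
    ml = bf_mean([r[1] for r in block])
    ap = bf_mean([r[2] for r in block])
    return math.degrees(math.atan2(ap, math.hypot(v, ml)))


def bf_spectral_entropy(x):
    n = len(x)
    power = []
    for k in range(1, n // 2 + 1):
        re = math.fsum(x[i] * math.cos(-2 * math.pi * k * i / n) for i in range(n))
        im = math.fsum(x[i] * math.sin(-2 * math.pi * k * i / n) for i in range(n))
        power.append(re * re + im * im)
    tot = math.fsum(power)
    if tot <= 0 or len(power) < 2:
        return 0.0
    h = -math.fsum(p / tot * math.log(p / tot) for p in power if p > 0)
    return h / math.log(len(power))


class TestWindowGeometry:
    @pytest.mark.parametrize(
        "size_s,step_s,win,hop",
        [(1.405, 0.072, 141, 7), (2.511, 0.427, 251, 43), (1.853, 0.249, 185, 25), (1.135, 0.073, 114, 7)],
    )
    def test_sample_counts_round_half_up(self, size_s, step_s, win, hop):
        spec = WindowSpec(size_s, step_s)
        assert spec.size_samples(100.0) == win
        assert spec.hop_samples(100.0) == hop

    def test_window_count_arithmetic(self, rng):
        rec = ImuRecording(
            np.arange(1000) / 100, rng.normal(size=(1000, 3)), rng.normal(size=(1000, 3)), 100.0
        )
        assert len(make_windows(rec, WindowSpec(2.0, 1.0))) == 9

    def test_whole_recording_is_one_window(self, rng):
        rec = ImuRecording(
            np.arange(300) / 100, rng.normal(size=(300, 3)), rng.normal(size=(300, 3)), 100.0
        )
        assert len(make_windows(rec, WindowSpec(3.0, 3.0))) == 1

    def test_too_short_recording_warns_and_is_empty(self, rng):
        rec = ImuRecording(
            np.arange(50) / 100, rng.normal(size=(50, 3)), rng.normal(size=(50, 3)), 100.0
        )
        with pytest.warns(UserWarning, match="shorter"):
            wins = make_windows(rec, WindowSpec(1.0, 0.5))
        assert len(wins) == 0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(1.0, 1.5)


class TestScalarFeatures:
    def test_hand_arithmetic_examples(self):
        x = [1.0, 2.0, 2.0, 1.0]
        assert feature_mean(x) == pytest.approx(1.5)
        assert feature_rms(x) == pytest.approx(math.sqrt(2.5))
        assert feature_signal_energy(x) == pytest.approx(10.0)
        assert feature_sd([3.0] * 7) == 0.0
        assert feature_rms([-3.0] * 7) == pytest.approx(3.0)

    def test_sma_svm_constants(self):
        zeros = np.zeros((10, 3))
        assert feature_sma(zeros) == 0.0
        assert feature_svm(zeros) == 0.0
        assert feature_sma(np.ones((10, 3))) == pytest.approx(3.0)
        assert feature_svm(np.tile([3.0, 4.0, 0.0], (10, 1))) == pytest.approx(5.0)

    def test_autocorrelation_definition_cases(self, rng):
        x = rng.normal(size=64)
        assert feature_autocorrelation(x, 0) == 1.0
        assert feature_autocorrelation(np.ones(64), 0) == 0.0  # zero variance
        p = 25
        sin = np.sin(2 * np.pi * np.arange(500) / p)
        assert feature_autocorrelation(sin, p) == pytest.approx(1.0, abs=0.01)

    def test_correlation_affine_and_degenerate(self, rng):
        a = rng.normal(size=80)
        assert feature_correlation(a, 2 * a + 1) == pytest.approx(1.0)
        assert feature_correlation(a, -a) == pytest.approx(-1.0)
        assert feature_correlation(a, np.zeros(80)) == 0.0

    def test_pitch_of_constructed_rotations(self):
        g = 9.81
        upright = np.tile([g, 0, 0], (20, 1))
        flat = np.tile([0, 0, g], (20, 1))
        tilted = np.tile([g / math.sqrt(2), 0, g / math.sqrt(2)], (20, 1))
        assert feature_pitch(upright) == pytest.approx(0.0)
        assert feature_pitch(flat) == pytest.approx(90.0)
        assert feature_pitch(tilted) == pytest.approx(45.0, abs=1e-9)

    def test_spectral_entropy_extremes(self, rng):
        n = 256
        t = np.arange(n)
        sine = np.sin(2 * np.pi * 8 * t / n)  # exactly bin 8
        assert feature_spectral_entropy(sine) < 0.2
        assert feature_spectral_entropy(rng.normal(size=n)) > 0.8
        assert feature_spectral_entropy(np.zeros(n)) == 0.0
        assert feature_spectral_entropy(np.full(n, 3.3)) == 0.0

    def test_empty_block_is_an_error(self):
        with pytest.raises(ValueError):
            feature_mean([])


@pytest.mark.parametrize(
    "func,oracle",
    [
        (feature_mean, bf_mean),
        (feature_sd, bf_sd),
        (feature_rms, bf_rms),
        (feature_signal_energy, bf_energy),
    ],
)
def test_channel_features_match_brute_force(rng, func, oracle):
    for _ in range(50):
        x = rng.normal(0, rng.uniform(0.1, 10), size=rng.integers(5, 200))
        assert func(x) == pytest.approx(oracle(list(x)), rel=1e-12, abs=1e-12)


def test_block_features_match_brute_force(rng):
    for _ in range(50):
        block = rng.normal(0, 3, size=(int(rng.integers(5, 100)), 3))
        rows = [list(r) for r in block]
        assert feature_sma(block) == pytest.approx(bf_sma(rows), rel=1e-12)
        assert feature_svm(block) == pytest.approx(bf_svm(rows), rel=1e-12)
        assert feature_pitch(block) == pytest.approx(bf_pitch(rows), rel=1e-9, abs=1e-9)


def test_lagged_and_paired_features_match_brute_force(rng):
    for _ in range(50):
        n = int(rng.integers(10, 150))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        lag = int(rng.integers(0, n))
        assert feature_autocorrelation(x, lag) == pytest.approx(bf_autocorr(list(x), lag), rel=1e-10, abs=1e-12)
        assert feature_correlation(x, y) == pytest.approx(bf_corr(list(x), list(y)), rel=1e-10, abs=1e-12)


def test_spectral_entropy_matches_dft_oracle(rng):
    for _ in range(10):
        x = rng.normal(size=int(rng.integers(16, 64)))
        assert feature_spectral_entropy(x) == pytest.approx(
            bf_spectral_entropy(list(x)), rel=1e-9, abs=1e-9
        )


class TestExtraction:
    def _recording(self, rng, n=600, sr=100.0):
        return ImuRecording(
            np.arange(n) / sr,
            rng.normal(0, 1, (n, 3)) + [9.81, 0, 0],
            rng.normal(0, 5, (n, 3)),
            sr,
        )

    def test_columns_stable_and_finite(self, rng):
        cfg = ts.default_configs()["state"]
        rec = self._recording(rng)
        fm1 = extract_features(rec, cfg.window, cfg.features)
        fm2 = extract_features(rec, cfg.window, cfg.features)
        assert fm1.columns == fm2.columns
        assert len(fm1.columns) == 42  # 6 AC + 15 C + 3 mean + 6 RMS + 6 SD + 6 energy
        assert np.all(np.isfinite(fm1.values))
        np.testing.assert_array_equal(fm1.values, fm2.values)

    def test_constant_recording_gives_identical_finite_rows(self):
        n = 400
        rec = ImuRecording(
            np.arange(n) / 100, np.tile([9.81, 0.0, 1.0], (n, 1)), np.zeros((n, 3)), 100.0
        )
        cfg = ts.default_configs()["static"]
        fm = extract_features(rec, cfg.window, cfg.features)
        assert np.all(np.isfinite(fm.values))
        assert np.allclose(fm.values, fm.values[0], atol=1e-12)

    def test_extraction_composes_from_scalar_features(self, rng):
        """Each emitted column equals the single-feature operation applied to
        that window's raw block (compositional oracle)."""
        rec = self._recording(rng)
        window = WindowSpec(1.0, 0.25)
        feats = (
            FeatureSpec("mean", "acc"),
            FeatureSpec("autocorrelation", "gyro"),
            FeatureSpec("correlation", "acc"),
            FeatureSpec("sma", "acc+gyro"),
            FeatureSpec("pitch", "acc"),
            FeatureSpec("spectral_entropy", "acc"),
        )
        fm = extract_features(rec, window, feats, autocorr_lag_s=0.5)
        wins = make_windows(rec, window)
        lag = 50
        for w in (0, 3, len(wins) - 1):
            block = wins.blocks[w]
            expected = (
                [feature_mean(block[:, j]) for j in range(3)]
                + [feature_autocorrelation(block[:, 3 + j], lag) for j in range(3)]
                + [
                    feature_correlation(block[:, i], block[:, j])
                    for i in range(3)
                    for j in range(i + 1, 3)
                ]
                + [feature_sma(block[:, :3]), feature_sma(block[:, 3:])]
                + [feature_pitch(block[:, :3])]
                + [feature_spectral_entropy(block[:, j]) for j in range(3)]
            )
            np.testing.assert_allclose(fm.values[w], expected, rtol=1e-10, atol=1e-12)

    def test_unknown_feature_name_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            FeatureSpec("kurtosis", "acc")


class TestInvarianceProperties:
    def test_gain_equivariance_and_invariance(self, rng):
        x = rng.normal(0, 2, size=128)
        g = 3.7
        assert feature_mean(g * x) == pytest.approx(g * feature_mean(x), rel=1e-10)
        assert feature_sd(g * x) == pytest.approx(g * feature_sd(x), rel=1e-10)
        assert feature_rms(g * x) == pytest.approx(g * feature_rms(x), rel=1e-10)
        y = rng.normal(size=128)
        assert feature_correlation(g * x, y) == pytest.approx(feature_correlation(x, y), rel=1e-10)
        assert feature_autocorrelation(g * x, 10) == pytest.approx(
            feature_autocorrelation(x, 10), rel=1e-10
        )
        assert feature_spectral_entropy(g * x) == pytest.approx(
            feature_spectral_entropy(x), rel=1e-10
        )
        block = rng.normal(size=(64, 3)) + [9.81, 0, 2]
        assert feature_pitch(g * block) == pytest.approx(feature_pitch(block), rel=1e-10)

    def test_time_shift_by_whole_hops_shifts_rows(self, rng):
        n, sr = 800, 100.0
        window = WindowSpec(1.0, 0.25)
        hop = window.hop_samples(sr)
        x = rng.normal(0, 1, (n, 6))
        rec1 = ImuRecording(np.arange(n) / sr, x[:, :3], x[:, 3:], sr)
        k = 3
        shifted = x[k * hop :]
        rec2 = ImuRecording(
            np.arange(shifted.shape[0]) / sr, shifted[:, :3], shifted[:, 3:], sr
        )
        feats = (FeatureSpec("rms", "acc+gyro"), FeatureSpec("correlation", "acc"))
        fm1 = extract_features(rec1, window, feats)
        fm2 = extract_features(rec2, window, feats)
        np.testing.assert_allclose(fm2.values, fm1.values[k:], atol=1e-10)
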