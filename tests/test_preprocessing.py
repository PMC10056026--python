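import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from semgrej.preprocessing import (
    AnalysisWindow,
    PreprocessingError,
    encode_feature_images,
    feature_row,
    fit_activity_threshold,
    is_active,
    load_images,
    mav,
    rms,
    save_images,
    segment_windows,
    window_counts,
    wl,
)
from semgrej.synthetic import (
    TARGET,
    EmgRecording,
    MovementSpec,
    SimulationConfig,
    Trial,
    generate_recording,
)

finite_vectors = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=2, max_size=64
)


class TestTimeDomainFeatures:
    def test_worked_example(self):
        x = [3.0, 4.0]
        assert rms(x) == pytest.approx(np.sqrt(25 / 2))
        assert mav(x) == pytest.approx(3.5)
        assert wl(x) == pytest.approx(1.0)

    @pytest.mark.parametrize("c", [0.0, 2.5, -3.0])
    def test_constant_signal(self, c):
        x = np.full(10, c)
        assert rms(x) == pytest.approx(abs(c))
        assert mav(x) == pytest.approx(abs(c))
        assert wl(x) == 0.0

    def test_sign_symmetry(self):
        assert mav([1.0, -1.0]) == pytest.approx(1.0)
        assert wl([1.0, -1.0]) == pytest.approx(2.0)

    def test_too_short_inputs(self):
        with pytest.raises(PreprocessingError):
            rms([])
        with pytest.raises(PreprocessingError):
            wl([1.0])

    @given(finite_vectors)
    def test_oracle_direct_formulas(self, xs):
        """RMS/MAV/WL match naive elementwise evaluation of their definitions."""
        n = len(xs)
        assert rms(xs) == pytest.approx(
            (sum(v * v for v in xs) / n) ** 0.5, rel=1e-12, abs=1e-12
        )
        assert mav(xs) == pytest.approx(sum(abs(v) for v in xs) / n, rel=1e-12, abs=1e-12)
        assert wl(xs) == pytest.approx(
            sum(abs(b - a) for a, b in zip(xs, xs[1:])), rel=1e-12, abs=1e-9
        )

    @given(finite_vectors, st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_scaling_equivariance(self, xs, k):
        x = np.asarray(xs)
        assert rms(k * x) == pytest.approx(k * rms(x), rel=1e-9, abs=1e-9)
        assert mav(k * x) == pytest.approx(k * mav(x), rel=1e-9, abs=1e-9)
        assert wl(k * x) == pytest.approx(k * wl(x), rel=1e-9, abs=1e-6)


class TestActivityThreshold:
    def test_rectified_pair(self):
        # |{-1, 1}| = {1, 1}: mean 1, population sd 0, threshold 1
        th = fit_activity_threshold([-1.0, 1.0])
        assert th.mu_neutral == pytest.approx(1.0)
        assert th.sigma_neutral == pytest.approx(0.0)
        assert th.threshold == pytest.approx(1.0)

    def test_all_zero(self):
        assert fit_activity_threshold(np.zeros(100)).threshold == 0.0

    def test_mu_plus_three_sigma(self, rng):
        x = rng.normal(size=5000)
        th = fit_activity_threshold(x)
        r = np.abs(x)
        assert th.threshold == pytest.approx(r.mean() + 3 * r.std(ddof=0), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(PreprocessingError):
            fit_activity_threshold([])

    def test_strict_boundary(self):
        th = fit_activity_threshold([0.8, 0.8])  # mu=0.8, sigma=0 -> threshold 0.8
        at = AnalysisWindow(np.full((50, 8), 0.8), "A", TARGET, 0)
        above = AnalysisWindow(np.full((50, 8), 0.9), "A", TARGET, 0)
        zero = AnalysisWindow(np.zeros((50, 8)), "A", TARGET, 0)
        assert not is_active(at, th)  # boundary is inactive
        assert is_active(above, th)
        assert not is_active(zero, fit_activity_threshold([0.0, 0.0]))


def brute_force_window_count(n: int, length: int, step: int) -> int:
    count = 0
    start = 0
    while start + length <= n:
        count += 1
        start += step
    return count


class TestSegmentWindows:
    @pytest.mark.parametrize("n,expected", [(1000, 48), (50, 1), (49, 0)])
    def test_window_count_examples(self, n, expected):
        assert window_counts(n, 50, 20) == expected

    @given(
        st.integers(min_value=0, max_value=5000),
        st.integers(min_value=1, max_value=200),
        st.integers(min_value=1, max_value=200),
    )
    def test_count_formula_vs_enumeration(self, n, length, step):
        assert window_counts(n, length, step) == brute_force_window_count(n, length, step)

    def test_windows_stay_inside_trials(self):
        samples = np.arange(300 * 8, dtype=float).reshape(300, 8)
        rec = EmgRecording(
            samples=samples,
            sampling_rate=200.0,
            trials=[Trial(0, 130, "A", TARGET), Trial(130, 300, "B", TARGET)],
        )
        windows = segment_windows(rec, 250.0, 100.0)  # 50 / 20 samples
        for w in windows:
            first = w.samples[0, 0]
            trial = rec.trials[0] if w.label == "A" else rec.trials[1]
            row0 = int(first // 8)
            assert trial.start <= row0 and row0 + 50 <= trial.end

    def test_short_trial_yields_nothing(self):
        rec = EmgRecording(
            samples=np.zeros((40, 8)),
            sampling_rate=200.0,
            trials=[Trial(0, 40, "A", TARGET)],
        )
        assert segment_windows(rec, 250.0, 100.0) == []

    def test_non_integer_window_rejected(self):
        rec = EmgRecording(
            samples=np.zeros((100, 8)), sampling_rate=200.0, trials=[Trial(0, 100, "A", TARGET)]
        )
        with pytest.raises(PreprocessingError):
            segment_windows(rec, 251.3, 100.0)


def _windows(n, value=1.0, label="A", trial_id=0):
    return [
        AnalysisWindow(np.full((50, 8), value), label, TARGET, trial_id, active=True)
        for _ in range(n)
    ]


class TestFeatureImages:
    def test_exact_stack_gives_single_image(self):
        images = encode_feature_images(_windows(53), stack=53)
        assert len(images) == 1
        assert images[0].planes.shape == (3, 53, 8)
        assert images[0].pad_count == 0

    def test_stride_one_count(self):
        assert len(encode_feature_images(_windows(5), stack=2)) == 4

    def test_constant_signal_planes(self):
        img = encode_feature_images(_windows(53, value=-2.0), stack=53)[0]
        np.testing.assert_allclose(img.planes[0], 2.0)  # RMS == |c|
        np.testing.assert_allclose(img.planes[1], 2.0)  # MAV == |c|
        np.testing.assert_allclose(img.planes[2], 0.0)  # WL == 0

    def test_short_trial_pads_by_repeating_last_row(self):
        ws = _windows(3)
        ws[-1].samples[:] = 5.0
        img = encode_feature_images(ws, stack=6)[0]
        assert img.pad_count == 3
        np.testing.assert_allclose(img.planes[1, 2:, :], 5.0)  # rows 2..5 share last MAV

    def test_inactive_windows_excluded(self):
        ws = _windows(5)
        for w in ws[3:]:
            w.active = False
        assert len(encode_feature_images(ws, stack=3)) == 1

    def test_mixed_trials_rejected(self):
        ws = _windows(2) + _windows(2, label="B", trial_id=1)
        with pytest.raises(PreprocessingError, match="single trial"):
            encode_feature_images(ws, stack=2)

    def test_empty_input_empty_output(self):
        assert encode_feature_images([], stack=3) == []

    def test_feature_row_matches_scalar_features(self, rng):
        w = AnalysisWindow(rng.normal(size=(50, 8)), "A", TARGET, 0)
        row = feature_row(w)
        for ch in range(8):
            assert row[0, ch] == pytest.approx(rms(w.samples[:, ch]), rel=1e-12)
            assert row[1, ch] == pytest.approx(mav(w.samples[:, ch]), rel=1e-12)
            assert row[2, ch] == pytest.approx(wl(w.samples[:, ch]), rel=1e-12)


class TestArchiveRoundTrip:
    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(
            repetition_s=2.0,
            rest_s=0.5,
            repetitions=1,
            seed=3,
            movements=[
                MovementSpec("A", TARGET, np.full(8, 0.8)),
                MovementSpec("B", TARGET, np.linspace(0.1, 1.0, 8)),
            ],
        )
        rec = generate_recording(cfg)
        from semgrej.preprocessing import encode_recording, fit_activity_threshold

        th = fit_activity_threshold(np.full(100, 1e-6))
        images, _ = encode_recording(rec, stack=10, threshold=th)
        assert images
        path = tmp_path / "images.npz"
        save_images(path, images)
        back = load_images(path)
        assert len(back) == len(images)
        for a, b in zip(images, back):
            np.testing.assert_array_equal(a.planes, b.planes)
            assert (a.label, a.kind, a.trial_id, a.pad_count) == (
                b.label,
                b.kind,
                b.trial_id,
                b.pad_count,
            )
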