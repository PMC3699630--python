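import numpy as np
import pytest

from erpselect import (
    ContinuousRun,
    EpochedDataset,
    SensorSet,
    build_design,
    fit_csp,
    fit_pca,
    fit_ssnr_model,
    fit_xdawn,
    ssnr_of_filter,
    ssnr_of_sensor,
    simulate_session,
)
from erpselect.spatial import xdawn_from_ssnr_model
from conftest import small_config


def make_run(signal, events, fs=100.0):
    signal = np.asarray(signal, dtype=float)
    return ContinuousRun(
        signal=signal,
        sample_rate=fs,
        channel_names=[f"ch{i}" for i in range(signal.shape[0])],
        events=list(events),
    )


def synthesized_run(rng, n_ch=4, erp_len=10, n_events=20, spacing=25,
                    noise_sd=0.0, n_samples=None):
    """Noise-free (by default) run built from known response matrices."""
    onsets = np.arange(n_events) * spacing + 3
    classes = ["target" if i % 3 == 0 else "standard" for i in range(n_events)]
    events = list(zip((int(o) for o in onsets), classes))
    if n_samples is None:
        n_samples = int(onsets[-1] + 2 * erp_len)
    A1 = rng.normal(size=(erp_len, n_ch))
    A2 = rng.normal(size=(erp_len, n_ch))
    D1 = build_design(events, n_samples, erp_len, "target").toarray()
    D2 = build_design(events, n_samples, erp_len, "all").toarray()
    X = (D1 @ A1 + D2 @ A2).T
    if noise_sd:
        X = X + rng.normal(0, noise_sd, X.shape)
    return make_run(X, events), A1, A2


class TestBuildDesign:
    def test_single_onset_diagonal(self):
        D = build_design([(0, "target")], 5, 3, "target").toarray()
        expected = np.zeros((5, 3))
        expected[0, 0] = expected[1, 1] = expected[2, 2] = 1
        np.testing.assert_array_equal(D, expected)

    def test_overlapping_onsets(self):
        D = build_design(
            [(0, "target"), (1, "target")], 4, 2, "target"
        ).toarray()
        expected = np.zeros((4, 2))
        expected[0, 0] = expected[1, 0] = 1  # onsets 0 and 1, shift 0
        expected[1, 1] = expected[2, 1] = 1  # onsets 0 and 1, shift 1
        np.testing.assert_array_equal(D, expected)

    def test_no_events_zero_matrix(self):
        D = build_design([], 6, 2, "all").toarray()
        np.testing.assert_array_equal(D, 0.0)

    def test_target_selection_and_truncation(self):
        events = [(0, "standard"), (4, "target")]
        D = build_design(events, 5, 3, "target").toarray()
        assert D[4, 0] == 1 and D.sum() == 1  # truncated at recording end
        D_all = build_design(events, 5, 3, "all").toarray()
        assert D_all.sum() == 4

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            build_design([], 5, 0, "all")
        with pytest.raises(ValueError):
            build_design([], 5, 2, "everything")


class TestSsnrModel:
    def test_noiseless_recovery(self, rng):
        run, A1, A2 = synthesized_run(rng)
        model = fit_ssnr_model(run, erp_len_ms=100.0)
        np.testing.assert_allclose(model.A1, A1, atol=1e-8)
        np.testing.assert_allclose(model.A2, A2, atol=1e-8)

    def test_zero_signal_zero_estimates(self):
        run = make_run(np.zeros((2, 100)), [(5, "target"), (40, "standard")])
        model = fit_ssnr_model(run, erp_len_ms=100.0)
        np.testing.assert_allclose(model.A1, 0.0, atol=1e-12)
        np.testing.assert_allclose(model.A2, 0.0, atol=1e-12)

    def test_targets_only_equals_epoch_average(self, rng):
        # non-overlapping targets-only design: LS estimate = epoch average
        erp_len, spacing = 10, 30
        onsets = [5, 35, 65, 95]
        events = [(o, "target") for o in onsets]
        X = rng.normal(size=(3, 130))
        run = make_run(X, events)
        model = fit_ssnr_model(run, erp_len_ms=100.0)
        avg = np.mean([X[:, o : o + erp_len] for o in onsets], axis=0).T
        np.testing.assert_allclose(model.A1, avg, atol=1e-10)
        np.testing.assert_allclose(model.A2, 0.0, atol=1e-12)

    def test_restriction_is_exact(self, rng):
        run, _, _ = synthesized_run(rng, noise_sd=0.5)
        model = fit_ssnr_model(run, erp_len_ms=100.0)
        sub = model.restrict(SensorSet(("ch2", "ch0")))
        direct = fit_ssnr_model(run.restrict(SensorSet(("ch2", "ch0"))), 100.0)
        np.testing.assert_allclose(sub.erp_gram, direct.erp_gram, atol=1e-8)
        np.testing.assert_allclose(sub.A1, direct.A1, atol=1e-8)


class TestSsnrOfSensor:
    def test_noiseless_target_only_sensor_is_one(self, rng):
        erp_len = 10
        events = [(5, "target"), (30, "standard"), (55, "target"),
                  (80, "standard")]
        a = rng.normal(size=erp_len)
        D1 = build_design(events, 120, erp_len, "target").toarray()
        X = (D1 @ a[:, None]).T
        run = make_run(np.vstack([X, rng.normal(size=(1, 120))]), events)
        model = fit_ssnr_model(run, erp_len_ms=100.0)
        assert ssnr_of_sensor(model, 0) == pytest.approx(1.0, abs=1e-8)

    def test_pure_noise_sensor_small(self):
        # Monte Carlo: fitted-design share of white noise energy is tiny
        for seed in range(20):
            rng = np.random.default_rng(seed)
            onsets = np.arange(40) * 120 + 7
            events = [
                (int(o), "target" if i % 4 == 0 else "standard")
                for i, o in enumerate(onsets)
            ]
            run = make_run(rng.normal(size=(1, 5000)), events)
            model = fit_ssnr_model(run, erp_len_ms=500.0)
            assert ssnr_of_sensor(model, 0) <= 0.05

    def test_erp_sensor_beats_matched_noise_sensor(self, rng):
        cfg = small_config(seed=9)
        (run, *_) = simulate_session(cfg, 0, 0)
        model = fit_ssnr_model(run, erp_len_ms=1000.0)
        assert ssnr_of_sensor(model, "Cz") > ssnr_of_sensor(model, "Fp1")

    def test_zero_energy_sensor(self):
        run = make_run(np.zeros((1, 50)), [(3, "target"), (20, "standard")])
        model = fit_ssnr_model(run, erp_len_ms=100.0)
        assert ssnr_of_sensor(model, 0) == 0.0


class TestSsnrOfFilter:
    @pytest.fixture()
    def model(self, rng):
        run, _, _ = synthesized_run(rng, noise_sd=1.0)
        return fit_ssnr_model(run, erp_len_ms=100.0)

    def test_indicator_filter_matches_sensor(self, model):
        for i in range(model.n_channels):
            w = np.zeros(model.n_channels)
            w[i] = 1.0
            assert ssnr_of_filter(model, w) == pytest.approx(
                ssnr_of_sensor(model, i), abs=1e-12
            )

    def test_scale_invariance(self, model, rng):
        w = rng.normal(size=model.n_channels)
        assert ssnr_of_filter(model, w) == pytest.approx(
            ssnr_of_filter(model, -3.7 * w), abs=1e-12
        )

    def test_zero_filter_rejected(self, model):
        with pytest.raises(ValueError):
            ssnr_of_filter(model, np.zeros(model.n_channels))

    def test_bounded_in_unit_interval(self, model, rng):
        for _ in range(100):
            w = rng.normal(size=model.n_channels)
            assert 0.0 <= ssnr_of_filter(model, w) <= 1.0


class TestXdawn:
    def test_single_informative_sensor_dominates_first_filter(self):
        for seed in range(10):
            cfg = small_config(
                seed=seed, informative_sensors=("Cz",), erp_amplitude=3.0,
                n_standards_per_run=80, n_targets_per_run=20,
                visual_amplitude=0.0,
            )
            (run, *_) = simulate_session(cfg, 0, 0)
            fm = fit_xdawn(run, n_filters=3)
            cz = run.channel_names.index("Cz")
            assert np.argmax(np.abs(fm.W[:, 0])) == cz

    def test_first_filter_beats_random_filters(self, rng):
        cfg = small_config(seed=4, n_standards_per_run=80, n_targets_per_run=20)
        (run, *_) = simulate_session(cfg, 0, 0)
        model = fit_ssnr_model(run, erp_len_ms=1000.0)
        fm = xdawn_from_ssnr_model(model, n_filters=1)
        best = ssnr_of_filter(model, fm.W[:, 0])
        for _ in range(200):
            w = rng.normal(size=model.n_channels)
            assert ssnr_of_filter(model, w / np.linalg.norm(w)) <= best + 1e-10

    def test_values_weakly_decreasing(self, small_session):
        fm = fit_xdawn(small_session[0])
        assert np.all(np.diff(fm.values) <= 1e-12)
        assert np.all((fm.values >= 0) & (fm.values <= 1))

    def test_full_bank_invertible_reconstruction(self, small_epochs):
        data = small_epochs[0]
        fm = fit_xdawn(data, n_filters=data.n_channels)
        virtual = fm.apply(data.epochs)
        back = np.einsum("cf,tfs->tcs", np.linalg.inv(fm.W.T), virtual)
        np.testing.assert_allclose(back, data.epochs, atol=1e-6)

    def test_requires_targets(self):
        run = make_run(np.random.default_rng(0).normal(size=(2, 100)),
                       [(5, "standard"), (50, "standard")])
        with pytest.raises(ValueError):
            fit_xdawn(run)


class TestCsp:
    def _epochs(self, x, labels):
        return EpochedDataset(
            epochs=x, labels=np.asarray(labels, dtype=object),
            window_ms=(0.0, 1000.0), sample_rate=100.0,
            channel_names=[f"ch{i}" for i in range(x.shape[1])],
        )

    def test_identical_covariances_give_half(self, rng):
        x = rng.normal(size=(40, 4, 50))
        data = self._epochs(np.concatenate([x, x]), ["standard"] * 40 + ["target"] * 40)
        fm = fit_csp(data)
        np.testing.assert_allclose(
            np.maximum(fm.values, 1 - fm.values), 0.5, atol=1e-9
        )

    def test_planted_direction_recovered(self, rng):
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        n, s = 150, 60
        noise = rng.normal(size=(2 * n, 6, s))
        extra = rng.normal(0, 3.0, size=(n, s))
        x = noise.copy()
        x[n:] += extra[:, None, :] * v[:, None]
        data = self._epochs(x, ["standard"] * n + ["target"] * n)
        fm = fit_csp(data)
        w = fm.W[:, 0]
        cos = abs(w @ v) / np.linalg.norm(w)
        assert np.degrees(np.arccos(min(cos, 1.0))) <= 10.0

    def test_filters_decorrelate_pooled_covariance(self, rng):
        x = rng.normal(size=(60, 5, 40))
        x[30:] *= 1.5
        data = self._epochs(x, ["standard"] * 30 + ["target"] * 30)
        fm = fit_csp(data)
        from erpselect.spatial import _epoch_covariances

        covs = _epoch_covariances(data)
        pooled = covs["standard"] + covs["target"]
        gram = fm.W.T @ pooled @ fm.W
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6

    def test_needs_both_classes(self, rng):
        data = self._epochs(rng.normal(size=(10, 3, 20)), ["target"] * 10)
        with pytest.raises(ValueError):
            fit_csp(data)


class TestPca:
    def _epochs(self, x):
        n = x.shape[0]
        return EpochedDataset(
            epochs=x,
            labels=np.asarray(["standard"] * n, dtype=object),
            window_ms=(0.0, 1000.0), sample_rate=100.0,
            channel_names=[f"ch{i}" for i in range(x.shape[1])],
        )

    def test_high_variance_sensor_dominates(self, rng):
        x = rng.normal(size=(50, 5, 40))
        x[:, 2, :] *= 10.0  # 100x variance
        fm = fit_pca(self._epochs(x))
        w = fm.W[:, 0] / np.linalg.norm(fm.W[:, 0])
        assert abs(w[2]) > 0.9

    def test_eigenvalues_weakly_decreasing(self, rng):
        fm = fit_pca(self._epochs(rng.normal(size=(30, 6, 20))))
        assert np.all(np.diff(fm.values) <= 1e-12)

    def test_orthonormal_filters(self, rng):
        fm = fit_pca(self._epochs(rng.normal(size=(30, 6, 20))))
        np.testing.assert_allclose(fm.W.T @ fm.W, np.eye(6), atol=1e-8)
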