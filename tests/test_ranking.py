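import numpy as np
import pytest

from erpselect import (
    ContinuousRun,
    FeatureTable,
    FilterModel,
    SensorSet,
    balanced_accuracy,
    epoch,
    fit_ssnr_model,
    make_ranker,
    rank_filter_weights,
    rank_performance,
    rank_ssnr_s,
    rank_ssnr_v,
    rank_svm,
    simulate_session,
    ssnr_of_sensor,
)
from erpselect.chain import ChainConfig
from erpselect.ranking import RANKER_IDS, train_ranking_svm
from conftest import small_config


@pytest.fixture(scope="module")
def run():
    cfg = small_config(seed=2, n_standards_per_run=100, n_targets_per_run=25)
    return simulate_session(cfg, 0, 0)[0]


@pytest.fixture(scope="module")
def ssnr_model(run):
    return fit_ssnr_model(run, erp_len_ms=1000.0)


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "counts,expected",
        [((9, 1, 90, 10), 0.9), ((0, 10, 100, 0), 0.5), ((5, 5, 5, 5), 0.5),
         ((10, 0, 0, 10), 0.5), ((10, 0, 10, 0), 1.0)],
    )
    def test_closed_form(self, counts, expected):
        assert balanced_accuracy(*counts) == pytest.approx(expected)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(0, 0, 5, 5)
        with pytest.raises(ValueError):
            balanced_accuracy(5, 5, 0, 0)


class TestFilterWeightRanking:
    def _model(self, W, names):
        return FilterModel(
            W=np.asarray(W, dtype=float), method="xdawn",
            n_filters=np.asarray(W).shape[1],
            values=np.zeros(np.asarray(W).shape[1]),
            channel_names=list(names),
        )

    def test_absolute_weight_sums(self):
        model = self._model([[1, -2], [0, 3]], ["a", "b"])
        score = rank_filter_weights(model, SensorSet(("a", "b")), k=2)
        assert score.contributions == {"a": 3.0, "b": 3.0}
        assert score.value == 6.0

    def test_zero_row_contributes_nothing(self):
        model = self._model([[1, 2], [0, 0], [3, 1]], ["a", "b", "c"])
        score = rank_filter_weights(model, SensorSet(("a", "b", "c")), k=2)
        assert score.contributions["b"] == 0.0
        assert min(score.contributions, key=score.contributions.get) == "b"

    def test_permutation_equivariance(self):
        model = self._model([[1, -2], [0, 3], [2, 2]], ["a", "b", "c"])
        fwd = rank_filter_weights(model, SensorSet(("a", "b", "c")), k=2)
        rev = rank_filter_weights(model, SensorSet(("c", "b", "a")), k=2)
        assert fwd.value == rev.value
        assert fwd.contributions == rev.contributions

    def test_k_exceeding_filters_rejected(self):
        model = self._model([[1], [2]], ["a", "b"])
        with pytest.raises(ValueError):
            rank_filter_weights(model, SensorSet(("a",)), k=2)


class TestSsnrSensorSpace:
    def test_singleton_equals_individual_ssnr(self, ssnr_model):
        for ch in ("Cz", "Fp1"):
            score = rank_ssnr_s(ssnr_model, SensorSet((ch,)))
            assert score.value == pytest.approx(ssnr_of_sensor(ssnr_model, ch))

    def test_additivity_over_disjoint_sets(self, ssnr_model):
        a = rank_ssnr_s(ssnr_model, SensorSet(("Cz", "Pz")))
        b = rank_ssnr_s(ssnr_model, SensorSet(("Fp1", "F3")))
        union = rank_ssnr_s(ssnr_model, SensorSet(("Cz", "Pz", "Fp1", "F3")))
        assert union.value == pytest.approx(a.value + b.value)

    def test_adding_sensor_never_decreases(self, ssnr_model, run):
        base = rank_ssnr_s(ssnr_model, SensorSet(("Cz",))).value
        for ch in run.channel_names:
            if ch == "Cz":
                continue
            grown = rank_ssnr_s(ssnr_model, SensorSet(("Cz", ch))).value
            assert grown >= base - 1e-12


class TestSsnrVirtualSpace:
    def test_full_set_equals_topk_filter_sum(self, ssnr_model, run):
        from erpselect.spatial import xdawn_from_ssnr_model

        k = 5
        score = rank_ssnr_v(ssnr_model, SensorSet(run.channel_names), k)
        fm = xdawn_from_ssnr_model(ssnr_model, n_filters=k)
        assert score.value == pytest.approx(float(np.sum(fm.values)), abs=1e-10)

    def test_duplicated_sensor_absorbed(self, run):
        i = run.channel_names.index("Pz")
        dup = ContinuousRun(
            signal=np.vstack([run.signal, run.signal[i]]),
            sample_rate=run.sample_rate,
            channel_names=run.channel_names + ["PzDup"],
            events=list(run.events),
        )
        model = fit_ssnr_model(dup, erp_len_ms=1000.0)
        s = SensorSet(("Cz", "CP1", "Pz", "P3", "Fz", "F3"))
        with_dup = SensorSet(s.members + ("PzDup",))
        a = rank_ssnr_v(model, s, 5).value
        b = rank_ssnr_v(model, with_dup, 5).value
        assert abs(a - b) <= 1e-6

    def test_monotone_on_nested_sets(self, ssnr_model, run, rng):
        names = np.array(run.channel_names)
        k = 5
        for _ in range(50):
            m_small = int(rng.integers(k, len(names) - 1))
            big_idx = rng.choice(len(names), size=m_small + 1, replace=False)
            small_idx = rng.choice(big_idx, size=m_small, replace=False)
            small = rank_ssnr_v(ssnr_model, SensorSet(names[small_idx]), k).value
            big = rank_ssnr_v(ssnr_model, SensorSet(names[big_idx]), k).value
            assert small <= big + 1e-9

    def test_small_set_lowers_k(self, ssnr_model):
        score = rank_ssnr_v(ssnr_model, SensorSet(("Cz", "Pz")), k=5)
        assert np.isfinite(score.value)


def make_feature_table(matrix, labels, names, per_sensor):
    fmap = [
        (ch, float(120 * j))
        for ch in names
        for j in range(per_sensor)
    ]
    return FeatureTable(
        matrix=np.asarray(matrix, dtype=float),
        labels=np.asarray(labels, dtype=object),
        feature_map=fmap,
        features_per_sensor=per_sensor,
        channel_names=list(names),
    )


class TestSvmRanking:
    def test_contribution_arithmetic(self):
        model_weights = np.array([0.5, -0.5, 0.1, 0.0])
        from erpselect.ranking import SvmModel

        model = SvmModel(
            weights=model_weights, bias=0.0, norm=2, c=1.0,
            feature_map=[("s1", 0.0), ("s1", 120.0), ("s2", 0.0), ("s2", 120.0)],
            channel_names=["s1", "s2"],
        )
        assert model.sensor_contribution("s1") == pytest.approx(1.0)
        assert model.sensor_contribution("s2") == pytest.approx(0.1)

    def test_one_norm_silences_noise_sensor(self, rng):
        n = 300
        y = rng.random(n) < 0.25
        labels = np.where(y, "target", "standard")
        informative = y.astype(float)[:, None] + rng.normal(0, 0.1, (n, 2))
        noise = rng.normal(size=(n, 2))
        table = make_feature_table(
            np.hstack([informative, noise]), labels, ["sig", "noi"], 2
        )
        score = rank_svm(table, SensorSet(("sig", "noi")), norm=1, c=0.1)
        assert score.contributions["noi"] <= 0.05 * score.contributions["sig"]

    def test_two_norm_splits_duplicate_features(self, rng):
        n = 300
        y = rng.random(n) < 0.25
        labels = np.where(y, "target", "standard")
        feat = y.astype(float)[:, None] + rng.normal(0, 0.3, (n, 1))
        solo = make_feature_table(feat, labels, ["a"], 1)
        dup = make_feature_table(np.hstack([feat, feat]), labels, ["a", "b"], 1)
        w_solo = train_ranking_svm(solo, norm=2, c=0.1).sensor_contribution("a")
        model = train_ranking_svm(dup, norm=2, c=0.1)
        for ch in ("a", "b"):
            assert model.sensor_contribution(ch) <= w_solo + 1e-8

    def test_single_class_rejected(self, rng):
        table = make_feature_table(
            rng.normal(size=(20, 2)), ["standard"] * 20, ["a"], 2
        )
        with pytest.raises(ValueError):
            rank_svm(table, SensorSet(("a",)), norm=2)


class TestPerformanceRanking:
    def test_separable_data_scores_high(self):
        cfg = small_config(seed=5, erp_amplitude=4.0, noise_sd=0.5,
                           n_standards_per_run=100, n_targets_per_run=25)
        run = simulate_session(cfg, 0, 0)[0]
        data = epoch(run, (0.0, 1000.0))
        score = rank_performance(data, SensorSet(cfg.informative_sensors))
        assert score.value >= 0.95

    def test_permuted_labels_score_at_chance(self, run):
        data = epoch(run, (0.0, 1000.0))
        scores = []
        for seed in range(10):
            shuffled = np.random.default_rng(seed).permutation(data.labels)
            permuted = type(data)(
                epochs=data.epochs, labels=shuffled, window_ms=data.window_ms,
                sample_rate=data.sample_rate, channel_names=data.channel_names,
            )
            scores.append(
                rank_performance(
                    permuted, SensorSet(("Cz", "Pz", "P3", "CP1")),
                ).value
            )
        assert 0.4 <= float(np.mean(scores)) <= 0.6

    def test_deterministic(self, run):
        data = epoch(run, (0.0, 1000.0))
        s = SensorSet(("Cz", "Pz"))
        assert rank_performance(data, s).value == rank_performance(data, s).value


class TestRegistry:
    def test_all_ids_construct_and_score(self, run):
        s = SensorSet(("Cz", "CP1", "CP2", "P3", "Pz", "Fp1"))
        cfg = ChainConfig(svm_grid=(0.01,))  # keep the performance ranker fast
        for method in RANKER_IDS:
            ranker = make_ranker(method, run, cfg)
            value = ranker.score(s).value
            assert np.isfinite(value), method

    def test_contribution_exposure(self, run):
        s = SensorSet(("Cz", "CP1", "Pz", "P3", "Fp1", "Fz"))
        expected_exposed = {"xdawn", "csp", "pca", "ssnr_s", "svm1", "svm2"}
        for method in RANKER_IDS:
            ranker = make_ranker(method, run, ChainConfig(svm_grid=(0.01,)))
            contrib = ranker.contributions(s)
            if method in expected_exposed:
                assert set(contrib) == set(s.members)
                assert all(np.isfinite(v) for v in contrib.values())
            else:
                assert contrib is None

    def test_unknown_method(self, run):
        with pytest.raises(KeyError):
            make_ranker("entropy", run)
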