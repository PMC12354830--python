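import numpy as np
import pytest

from efmon.detector import (
    DetectorConfig,
    LabeledSegment,
    augment,
    build_model,
    classify,
    evaluate,
    fit_length,
    metrics_from_scores,
    pitch_shift,
    time_stretch,
)
from efmon.detector import train as train_detector
from efmon.errors import ContractError, SplitLeakageError
from efmon.signals import Segment, Spectrogram, spectrogram
from conftest import labeled_split


class _StubRng:
    """Deterministic rng double: feeds queued values to augment()."""

    def __init__(self, randoms, uniforms=(), normals_sd=None):
        self._randoms = list(randoms)
        self._uniforms = list(uniforms)
        self._real = np.random.default_rng(0)

    def random(self, *args, **kwargs):
        return self._randoms.pop(0)

    def uniform(self, lo, hi, *args):
        return self._uniforms.pop(0)

    def normal(self, loc, scale, size=None):
        return self._real.normal(loc, scale, size)

    def integers(self, lo, hi):
        return lo


def _noise_segment(seed=0, scale=0.01):
    return Segment(np.random.default_rng(seed).normal(0, scale, 4000), 0)


class TestBuildModel:
    def test_architecture_determinism(self):
        a = build_model(seed=0)
        b = build_model(seed=0)
        assert a.n_parameters == b.n_parameters > 0
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_dropout_off_forward_is_deterministic(self):
        cfg = DetectorConfig(dropout_rate=0.0, conv_dropout_rate=0.0)
        m = build_model(cfg, seed=0)
        x = np.random.default_rng(1).normal(0, 1, (2, 129, 32)).astype(np.float32)
        out1, _ = m.forward(x, training=True, rng=np.random.default_rng(1))
        out2, _ = m.forward(x, training=True, rng=np.random.default_rng(99))
        np.testing.assert_array_equal(out1, out2)

    def test_dropout_on_changes_training_forward(self):
        m = build_model(seed=0)
        x = np.random.default_rng(1).normal(0, 1, (2, 129, 32)).astype(np.float32)
        out1, _ = m.forward(x, training=True, rng=np.random.default_rng(1))
        out2, _ = m.forward(x, training=True, rng=np.random.default_rng(2))
        assert not np.array_equal(out1, out2)

    def test_probability_output_range(self):
        m = build_model(seed=0)
        spec = spectrogram(_noise_segment())
        res = classify(m, spec)
        assert 0.0 <= res.probability <= 1.0

    def test_zero_spectrogram_finite_probability(self):
        m = build_model(seed=0)
        spec = Spectrogram(np.zeros((129, 32)), 15.625, 0.032)
        res = classify(m, spec)
        assert np.isfinite(res.probability)
        assert 0.0 <= res.probability <= 1.0

    def test_threshold_tie_labeled_insect(self):
        m = build_model(seed=0)
        spec = spectrogram(_noise_segment())
        p = classify(m, spec).probability
        assert classify(m, spec, threshold=p).is_insect

    def test_shape_mismatch_rejected(self):
        m = build_model(seed=0)
        with pytest.raises(ContractError):
            classify(m, np.zeros((64, 32)))

    def test_unsupported_kernel_rejected(self):
        with pytest.raises(ContractError):
            build_model(DetectorConfig(kernel_size=5))


class TestAugment:
    def test_identity_when_gate_does_not_trigger(self):
        seg = _noise_segment()
        out = augment(seg, _StubRng([0.9]))
        np.testing.assert_array_equal(out.samples, seg.samples)

    def test_time_shift_impulse(self):
        x = np.zeros(4000)
        x[1000] = 1.0
        # gate on; skip pitch, skip stretch, take shift(+0.25), skip noises
        rng = _StubRng([0.1, 0.9, 0.9, 0.1, 0.9, 0.9], uniforms=[0.25])
        out = augment(Segment(x, 0), rng)
        assert np.argmax(out.samples) == 2000

    def test_gaussian_noise_amplitude(self):
        seg = Segment(np.zeros(4000), 0)
        rng = _StubRng([0.1, 0.9, 0.9, 0.9, 0.1, 0.9])
        out = augment(seg, rng)
        assert out.samples.std() == pytest.approx(0.003, rel=0.15)

    def test_empty_noise_bank_warns(self):
        rng = _StubRng([0.1, 0.9, 0.9, 0.9, 0.9, 0.1])
        with pytest.warns(UserWarning, match="noise bank"):
            out = augment(_noise_segment(), rng, noise_bank=None)
        assert out.samples.size == 4000

    def test_output_always_4000_samples(self):
        rng = np.random.default_rng(5)
        seg = _noise_segment()
        for _ in range(10):
            assert augment(seg, rng).samples.size == 4000

    def test_pitch_shift_moves_tone(self):
        t = np.arange(4000) / 4000
        tone = np.sin(2 * np.pi * 200 * t)
        y = pitch_shift(tone, 4.0)
        f = np.abs(np.fft.rfft(y * np.hanning(4000)))
        assert np.argmax(f) == pytest.approx(200 * 2 ** (4 / 12), abs=2)

    def test_time_stretch_changes_duration(self):
        x = _noise_segment().samples
        assert time_stretch(x, 0.8).size == 5000
        assert time_stretch(x, 1.25).size == 3200

    def test_fit_length(self):
        assert fit_length(np.arange(10.0), 4).size == 4
        padded = fit_length(np.arange(4.0), 10)
        assert padded.size == 10 and padded[0] == 0.0


class TestTraining:
    def _tiny_sets(self, n_pos, n_neg, sensors=("A", "B")):
        rng = np.random.default_rng(0)
        out = []
        for i in range(n_pos):
            t = np.arange(4000) / 4000
            x = 0.1 * np.sin(2 * np.pi * 200 * t) + rng.normal(0, 0.005, 4000)
            out.append(LabeledSegment(Segment(x, 0), "insect", sensors[i % len(sensors)]))
        for i in range(n_neg):
            x = rng.normal(0, 0.005, 4000)
            out.append(LabeledSegment(Segment(x, 0), "non-insect", sensors[i % len(sensors)]))
        return out

    def test_positive_class_weight_is_ratio(self):
        cfg = DetectorConfig(conv_filters=(2, 2), dense_units=4, epochs=1, batch_size=8)
        train_set = self._tiny_sets(5, 30, sensors=("A",))
        val_set = self._tiny_sets(2, 2, sensors=("B",))
        model = build_model(cfg, seed=0)
        _, history = train_detector(model, train_set, val_set, cfg, seed=0,
                                    use_augmentation=False)
        assert history["pos_weight"] == pytest.approx(6.0)

    def test_split_leakage_rejected(self):
        cfg = DetectorConfig(conv_filters=(2, 2), dense_units=4, epochs=1)
        both = self._tiny_sets(2, 2, sensors=("A",))
        with pytest.raises(SplitLeakageError):
            train_detector(build_model(cfg, seed=0), both, both, cfg, seed=0)

    def test_single_class_training_rejected(self):
        cfg = DetectorConfig(conv_filters=(2, 2), dense_units=4, epochs=1)
        pos_only = self._tiny_sets(4, 0, sensors=("A",))
        val = self._tiny_sets(1, 1, sensors=("B",))
        with pytest.raises(ContractError):
            train_detector(build_model(cfg, seed=0), pos_only, val, cfg, seed=0)

    def test_seeded_training_reproducible(self):
        cfg = DetectorConfig(conv_filters=(2, 3), dense_units=8, epochs=2, batch_size=8)
        train_set = self._tiny_sets(6, 6, sensors=("A",))
        val_set = self._tiny_sets(2, 2, sensors=("B",))
        h = []
        for _ in range(2):
            model = build_model(cfg, seed=7)
            _, history = train_detector(model, train_set, val_set, cfg, seed=7)
            h.append((history["train_loss"], history["val_loss"]))
        assert h[0] == h[1]

    def test_separable_classes_reach_high_auc(self, trained_detector, small_dataset):
        model, history = trained_detector
        manifest, waves = small_dataset
        metrics = evaluate(model, labeled_split(manifest, waves, "test"))
        assert metrics["auc"] >= 0.95

    def test_heldout_insect_detected(self, trained_detector, small_dataset):
        model, _ = trained_detector
        manifest, waves = small_dataset
        test = labeled_split(manifest, waves, "test")
        hits = [
            classify(model, spectrogram(s.segment)).is_insect
            for s in test if s.label == "insect"
        ]
        assert np.mean(hits) >= 0.9

    def test_checkpoint_roundtrip(self, trained_detector, tmp_path):
        model, _ = trained_detector
        model.save(tmp_path / "ckpt")
        from efmon.detector import DetectorModel

        back = DetectorModel.load(tmp_path / "ckpt.npz")
        x = np.random.default_rng(0).normal(0, 1, (3, 129, 32)).astype(np.float32)
        np.testing.assert_allclose(model.predict_proba(x), back.predict_proba(x))


class TestMetrics:
    def test_perfect_classifier(self):
        y = np.array([1, 1, 0, 0])
        m = metrics_from_scores(y, np.array([0.9, 0.8, 0.1, 0.2]))
        assert m["auc"] == 1.0 and m["f1"] == 1.0

    def test_uninformative_scores(self):
        y = np.array([1, 0, 1, 0])
        m = metrics_from_scores(y, np.full(4, 0.5))
        assert m["auc"] == pytest.approx(0.5)

    def test_constructed_confusion_table(self):
        # TP=81, FP=24, FN=19, TN=76 over 100 positives / 100 negatives
        y = np.concatenate([np.ones(100), np.zeros(100)])
        probs = np.concatenate(
            [np.full(81, 0.9), np.full(19, 0.1), np.full(24, 0.9), np.full(76, 0.1)]
        )
        m = metrics_from_scores(y, probs)
        assert m["precision"] == pytest.approx(0.771, abs=5e-4)
        assert m["recall"] == pytest.approx(0.81, abs=1e-9)
        assert m["f1"] == pytest.approx(0.790, abs=5e-4)

    def test_single_class_set_rejected(self):
        with pytest.raises(ContractError):
            metrics_from_scores(np.ones(5), np.linspace(0, 1, 5))
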