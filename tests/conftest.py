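import numpy as np
import pytest

from efmon.detector import DetectorConfig, LabeledSegment, build_model
from efmon.detector import train as train_detector
from efmon.signals import Segment
from efmon.simulate import synth_dataset


def labeled_split(manifest, waves, split: str) -> list[LabeledSegment]:
    mask = (manifest["split"] == split).to_numpy()
    return [
        LabeledSegment(Segment(w, 0), label, sensor)
        for w, label, sensor in zip(
            waves[mask], manifest["label"][mask], manifest["sensor_id"][mask]
        )
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """Sensor-disjoint labelled dataset shared across detector tests."""
    manifest, waves = synth_dataset(300, 800, out_dir=None, seed=11)
    return manifest, waves


@pytest.fixture(scope="session")
def trained_detector(small_dataset):
    """A detector good enough for pipeline tests (~2 min to train once)."""
    manifest, waves = small_dataset
    cfg = DetectorConfig(epochs=6, patience=4)
    model = build_model(cfg, seed=0)
    model, history = train_detector(
        model,
        labeled_split(manifest, waves, "train"),
        labeled_split(manifest, waves, "val"),
        cfg,
        seed=0,
        use_augmentation=False,
    )
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
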