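"""CNN insect/non-insect classifier over 1-s spectrograms.

Architecture: conv(16) + ReLU + BN -> dropout -> conv(32) + ReLU + BN ->
2x2 max-pool -> flatten -> dense(256) + BN + ReLU -> dropout -> dense(1)
with a sigmoid output. Training uses class-weighted binary cross-entropy
(positive weight = #negative/#positive, i.e. no rebalancing of the data
itself) and per-epoch waveform augmentation: each segment is augmented with
probability 0.5, and an augmented segment receives each technique (pitch
shift of +-4 semitones, circular time shift by -0.5..+0.5 of the length,
time stretch by 0.8-1.25, Gaussian noise of amplitude 0.003, real-noise
mixing) independently with probability 0.5, applied to both classes.

Spectrograms are fed as log(1 + magnitude), per-segment max-normalized.
The network runs on a small numpy engine (:mod:`efmon._nn`); checkpoints
are ``.npz`` archives with a JSON sidecar recording the configuration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.special import expit
from scipy.stats import rankdata

from . import _nn
from .errors import ContractError, SplitLeakageError
from .signals import Segment, Spectrogram, spectrogram

DEFAULT_THRESHOLD = 0.5


@dataclass
class DetectorConfig:
    conv_filters: tuple[int, int] = (16, 32)
    dense_units: int = 256
    dropout_rate: float = 0.5
    conv_dropout_rate: float = 0.25
    kernel_size: int = 3
    pool_size: int = 2
    epochs: int = 30
    batch_size: int = 32
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    patience: int = 5
    augment_prob: float = 0.5
    technique_prob: float = 0.5
    class_weighting: bool = True


@dataclass
class LabeledSegment:
    segment: Segment
    label: str  # "insect" | "non-insect"
    source_sensor: str

    def __post_init__(self) -> None:
        if self.label not in ("insect", "non-insect"):
            raise ContractError(f"label must be binary, got {self.label!r}")
        if not self.source_sensor:
            raise ContractError("source_sensor must be non-empty")

    @property
    def y(self) -> float:
        return 1.0 if self.label == "insect" else 0.0


@dataclass
class DetectionResult:
    segment_index: int
    probability: float
    is_insect: bool


# ------------------------------------------------------------- features ----

def features_from_waveform(x: np.ndarray, fs: int = 4000, index: int = 0) -> np.ndarray:
    spec = spectrogram(Segment(samples=x, index=index, fs=fs))
    return features_from_spectrogram(spec.magnitudes)


def features_from_spectrogram(mags: np.ndarray) -> np.ndarray:
    """log(1 + magnitude), max-normalized per segment."""
    z = np.log1p(np.asarray(mags, dtype=np.float32))
    peak = z.max()
    if peak > 0:
        z = z / peak
    return z


# ---------------------------------------------------------------- model ----

class DetectorModel:
    """Parameter container plus forward/backward passes."""

    def __init__(self, cfg: DetectorConfig, rng: np.random.Generator | None = None):
        if cfg.kernel_size != 3 or cfg.pool_size != 2:
            raise ContractError("engine supports kernel 3 and pool 2 only")
        self.cfg = cfg
        rng = rng or np.random.default_rng(0)
        f1, f2 = cfg.conv_filters
        h, w = 129, 32
        flat = (h // 2) * (w // 2) * f2
        d = cfg.dense_units
        self.params = {
            "w1": _nn.he_init(rng, (3, 3, 1, f1), 9),
            "b1": np.zeros(f1, np.float32),
            "g1": np.ones(f1, np.float32),
            "be1": np.zeros(f1, np.float32),
            "w2": _nn.he_init(rng, (3, 3, f1, f2), 9 * f1),
            "b2": np.zeros(f2, np.float32),
            "g2": np.ones(f2, np.float32),
            "be2": np.zeros(f2, np.float32),
            "w3": _nn.he_init(rng, (flat, d), flat),
            "b3": np.zeros(d, np.float32),
            "g3": np.ones(d, np.float32),
            "be3": np.zeros(d, np.float32),
            "w4": _nn.he_init(rng, (d, 1), d),
            "b4": np.zeros(1, np.float32),
        }
        self.running = {
            "bn1": {"mean": np.zeros(f1, np.float32), "var": np.ones(f1, np.float32)},
            "bn2": {"mean": np.zeros(f2, np.float32), "var": np.ones(f2, np.float32)},
            "bn3": {"mean": np.zeros(d, np.float32), "var": np.ones(d, np.float32)},
        }

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """x: (N, 129, 32). Returns (logits (N,1), cache)."""
        p, cfg = self.params, self.cfg
        rng = rng or np.random.default_rng(0)
        x = x.astype(np.float32)[..., None]
        c1, cc1 = _nn.conv2d_forward(x, p["w1"], p["b1"])
        r1, rm1 = _nn.relu_forward(c1)
        n1, cb1 = _nn.batchnorm_forward(r1, p["g1"], p["be1"], self.running["bn1"], training)
        d1, dm1 = _nn.dropout_forward(n1, cfg.conv_dropout_rate, rng, training)
        c2, cc2 = _nn.conv2d_forward(d1, p["w2"], p["b2"])
        r2, rm2 = _nn.relu_forward(c2)
        n2, cb2 = _nn.batchnorm_forward(r2, p["g2"], p["be2"], self.running["bn2"], training)
        pl, cp = _nn.maxpool2_forward(n2)
        flat = pl.reshape(pl.shape[0], -1)
        z3 = flat @ p["w3"] + p["b3"]
        n3, cb3 = _nn.batchnorm_forward(z3, p["g3"], p["be3"], self.running["bn3"], training)
        r3, rm3 = _nn.relu_forward(n3)
        d3, dm3 = _nn.dropout_forward(r3, cfg.dropout_rate, rng, training)
        logits = d3 @ p["w4"] + p["b4"]
        cache = (cc1, rm1, cb1, dm1, cc2, rm2, cb2, cp, flat, cb3, rm3, dm3, d3, pl.shape)
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache) -> dict:
        p = self.params
        cc1, rm1, cb1, dm1, cc2, rm2, cb2, cp, flat, cb3, rm3, dm3, d3, pl_shape = cache
        grads = {}
        grads["w4"] = d3.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dd3 = dlogits @ p["w4"].T
        dr3 = _nn.dropout_backward(dd3, dm3)
        dn3 = _nn.relu_backward(dr3, rm3)
        dz3, grads["g3"], grads["be3"] = _nn.batchnorm_backward(dn3, cb3)
        grads["w3"] = flat.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["w3"].T
        dpl = dflat.reshape(pl_shape)
        dn2 = _nn.maxpool2_backward(dpl, cp)
        dr2, grads["g2"], grads["be2"] = _nn.batchnorm_backward(dn2, cb2)
        dc2 = _nn.relu_backward(dr2, rm2)
        dd1, grads["w2"], grads["b2"] = _nn.conv2d_backward(dc2, cc2)
        dn1 = _nn.dropout_backward(dd1, dm1)
        dr1, grads["g1"], grads["be1"] = _nn.batchnorm_backward(dn1, cb1)
        dc1 = _nn.relu_backward(dr1, rm1)
        _, grads["w1"], grads["b1"] = _nn.conv2d_backward(dc1, cc1)
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits, _ = self.forward(x[i : i + batch_size], training=False)
            out.append(expit(logits.astype(np.float64).ravel()))
        return np.concatenate(out) if out else np.empty(0)

    # ------------------------------------------------------- persistence ----

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = dict(self.params)
        for bn, st in self.running.items():
            arrays[f"{bn}_mean"] = st["mean"]
            arrays[f"{bn}_var"] = st["var"]
        np.savez(path, **arrays)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"config": asdict(self.cfg)}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DetectorModel":
        path = Path(path)
        sidecar = path.with_suffix(".json")
        cfg_dict = json.loads(sidecar.read_text())["config"]
        cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
        model = cls(DetectorConfig(**cfg_dict))
        with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as z:
            for k in model.params:
                model.params[k] = z[k]
            for bn in model.running:
                model.running[bn] = {"mean": z[f"{bn}_mean"], "var": z[f"{bn}_var"]}
        return model


def build_model(cfg: DetectorConfig | None = None, seed: int = 0) -> DetectorModel:
    return DetectorModel(cfg or DetectorConfig(), np.random.default_rng(seed))


# ---------------------------------------------------------- augmentation ----

_PV_NFFT = 256
_PV_HOP = 64


def _stft(x: np.ndarray) -> np.ndarray:
    pad = _PV_NFFT // 2
    xp = np.pad(x, pad, mode="reflect")
    n_frames = 1 + (xp.size - _PV_NFFT) // _PV_HOP
    idx = np.arange(_PV_NFFT)[None, :] + _PV_HOP * np.arange(n_frames)[:, None]
    return np.fft.rfft(xp[idx] * np.hanning(_PV_NFFT)[None, :], axis=1).T


def _istft(s: np.ndarray, length: int) -> np.ndarray:
    win = np.hanning(_PV_NFFT)
    frames = np.fft.irfft(s.T, n=_PV_NFFT, axis=1) * win[None, :]
    n = _PV_NFFT + _PV_HOP * (frames.shape[0] - 1)
    out = np.zeros(n)
    norm = np.zeros(n)
    for t in range(frames.shape[0]):
        sl = slice(t * _PV_HOP, t * _PV_HOP + _PV_NFFT)
        out[sl] += frames[t]
        norm[sl] += win**2
    # floor the window-power normalization: edge frames with near-zero
    # overlap weight would otherwise amplify incoherent residue enormously
    out /= np.maximum(norm, 1e-2)
    pad = _PV_NFFT // 2
    return out[pad : pad + length]


def time_stretch(x: np.ndarray, rate: float) -> np.ndarray:
    """Phase-vocoder time stretch; output duration ~ len(x)/rate."""
    if rate <= 0:
        raise ContractError("stretch rate must be positive")
    s = _stft(x)
    n_bins, n_frames = s.shape
    steps = np.arange(0, n_frames - 1, rate)
    omega = 2 * np.pi * _PV_HOP * np.arange(n_bins) / _PV_NFFT
    out = np.zeros((n_bins, steps.size), dtype=complex)
    phase = np.angle(s[:, 0])
    for j, t in enumerate(steps):
        i = int(t)
        frac = t - i
        mag = (1 - frac) * np.abs(s[:, i]) + frac * np.abs(s[:, min(i + 1, n_frames - 1)])
        out[:, j] = mag * np.exp(1j * phase)
        dphi = np.angle(s[:, min(i + 1, n_frames - 1)]) - np.angle(s[:, i]) - omega
        dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
        phase += omega + dphi
    return _istft(out, int(round(x.size / rate)))


def pitch_shift(x: np.ndarray, semitones: float) -> np.ndarray:
    """Shift pitch keeping duration: stretch then resample back."""
    r = 2.0 ** (semitones / 12.0)
    y = time_stretch(x, 1.0 / r)
    return sps.resample(y, x.size)


def fit_length(x: np.ndarray, n: int) -> np.ndarray:
    """Center-crop or symmetrically zero-pad to exactly n samples."""
    if x.size == n:
        return x
    if x.size > n:
        start = (x.size - n) // 2
        return x[start : start + n]
    pad = n - x.size
    return np.pad(x, (pad // 2, pad - pad // 2))


def augment(
    seg: Segment,
    rng: np.random.Generator,
    noise_bank: list[np.ndarray] | None = None,
    augment_prob: float = 0.5,
    technique_prob: float = 0.5,
    gaussian_amplitude: float = 0.003,
) -> Segment:
    """Stochastic waveform augmentation; output is always fs samples long."""
    n = seg.samples.size
    if rng.random() >= augment_prob:
        return Segment(seg.samples.copy(), seg.index, seg.fs, seg.sensor_id, seg.start_time)
    x = seg.samples.copy()
    if rng.random() < technique_prob:
        x = pitch_shift(x, float(rng.uniform(-4.0, 4.0)))
    if rng.random() < technique_prob:
        x = fit_length(time_stretch(x, float(rng.uniform(0.8, 1.25))), n)
    if rng.random() < technique_prob:
        x = np.roll(x, int(round(float(rng.uniform(-0.5, 0.5)) * n)))
    if rng.random() < technique_prob:
        x = x + rng.normal(0.0, gaussian_amplitude, x.size)
    if rng.random() < technique_prob:
        if noise_bank:
            x = x + noise_bank[int(rng.integers(0, len(noise_bank)))][: x.size]
        else:
            warnings.warn("empty noise bank; real-noise mix skipped")
    x = fit_length(x, n)
    return Segment(x, seg.index, seg.fs, seg.sensor_id, seg.start_time)


# ------------------------------------------------------------- training ----

def _check_disjoint(*sets_of_segments: list[LabeledSegment]) -> None:
    seen: dict[str, int] = {}
    for i, group in enumerate(sets_of_segments):
        for ls in group:
            if ls.source_sensor in seen and seen[ls.source_sensor] != i:
                raise SplitLeakageError(
                    f"sensor {ls.source_sensor!r} appears in more than one split"
                )
            seen[ls.source_sensor] = i


def train(
    model: DetectorModel,
    train_set: list[LabeledSegment],
    val_set: list[LabeledSegment],
    cfg: DetectorConfig | None = None,
    seed: int = 0,
    noise_bank: list[np.ndarray] | None = None,
    use_augmentation: bool = True,
) -> tuple[DetectorModel, dict]:
    """Train with class-weighted BCE, per-epoch augmentation, and early
    stopping on validation loss; the best-validation parameters are restored.
    """
    cfg = cfg or model.cfg
    _check_disjoint(train_set, val_set)
    rng = np.random.default_rng(seed)
    n_pos = sum(1 for s in train_set if s.y == 1.0)
    n_neg = len(train_set) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ContractError("training set must contain both classes")
    pos_weight = (n_neg / n_pos) if cfg.class_weighting else 1.0

    y_train = np.array([s.y for s in train_set], dtype=np.float32)
    x_val = np.stack(
        [features_from_waveform(s.segment.samples, s.segment.fs) for s in val_set]
    )
    y_val = np.array([s.y for s in val_set], dtype=np.float32)
    base_feats = np.stack(
        [features_from_waveform(s.segment.samples, s.segment.fs) for s in train_set]
    )

    opt = _nn.Adam(model.params, lr=cfg.learning_rate)
    history = {"train_loss": [], "val_loss": [], "pos_weight": pos_weight}
    best_loss = np.inf
    best_params = None
    best_running = None
    patience_left = cfg.patience

    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start : start + cfg.batch_size]
            feats = []
            for i in batch_idx:
                if use_augmentation:
                    aug = augment(
                        train_set[i].segment,
                        rng,
                        noise_bank,
                        augment_prob=cfg.augment_prob,
                        technique_prob=cfg.technique_prob,
                    )
                    feats.append(features_from_waveform(aug.samples, aug.fs))
                else:
                    feats.append(base_feats[i])
            xb = np.stack(feats)
            yb = y_train[batch_idx]
            logits, cache = model.forward(xb, training=True, rng=rng)
            loss, dlogits = _nn.weighted_bce_with_logits(logits, yb, pos_weight)
            grads = model.backward(dlogits, cache)
            opt.step(model.params, grads)
            epoch_losses.append(loss)
        val_logits, _ = model.forward(x_val, training=False)
        val_loss, _ = _nn.weighted_bce_with_logits(val_logits, y_val, pos_weight)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_running = {
                bn: {k: v.copy() for k, v in st.items()}
                for bn, st in model.running.items()
            }
            patience_left = cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_params is not None:
        model.params = best_params
        model.running = best_running
    return model, history


# ------------------------------------------------------------ inference ----

def classify(
    model: DetectorModel, spec: Spectrogram | np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> DetectionResult:
    """Probability and thresholded label for one spectrogram (>= is insect)."""
    mags = spec.magnitudes if isinstance(spec, Spectrogram) else np.asarray(spec)
    index = spec.segment_index if isinstance(spec, Spectrogram) else 0
    if mags.shape != (129, 32):
        raise ContractError(f"expected 129x32 spectrogram, got {mags.shape}")
    x = features_from_spectrogram(mags)[None]
    prob = float(model.predict_proba(x)[0])
    return DetectionResult(index, prob, prob >= threshold)


def evaluate(model: DetectorModel, test_set: list[LabeledSegment]) -> dict:
    """AUC (rank formula), F1/precision/recall at threshold 0.5."""
    y = np.array([s.y for s in test_set])
    if len(np.unique(y)) < 2:
        raise ContractError("AUC undefined for a single-class test set")
    x = np.stack(
        [features_from_waveform(s.segment.samples, s.segment.fs) for s in test_set]
    )
    probs = model.predict_proba(x)
    return metrics_from_scores(y, probs)


def metrics_from_scores(
    y: np.ndarray, probs: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> dict:
    y = np.asarray(y, dtype=float)
    probs = np.asarray(probs, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("AUC undefined for a single-class set")
    ranks = rankdata(probs)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    pred = probs >= threshold
    tp = int(((y == 1) & pred).sum())
    fp = int(((y == 0) & pred).sum())
    fn = int(((y == 1) & ~pred).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "auc": float(auc),
        "f1": float(f1),
        "precision": float(precision),
        "recall": float(recall),
    }
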