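"""Ground-truth signal simulator.

Synthesizes electric-field style recordings as sums of harmonic wing-beat
stacks (fundamental plus geometrically decaying harmonics, slow Gaussian
frequency jitter, amplitude envelopes), optional mains interference with
harmonics, and broadband noise, quantized to 16-bit. Every generator is a
pure function of (spec, seed), and each scene returns a ground-truth table
so detection, F0 recovery, and aggregation can be scored without field data.

The per-frame frequency jitter is a mean-reverting fluctuation re-centred
on the nominal wing-beat frequency, so the realized mean F0 of an event
equals its ``true_wbf`` while varying enough to pass the sigma >= 1 Hz
keep-rule without drifting between adjacent seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError
from .signals import PCM_FULL_SCALE, Recording, write_recording

JITTER_FRAME_S = 0.032  # granularity of the wing-beat frequency fluctuation


@dataclass
class InsectEventSpec:
    true_wbf: float
    onset_s: float
    duration_s: float
    peak_amplitude: float = 0.05
    target_snr_db: float | None = None  # overrides peak_amplitude when set
    wbf_jitter_sd: float = 3.0  # stationary sd of the F0 fluctuation, Hz
    wbf_jitter_tau_s: float = 0.2  # mean-reversion time of the fluctuation
    n_harmonics: int = 4
    harmonic_decay: float = 0.6
    envelope: str = "hann"  # hann (floored) | gauss (approach-retreat) | flat

    def __post_init__(self) -> None:
        if not 20 < self.true_wbf < 2000:
            raise ContractError("true_wbf must lie in (20, 2000) Hz")
        if self.duration_s <= 0:
            raise ContractError("duration must be positive")


@dataclass
class SceneSpec:
    duration_s: float = 60.0
    fs: int = 4000
    events: list[InsectEventSpec] = field(default_factory=list)
    mains_hz: int | None = None
    mains_amplitude: float = 0.0
    mains_harmonics: int = 3
    noise_level: float = 0.001
    seed: int = 0
    sensor_id: str = "SIM0"
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.onset_s < 0 or ev.onset_s + ev.duration_s > self.duration_s:
                raise ContractError("event does not fit within the recording")


def _envelope(n: int, kind: str) -> np.ndarray:
    if kind == "gauss":
        t = np.linspace(-1, 1, n)
        return np.exp(-0.5 * (t / 0.35) ** 2)
    if kind == "flat":
        return np.ones(n)
    # raised cosine with a floor: annotated events are slices of a flight
    # path, so the field signature does not vanish at the annotation edges
    return 0.25 + 0.75 * np.hanning(n)


def _event_wave(ev: InsectEventSpec, fs: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-peak harmonic stack over the event duration."""
    n = int(round(ev.duration_s * fs))
    frame = max(2, int(round(JITTER_FRAME_S * fs)))
    n_steps = n // frame + 2
    # mean-reverting (OU) fluctuation about the insect's base WBF. A
    # drifting walk makes adjacent-second means diverge so the interval-
    # overlap merge criterion could never fire on genuine multi-second
    # events; uncorrelated per-frame noise is averaged away by the pitch
    # tracker's analysis frames and fails the sigma >= 1 Hz keep-rule.
    dt = JITTER_FRAME_S
    a = np.exp(-dt / ev.wbf_jitter_tau_s)
    innov = rng.normal(0.0, ev.wbf_jitter_sd * np.sqrt(1 - a * a), n_steps)
    steps = np.empty(n_steps)
    steps[0] = rng.normal(0.0, ev.wbf_jitter_sd)
    for k in range(1, n_steps):
        steps[k] = a * steps[k - 1] + innov[k]
    f = np.interp(np.arange(n) / frame, np.arange(n_steps), steps)
    # re-centre the realized per-sample track: time-averaged F0 == true_wbf
    f = np.maximum(ev.true_wbf + f - f.mean(), 5.0)
    phase = 2 * np.pi * np.cumsum(f) / fs + rng.uniform(0, 2 * np.pi)
    wave = np.zeros(n)
    for k in range(1, ev.n_harmonics + 1):
        wave += ev.harmonic_decay ** (k - 1) * np.sin(k * phase)
    wave *= _envelope(n, ev.envelope)
    peak = np.abs(wave).max()
    if peak > 0:
        wave /= peak
    return wave


def synth_recording(scene: SceneSpec) -> tuple[Recording, pd.DataFrame]:
    """Render a scene to a 16-bit recording plus its ground-truth table.

    Ground-truth columns: event_id, onset_s, duration_s, true_wbf,
    amplitude, snr_db. When the summed signal would clip, a warning is
    issued and the whole mix is peak-normalized to 0.99.
    """
    rng = np.random.default_rng(scene.seed)
    n = int(round(scene.duration_s * scene.fs))
    x = rng.normal(0.0, scene.noise_level, n)
    if scene.mains_hz:
        t = np.arange(n) / scene.fs
        for k in range(1, scene.mains_harmonics + 1):
            x += (scene.mains_amplitude / k) * np.sin(
                2 * np.pi * k * scene.mains_hz * t + rng.uniform(0, 2 * np.pi)
            )
    truth_rows = []
    for i, ev in enumerate(scene.events):
        wave = _event_wave(ev, scene.fs, rng)
        power = float(np.mean(wave**2))
        if ev.target_snr_db is not None and scene.noise_level > 0:
            amp = scene.noise_level * np.sqrt(10 ** (ev.target_snr_db / 10) / power)
        else:
            amp = ev.peak_amplitude
        start = int(round(ev.onset_s * scene.fs))
        x[start : start + wave.size] += amp * wave
        snr_db = (
            10 * np.log10((amp**2 * power) / scene.noise_level**2)
            if scene.noise_level > 0
            else np.inf
        )
        truth_rows.append(
            {
                "event_id": i,
                "onset_s": ev.onset_s,
                "duration_s": ev.duration_s,
                "true_wbf": ev.true_wbf,
                "amplitude": amp,
                "snr_db": snr_db,
            }
        )
    peak = np.abs(x).max()
    if peak >= 1.0:
        warnings.warn("synthesized scene clips; peak-normalizing to 0.99")
        x *= 0.99 / peak
    samples = np.clip(np.round(x * (PCM_FULL_SCALE - 1)), -32768, 32767).astype(np.int16)
    rec = Recording(
        samples=samples,
        fs=scene.fs,
        sensor_id=scene.sensor_id,
        start_time=scene.start_time or datetime(2024, 6, 17, tzinfo=timezone.utc),
    )
    return rec, pd.DataFrame(truth_rows)


def curate_annotation(
    onset_s: float, duration_s: float, recording_s: float
) -> list[float]:
    """Start times of 1-s training windows for one annotated event.

    Annotations of one second or longer are rounded down to whole seconds;
    shorter ones are symmetrically padded with adjacent signal, shifted
    inward when limited by the recording boundaries.
    """
    if duration_s >= 1.0:
        return [onset_s + i for i in range(int(np.floor(duration_s)))]
    pad = (1.0 - duration_s) / 2.0
    start = min(max(onset_s - pad, 0.0), recording_s - 1.0)
    return [start]


_NOISE_FLAVORS = ("white", "mains", "rumble", "clicks", "tone")


def _noise_scene(
    fs: int, rng: np.random.Generator, flavor: str, noise_level: float
) -> np.ndarray:
    """One second of labelled non-insect material."""
    n = fs
    x = rng.normal(0.0, noise_level, n)
    t = np.arange(n) / fs
    if flavor == "mains":
        f0 = rng.choice([50, 60])
        for k in range(1, 4):
            x += (rng.uniform(0.005, 0.05) / k) * np.sin(
                2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi)
            )
    elif flavor == "rumble":
        # wind-like low-frequency sway below the 20 Hz floor
        for _ in range(3):
            f = rng.uniform(1.0, 15.0)
            x += rng.uniform(0.01, 0.08) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    elif flavor == "clicks":
        for _ in range(rng.integers(1, 6)):
            pos = rng.integers(0, n - 40)
            width = rng.integers(4, 40)
            x[pos : pos + width] += rng.uniform(-0.3, 0.3)
    elif flavor == "tone":
        # rock-steady electrical whine (sigma < 1 Hz filter material)
        f = rng.uniform(100, 900)
        x += rng.uniform(0.01, 0.05) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return x


def synth_dataset(
    n_insect: int,
    n_noise: int,
    out_dir: str | Path | None,
    seed: int = 0,
    n_sensors: int = 6,
    wbf_range: tuple[float, float] = (50.0, 500.0),
    snr_range: tuple[float, float] = (10.0, 30.0),
    noise_level: float = 0.001,
    split_fractions: tuple[float, float, float] = (4 / 6, 1 / 6, 1 / 6),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Labelled, sensor-disjoint 1-s segment dataset.

    Returns (manifest, segments): the manifest has columns
    ``wav_path,segment_index,label,sensor_id,split`` and ``segments`` holds
    the corresponding normalized waveforms, row-aligned with the manifest.
    WAV files are written only when ``out_dir`` is given (one 1-s file per
    segment, named by the ``<sensor_id>_<ISO8601>`` convention).
    """
    if n_insect < 1 or n_noise < 1:
        raise ContractError("need at least one segment per class")
    if n_sensors < 3:
        raise ContractError("need >= 3 sensors for disjoint train/val/test")
    rng = np.random.default_rng(seed)
    fs = 4000
    sensors = [f"V{j:02d}" for j in range(n_sensors)]
    n_train = max(1, int(round(split_fractions[0] * n_sensors)))
    n_val = max(1, int(round(split_fractions[1] * n_sensors)))
    n_val = min(n_val, n_sensors - n_train - 1)
    split_of = {}
    for j, s in enumerate(sensors):
        split_of[s] = "train" if j < n_train else ("val" if j < n_train + n_val else "test")

    rows, waves = [], []
    t0 = datetime(2024, 6, 17, 4, 0, 0, tzinfo=timezone.utc)
    counter = 0

    def emit(wave: np.ndarray, label: str, sensor: str) -> None:
        nonlocal counter
        stamp = (t0 + timedelta(seconds=counter)).strftime("%Y-%m-%dT%H-%M-%S")
        name = f"{sensor}_{stamp}.wav"
        path = str(Path(out_dir) / name) if out_dir is not None else name
        rows.append(
            {
                "wav_path": path,
                "segment_index": 0,
                "label": label,
                "sensor_id": sensor,
                "split": split_of[sensor],
            }
        )
        waves.append(wave)
        if out_dir is not None:
            samples = np.clip(np.round(wave * (PCM_FULL_SCALE - 1)), -32768, 32767).astype(
                np.int16
            )
            write_recording(Recording(samples=samples, fs=fs, sensor_id=sensor), path)
        counter += 1

    made_insect = 0
    scene_seed = seed * 1_000_003
    while made_insect < n_insect:
        sensor = sensors[int(rng.integers(0, n_sensors))]
        duration = float(rng.uniform(0.5, 1.9))
        scene = SceneSpec(
            duration_s=3.0,
            events=[
                InsectEventSpec(
                    true_wbf=float(rng.uniform(*wbf_range)),
                    onset_s=0.8,
                    duration_s=duration,
                    target_snr_db=float(rng.uniform(*snr_range)),
                )
            ],
            noise_level=noise_level,
            seed=scene_seed,
            sensor_id=sensor,
        )
        scene_seed += 1
        rec, _ = synth_recording(scene)
        x = rec.normalized()
        for start in curate_annotation(0.8, duration, 3.0):
            if made_insect >= n_insect:
                break
            i0 = int(round(start * fs))
            emit(x[i0 : i0 + fs], "insect", sensor)
            made_insect += 1

    for _ in range(n_noise):
        sensor = sensors[int(rng.integers(0, n_sensors))]
        flavor = _NOISE_FLAVORS[int(rng.integers(0, len(_NOISE_FLAVORS)))]
        emit(_noise_scene(fs, rng, flavor, noise_level), "non-insect", sensor)

    manifest = pd.DataFrame(rows)
    return manifest, np.asarray(waves)


def synth_reference_table(
    n_dense: int,
    n_less_dense: int,
    n_sparse: int,
    seed: int = 0,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Synthetic WBF -> body-mass table with the three-region structure.

    When ``n_sparse >= 1`` the first sparse entry sits exactly at 480 Hz so
    the mosquito fallback is always resolvable. Masses are log-normal,
    Europe flags mixed, observation probabilities 1 (the placeholder regime).
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(wbf: float, log_mass_mean: float) -> None:
        rows.append(
            {
                "taxon": f"taxon_{len(rows):04d}",
                "wbf_hz": round(float(wbf), 2),
                "mass_mg": round(float(rng.lognormal(log_mass_mean, 0.9)), 4),
                "in_europe": bool(rng.random() < 0.8),
                "obs_prob": 1.0,
            }
        )

    for _ in range(n_dense):
        add(rng.uniform(20.0, 240.0), np.log(8.0))
    for _ in range(n_less_dense):
        add(rng.uniform(240.01, 340.0), np.log(4.0))
    if n_sparse >= 1:
        add(480.0, np.log(2.0))
    for _ in range(max(0, n_sparse - 1)):
        add(rng.uniform(340.01, 800.0), np.log(2.0))
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
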