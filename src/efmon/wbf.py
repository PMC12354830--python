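"""Wing-beat frequency estimation via probabilistic YIN.

For each insect-positive 1-s segment, short analysis frames (assumed
stationary) yield YIN fundamental-frequency candidates whose probabilities
come from a prior over difference-function thresholds; a Viterbi pass over a
log-spaced pitch grid with voiced/unvoiced states then decodes the most
likely F0 track. Per-segment statistics (mu_f0, sigma_f0) are computed over
voiced frames only, and segments failing the plausibility rules (mu < 20 Hz,
sigma < 1 Hz, sigma/mu indicating a drastically unstable track) are
discarded before event aggregation.

The estimator works internally at 4x the sensor rate so that short YIN lags
(high frequencies) retain sub-Hz precision after parabolic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import beta as beta_dist

from .errors import ContractError
from .signals import Segment

FMIN_HZ = 20.0
FMAX_HZ = 2000.0
FRAME_LENGTH = 1024  # at the sensor rate; scaled by the internal upsampling
HOP_LENGTH = 256
UPSAMPLE = 4

# pYIN threshold prior and HMM settings
_N_THRESHOLDS = 100
_BETA_A, _BETA_B = 2.0, 18.0
_NO_TROUGH_PROB = 0.01
_BINS_PER_SEMITONE = 4
_SWITCH_PROB = 0.01
_MAX_JUMP_SEMITONES = 8.0


@dataclass
class WbfSegment:
    """Per-segment F0 track and summary statistics."""

    index: int
    f0_track: np.ndarray  # Hz per frame, NaN where unvoiced
    voiced: np.ndarray  # boolean per frame
    mu_f0: float  # NaN when no voiced frame
    sigma_f0: float
    probability: float = 1.0  # detector probability carried through

    @property
    def has_estimate(self) -> bool:
        return bool(np.isfinite(self.mu_f0))


@dataclass
class WbfFilterConfig:
    mu_min_hz: float = 20.0
    sigma_min_hz: float = 1.0
    ratio_limit: float = 0.8
    #: discard when sigma/mu < ratio_limit instead of > (literal reading)
    ratio_as_printed: bool = False
    #: combine the three discard rules with "or" (default) or "and"
    combine: str = "or"


def _frame(x: np.ndarray, frame_length: int, hop: int) -> np.ndarray:
    """Centred framing with reflect padding; frame t centred at t*hop."""
    pad = frame_length // 2
    xp = np.pad(x, pad, mode="reflect")
    n_frames = 1 + x.size // hop
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    return xp[idx]


def _cmnd(frames: np.ndarray, tau_max: int) -> np.ndarray:
    """Cumulative-mean-normalized difference function per frame.

    d(tau) = sum_{j<W} (x_j - x_{j+tau})^2 with W = frame_length // 2,
    computed via FFT correlation; returned normalized, shape
    (n_frames, tau_max + 1), with d'(0) = 1.
    """
    n_frames, length = frames.shape
    w = length // 2
    if tau_max > length - w:
        raise ContractError("tau_max exceeds frame capacity")
    a = np.zeros_like(frames)
    a[:, :w] = frames[:, :w]
    fa = np.fft.rfft(a, n=length, axis=1)
    ff = np.fft.rfft(frames, n=length, axis=1)
    corr = np.fft.irfft(ff * np.conj(fa), n=length, axis=1)[:, : tau_max + 1]
    sq = np.concatenate(
        [np.zeros((n_frames, 1)), np.cumsum(frames**2, axis=1)], axis=1
    )
    # E_tau = sum_{j=tau}^{tau+w-1} x_j^2
    taus = np.arange(tau_max + 1)
    e_tau = sq[:, taus + w] - sq[:, taus]
    e0 = e_tau[:, :1]
    d = e0 + e_tau - 2.0 * corr
    d = np.maximum(d, 0.0)
    cum = np.cumsum(d[:, 1:], axis=1)
    cum = np.maximum(cum, 1e-300)
    out = np.ones_like(d)
    out[:, 1:] = d[:, 1:] * taus[1:] / cum
    return out


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a local-minimum index by fitting a parabola through its
    neighbours; returns (position, value)."""
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom <= 0:
        return float(i), float(b)
    shift = 0.5 * (a - c) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    value = b - 0.25 * (a - c) * shift
    return i + shift, float(value)


def _frame_candidates(
    cmnd_row: np.ndarray, tau_min: int, thresholds: np.ndarray, beta_cdf: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """YIN candidates (refined lags) and their probabilities for one frame.

    A trough is chosen by threshold t when it is the first trough below t;
    integrating the Beta prior over thresholds gives each trough's mass.
    Thresholds below every trough contribute ``_NO_TROUGH_PROB`` of their
    mass to the deepest trough.
    """
    d = cmnd_row
    interior = np.arange(tau_min + 1, d.size - 1)
    is_min = (d[interior] < d[interior - 1]) & (d[interior] <= d[interior + 1])
    troughs = interior[is_min]
    if troughs.size == 0:
        return np.empty(0), np.empty(0)
    lags = np.empty(troughs.size)
    vals = np.empty(troughs.size)
    for j, t in enumerate(troughs):
        lags[j], vals[j] = _parabolic_refine(d, t)
    vals = np.clip(vals, 0.0, None)
    probs = np.zeros(troughs.size)

    def cdf(v: float) -> float:
        # P(threshold <= v) under the Beta prior on the threshold grid
        i = np.searchsorted(thresholds, v, side="right")
        return float(beta_cdf[i - 1]) if i > 0 else 0.0

    running_min = np.inf
    for j in range(troughs.size):
        if vals[j] < running_min:
            # chosen for thresholds in (vals[j], running_min]
            probs[j] = cdf(min(running_min, 1.0)) - cdf(vals[j])
            running_min = vals[j]
    global_best = int(np.argmin(vals))
    probs[global_best] += _NO_TROUGH_PROB * cdf(min(running_min, 1.0))
    keep = probs > 0
    return lags[keep], probs[keep]


class _PitchGrid:
    """Log-spaced pitch bins with a banded transition kernel."""

    def __init__(self, fmin: float, fmax: float, bins_per_semitone: int):
        n_bins = int(np.ceil(12 * bins_per_semitone * np.log2(fmax / fmin))) + 1
        self.freqs = fmin * 2.0 ** (np.arange(n_bins) / (12 * bins_per_semitone))
        self.n_bins = n_bins
        max_jump = int(round(_MAX_JUMP_SEMITONES * bins_per_semitone))
        offsets = np.arange(-max_jump, max_jump + 1)
        kernel = 1.0 - np.abs(offsets) / (max_jump + 1)
        trans = np.zeros((n_bins, n_bins))
        for o, kv in zip(offsets, kernel):
            trans += kv * np.eye(n_bins, k=o)
        self.transition = trans / trans.sum(axis=1, keepdims=True)

    def bin_of(self, freq: float) -> int:
        return int(np.clip(np.round(
            12 * _BINS_PER_SEMITONE * np.log2(freq / self.freqs[0])
        ), 0, self.n_bins - 1))


def _viterbi(
    obs_voiced: np.ndarray, obs_unvoiced: np.ndarray, grid: _PitchGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Decode (voiced flags, bin indices) from per-frame observation probs.

    States are (voiced, bin) pairs; pitch transitions follow the banded
    kernel within each voicing state and voicing flips with a small
    switching probability.
    """
    n_frames, n_bins = obs_voiced.shape
    log_trans = np.log(grid.transition + 1e-300)
    log_stay = np.log1p(-_SWITCH_PROB)
    log_switch = np.log(_SWITCH_PROB)
    log_ov = np.log(obs_voiced + 1e-300)
    log_ou = np.log(obs_unvoiced + 1e-300)

    delta_v = np.full(n_bins, np.log(0.5 / n_bins)) + log_ov[0]
    delta_u = np.full(n_bins, np.log(0.5 / n_bins)) + log_ou[0]
    ptr_v = np.zeros((n_frames, n_bins, 2), dtype=np.int32)  # (src bin, src voicing)
    ptr_u = np.zeros((n_frames, n_bins, 2), dtype=np.int32)

    for t in range(1, n_frames):
        # best predecessor bin for each target bin, per source voicing
        cand_v = delta_v[:, None] + log_trans  # (src, dst)
        cand_u = delta_u[:, None] + log_trans
        best_v_src = np.argmax(cand_v, axis=0)
        best_u_src = np.argmax(cand_u, axis=0)
        best_v = cand_v[best_v_src, np.arange(n_bins)]
        best_u = cand_u[best_u_src, np.arange(n_bins)]

        to_v_from_v = best_v + log_stay
        to_v_from_u = best_u + log_switch
        take_v = to_v_from_v >= to_v_from_u
        new_delta_v = np.where(take_v, to_v_from_v, to_v_from_u) + log_ov[t]
        ptr_v[t, :, 0] = np.where(take_v, best_v_src, best_u_src)
        ptr_v[t, :, 1] = take_v.astype(np.int32)

        to_u_from_u = best_u + log_stay
        to_u_from_v = best_v + log_switch
        take_u = to_u_from_u >= to_u_from_v
        new_delta_u = np.where(take_u, to_u_from_u, to_u_from_v) + log_ou[t]
        ptr_u[t, :, 0] = np.where(take_u, best_u_src, best_v_src)
        ptr_u[t, :, 1] = 1 - take_u.astype(np.int32)

        delta_v, delta_u = new_delta_v, new_delta_u

    voiced = np.zeros(n_frames, dtype=bool)
    bins = np.zeros(n_frames, dtype=np.int32)
    if delta_v.max() >= delta_u.max():
        voiced[-1] = True
        bins[-1] = int(np.argmax(delta_v))
    else:
        voiced[-1] = False
        bins[-1] = int(np.argmax(delta_u))
    for t in range(n_frames - 1, 0, -1):
        ptr = ptr_v if voiced[t] else ptr_u
        src_bin = ptr[t, bins[t], 0]
        src_voiced = bool(ptr[t, bins[t], 1])
        bins[t - 1] = src_bin
        voiced[t - 1] = src_voiced
    return voiced, bins


def estimate_f0(
    seg: Segment,
    fmin: float = FMIN_HZ,
    fmax: float = FMAX_HZ,
    frame_length: int = FRAME_LENGTH,
    hop_length: int = HOP_LENGTH,
    detector_probability: float = 1.0,
) -> WbfSegment:
    """Probabilistic-YIN F0 track and (mu, sigma) for one 1-s segment."""
    x = np.asarray(seg.samples, dtype=np.float64)
    fs_up = seg.fs * UPSAMPLE
    xu = sps.resample_poly(x, UPSAMPLE, 1)
    frames = _frame(xu, frame_length * UPSAMPLE, hop_length * UPSAMPLE)
    tau_min = max(2, int(np.floor(fs_up / fmax)))
    tau_max = int(np.ceil(fs_up / fmin))
    cmnd = _cmnd(frames, tau_max)

    thresholds = np.linspace(0.01, 1.0, _N_THRESHOLDS)
    beta_cdf = beta_dist.cdf(thresholds, _BETA_A, _BETA_B)
    grid = _PitchGrid(fmin, fmax, _BINS_PER_SEMITONE)

    n_frames = frames.shape[0]
    obs_voiced = np.zeros((n_frames, grid.n_bins))
    obs_unvoiced = np.zeros((n_frames, grid.n_bins))
    frame_cands: list[tuple[np.ndarray, np.ndarray]] = []
    for t in range(n_frames):
        lags, probs = _frame_candidates(cmnd[t], tau_min, thresholds, beta_cdf)
        freqs = fs_up / lags if lags.size else lags
        ok = (freqs >= fmin) & (freqs <= fmax) if lags.size else np.empty(0, bool)
        freqs, probs = freqs[ok], probs[ok]
        frame_cands.append((freqs, probs))
        for f, p in zip(freqs, probs):
            obs_voiced[t, grid.bin_of(f)] += p
        residual = max(0.0, 1.0 - probs.sum())
        obs_unvoiced[t] = residual / grid.n_bins

    voiced, bins = _viterbi(obs_voiced, obs_unvoiced, grid)

    f0 = np.full(n_frames, np.nan)
    for t in range(n_frames):
        if not voiced[t]:
            continue
        target = grid.freqs[bins[t]]
        freqs, _ = frame_cands[t]
        if freqs.size:
            # snap to the nearest YIN candidate for sub-bin precision
            j = int(np.argmin(np.abs(np.log(freqs / target))))
            if abs(np.log2(freqs[j] / target)) < 1.5 / 12:
                f0[t] = freqs[j]
                continue
        f0[t] = target

    voiced_f0 = f0[np.isfinite(f0)]
    if voiced_f0.size:
        mu = float(voiced_f0.mean())
        sigma = float(voiced_f0.std(ddof=0))
    else:
        mu, sigma = float("nan"), float("nan")
    return WbfSegment(
        index=seg.index,
        f0_track=f0,
        voiced=voiced & np.isfinite(f0),
        mu_f0=mu,
        sigma_f0=sigma,
        probability=detector_probability,
    )


def passes_wbf_filter(w: WbfSegment, cfg: WbfFilterConfig | None = None) -> bool:
    """Apply the plausibility rules; True means the segment is kept.

    Default semantics discard a segment when mu_f0 < 20 Hz, OR
    sigma_f0 < 1 Hz, OR sigma_f0/mu_f0 > 0.8 (a drastically varying track).
    ``cfg.ratio_as_printed`` flips the ratio inequality and
    ``cfg.combine='and'`` requires all three rules to fire before discarding.
    """
    cfg = cfg or WbfFilterConfig()
    if not w.has_estimate:
        return False
    low_mu = w.mu_f0 < cfg.mu_min_hz
    low_sigma = w.sigma_f0 < cfg.sigma_min_hz
    ratio = w.sigma_f0 / w.mu_f0
    bad_ratio = ratio < cfg.ratio_limit if cfg.ratio_as_printed else ratio > cfg.ratio_limit
    if cfg.combine == "and":
        discard = low_mu and low_sigma and bad_ratio
    else:
        discard = low_mu or low_sigma or bad_ratio
    return not discard
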