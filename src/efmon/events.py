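"""Merging adjacent wing-beat segments into insect events.

Two index-adjacent segments are judged to come from the same insect when
their frequency intervals E_i = [mu - sigma/2, mu + sigma/2] overlap enough
(interval IoU >= 0.1) and their (mu, sigma) Gaussians are similar enough
(Bhattacharyya coefficient exp(-distance) >= 0.7). Merged chains are
summarised by inverse-variance weighting.

The similarity threshold is applied to the Bhattacharyya *coefficient*:
thresholding the distance from above at 0.7 would merge dissimilar
segments, since the distance is 0 for identical inputs. The literal
distance reading stays available behind ``bc_as_printed``. Likewise the
regrouped sigma defaults to the inverse-variance standard error
sqrt(1 / sum(1/sigma_i^2)); the printed sqrt(sum(1/sigma_i^2)) grows with
the number of members and is available behind ``sigma_as_printed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .wbf import WbfSegment

IOU_THRESHOLD = 0.1
BC_THRESHOLD = 0.7


@dataclass
class InsectEvent:
    """One insect crossing: consecutive merged segments."""

    member_indices: list[int]
    mu_regrouped: float
    sigma_regrouped: float
    start_s: float
    end_s: float  # half-open [start_s, end_s)
    recording_id: str = ""
    mass_mg: float | None = None

    @property
    def n_segments(self) -> int:
        return len(self.member_indices)


@dataclass
class PeriodAggregate:
    period_id: str
    count: int
    biomass_g: float
    start: object = None
    end: object = None


def interval_iou(w1: WbfSegment, w2: WbfSegment) -> float:
    """Intersection-over-union of E_i = [mu - sigma/2, mu + sigma/2].

    Zero-width intervals (sigma = 0) compare by exact mu equality.
    """
    lo1, hi1 = w1.mu_f0 - w1.sigma_f0 / 2, w1.mu_f0 + w1.sigma_f0 / 2
    lo2, hi2 = w2.mu_f0 - w2.sigma_f0 / 2, w2.mu_f0 + w2.sigma_f0 / 2
    if hi1 == lo1 and hi2 == lo2:
        return 1.0 if lo1 == lo2 else 0.0
    inter = max(0.0, min(hi1, hi2) - max(lo1, lo2))
    union = max(hi1, hi2) - min(lo1, lo2)
    if union <= 0:
        return 0.0
    return inter / union


def bhattacharyya_distance(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """Closed-form Bhattacharyya distance between two Gaussians."""
    if sigma1 <= 0 or sigma2 <= 0:
        raise ContractError("sigmas must be positive")
    var_sum = sigma1**2 + sigma2**2
    return 0.25 * (mu1 - mu2) ** 2 / var_sum + 0.5 * np.log(
        var_sum / (2.0 * sigma1 * sigma2)
    )


def bhattacharyya_coefficient(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """exp(-distance); 1 iff the distributions are identical, in (0, 1]."""
    return float(np.exp(-bhattacharyya_distance(mu1, sigma1, mu2, sigma2)))


def regroup(
    members: list[WbfSegment], sigma_as_printed: bool = False
) -> tuple[float, float]:
    """Inverse-variance weighted (mu, sigma) over merged segments."""
    if not members:
        raise ContractError("regroup needs at least one member")
    mus = np.array([m.mu_f0 for m in members])
    sigmas = np.array([m.sigma_f0 for m in members])
    if np.any(sigmas <= 0):
        raise ContractError("all member sigmas must be positive")
    weights = 1.0 / sigmas**2
    mu = float((mus * weights).sum() / weights.sum())
    if sigma_as_printed:
        sigma = float(np.sqrt(weights.sum()))
    else:
        sigma = float(np.sqrt(1.0 / weights.sum()))
    return mu, sigma


def _pair_merges(
    a: WbfSegment,
    b: WbfSegment,
    iou_threshold: float,
    bc_threshold: float,
    bc_as_printed: bool,
) -> bool:
    if interval_iou(a, b) < iou_threshold:
        return False
    dist = bhattacharyya_distance(a.mu_f0, a.sigma_f0, b.mu_f0, b.sigma_f0)
    if bc_as_printed:
        return dist >= bc_threshold
    return np.exp(-dist) >= bc_threshold


def aggregate_segments(
    kept: list[WbfSegment],
    iou_threshold: float = IOU_THRESHOLD,
    bc_threshold: float = BC_THRESHOLD,
    bc_as_printed: bool = False,
    sigma_as_printed: bool = False,
    recording_id: str = "",
) -> list[InsectEvent]:
    """Chain index-adjacent segments into events.

    Segment i+1 joins the running chain when it is index-adjacent to the
    chain's last raw segment and the pair passes both the IoU and the
    Bhattacharyya tests; each completed chain becomes one event with
    regrouped statistics. Non-adjacent segments never merge.
    """
    kept = sorted(kept, key=lambda w: w.index)
    events: list[InsectEvent] = []
    chain: list[WbfSegment] = []

    def flush() -> None:
        if not chain:
            return
        mu, sigma = regroup(chain, sigma_as_printed=sigma_as_printed)
        events.append(
            InsectEvent(
                member_indices=[w.index for w in chain],
                mu_regrouped=mu,
                sigma_regrouped=sigma,
                start_s=float(chain[0].index),
                end_s=float(chain[-1].index + 1),
                recording_id=recording_id,
            )
        )

    for w in kept:
        if chain and w.index == chain[-1].index + 1 and _pair_merges(
            chain[-1], w, iou_threshold, bc_threshold, bc_as_printed
        ):
            chain.append(w)
        else:
            flush()
            chain = [w]
    flush()
    return events


def aggregate_period(
    events: list[InsectEvent],
    periods: list[tuple[str, object, object]],
    event_times: list[object] | None = None,
) -> list[PeriodAggregate]:
    """Sum counts and biomass per trapping period.

    ``periods`` holds (id, start, end) with half-open [start, end); an event
    landing exactly on a boundary belongs to the later period. ``event_times``
    supplies each event's absolute timestamp (defaults to ``start_s`` treated
    on the same axis as the period bounds). Events outside all periods are
    dropped with a warning.
    """
    if event_times is None:
        event_times = [e.start_s for e in events]
    aggs = [
        PeriodAggregate(period_id=pid, count=0, biomass_g=0.0, start=s, end=e)
        for pid, s, e in periods
    ]
    for ev, t in zip(events, event_times):
        placed = False
        for agg in aggs:
            if agg.start <= t < agg.end:
                agg.count += 1
                agg.biomass_g += (ev.mass_mg or 0.0) / 1000.0
                placed = True
                break
        if not placed:
            warnings.warn(f"event at {t} falls outside all periods; dropped")
    return aggs
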