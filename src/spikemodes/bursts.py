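"""Burst-episode detection by an interval-threshold rule.

A cell counts as bursting when the analysis window contains at least
``min_bursts`` burst events of at least ``min_spikes_per_burst`` spikes each.
A burst episode is a maximal run of consecutive interevent intervals at or
below ``max_intraburst_iei_s``; the default 100-ms threshold sits well below
the 250–1000 ms tonic intervals of cells firing 1–4 Hz and well above typical
intra-burst intervals (~50 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trains import SpikeTrain, compute_ieis


@dataclass(frozen=True)
class BurstParams:
    max_intraburst_iei_s: float = 0.1
    min_spikes_per_burst: int = 3
    min_bursts: int = 3
    window_s: float = 180.0
    adaptive: bool = False  # threshold = 0.5 * median IEI instead of the fixed value

    def __post_init__(self) -> None:
        if self.max_intraburst_iei_s <= 0 or self.window_s <= 0:
            raise ValueError("thresholds and window must be positive")
        if self.min_spikes_per_burst < 2:
            raise ValueError("min_spikes_per_burst must be at least 2")
        if self.min_bursts < 1:
            raise ValueError("min_bursts must be at least 1")


@dataclass(frozen=True)
class BurstEpisode:
    first_index: int
    last_index: int
    n_spikes: int
    duration_s: float
    start_s: float
    end_s: float


@dataclass(frozen=True)
class BurstAnnotation:
    episodes: list[BurstEpisode]
    is_bursting: bool
    tonic_fraction: float
    params: BurstParams

    @property
    def n_bursts(self) -> int:
        return len(self.episodes)


@dataclass(frozen=True)
class BurstStats:
    n_bursts: int
    mean_burst_duration_s: float
    mean_spikes_per_burst: float
    mean_interburst_interval_s: float | None


class NoBurstsError(ValueError):
    """Burst statistics requested for an annotation without episodes."""


def detect_bursts(train: SpikeTrain, params: BurstParams | None = None) -> BurstAnnotation:
    """Annotate maximal sub-threshold IEI runs as burst episodes.

    Empty or single-spike trains yield no episodes and ``is_bursting=False``.
    """
    params = params or BurstParams()
    times = train.times
    n = times.size
    if n < params.min_spikes_per_burst:
        return BurstAnnotation([], False, 1.0 if n else 0.0, params)

    ieis = compute_ieis(train)
    threshold = params.max_intraburst_iei_s
    if params.adaptive:
        threshold = 0.5 * float(np.median(ieis))
    below = ieis <= threshold

    episodes: list[BurstEpisode] = []
    i = 0
    while i < below.size:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < below.size and below[j]:
            j += 1
        # spikes i..j span j - i + 1 spikes
        n_spk = j - i + 1
        if n_spk >= params.min_spikes_per_burst:
            episodes.append(
                BurstEpisode(
                    first_index=i,
                    last_index=j,
                    n_spikes=n_spk,
                    duration_s=float(times[j] - times[i]),
                    start_s=float(times[i]),
                    end_s=float(times[j]),
                )
            )
        i = j

    in_burst = sum(e.n_spikes for e in episodes)
    tonic_fraction = 1.0 - in_burst / n
    return BurstAnnotation(
        episodes=episodes,
        is_bursting=len(episodes) >= params.min_bursts,
        tonic_fraction=tonic_fraction,
        params=params,
    )


def burst_stats(annotation: BurstAnnotation, train: SpikeTrain) -> BurstStats:
    """Arithmetic means of burst duration, spikes per burst, and inter-burst interval.

    The inter-burst interval runs from the last spike of one episode to the
    first spike of the next.
    """
    eps = annotation.episodes
    if not eps:
        raise NoBurstsError("annotation contains no burst episodes")
    ibis = [
        float(train.times[eps[k + 1].first_index] - train.times[eps[k].last_index])
        for k in range(len(eps) - 1)
    ]
    return BurstStats(
        n_bursts=len(eps),
        mean_burst_duration_s=float(np.mean([e.duration_s for e in eps])),
        mean_spikes_per_burst=float(np.mean([e.n_spikes for e in eps])),
        mean_interburst_interval_s=float(np.mean(ibis)) if ibis else None,
    )
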