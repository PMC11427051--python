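"""Spike-train containers, analysis-window selection, and interevent-interval statistics.

The raw object of every computation here is a cell-attached recording reduced to
spike event times. Physiology convention: a 3-min stable analysis window follows a
3-min equilibration period, cells firing below 0.5 Hz are discarded, and spike-timing
variability is summarised by the coefficient of variation (CV) of the interevent
interval (IEI) distribution, SD/mean.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class Region(str, enum.Enum):
    NAC_CORE = "NAc_core"
    NAC_SHELL = "NAc_shell"
    UNKNOWN = "unknown"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Estrous(str, enum.Enum):
    PROESTRUS = "proestrus"
    ESTRUS = "estrus"
    METESTRUS = "metestrus"
    DIESTRUS = "diestrus"
    NA = "NA"


class Treatment(str, enum.Enum):
    NONE = "none"
    FSS_1WK = "FSS_1wk"
    FSS_2WK = "FSS_2wk"


class Drug(str, enum.Enum):
    VEHICLE = "vehicle"
    CRF = "CRF"
    APAMIN = "apamin"
    NONE = "none"


class InsufficientRecordingError(ValueError):
    """Recording shorter than equilibration + analysis window."""


class UndefinedCVError(ValueError):
    """CV requested for fewer than two interevent intervals."""


@dataclass(frozen=True)
class CellMeta:
    """Per-cell experimental covariates."""

    cell_id: str
    region: Region = Region.UNKNOWN
    sex: Sex = Sex.UNKNOWN
    estrous: Estrous = Estrous.NA
    treatment: Treatment = Treatment.NONE
    drug: Drug = Drug.NONE
    concentration_nM: float = 0.0

    def __post_init__(self) -> None:
        if self.sex != Sex.FEMALE and self.estrous != Estrous.NA:
            raise ValueError("estrous stage only applies to female cells")
        if self.concentration_nM < 0:
            raise ValueError("concentration_nM must be non-negative")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (seconds) inside a half-open window [t0, t0 + duration).

    Times are strictly increasing and absolute (not re-referenced to the window
    start unless explicitly requested when slicing).
    """

    times: np.ndarray
    t0: float = 0.0
    duration: float = 180.0
    meta: CellMeta = field(default_factory=lambda: CellMeta(cell_id="cell"))

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if t.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if t[0] < self.t0 or t[-1] >= self.t0 + self.duration:
                raise ValueError("spike times must lie within [t0, t0 + duration)")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class IEISummary:
    """Firing rate and IEI statistics for one analysis window."""

    n_spikes: int
    rate_hz: float
    iei_mean: float
    iei_sd: float
    cv: float | None
    histogram: list[tuple[float, float, int]]


def select_analysis_window(
    train: SpikeTrain,
    equilibration_s: float = 180.0,
    window_s: float = 180.0,
    rereference: bool = False,
) -> SpikeTrain:
    """Slice out the stable analysis window following the equilibration period.

    The returned train covers [t0 + equilibration, t0 + equilibration + window)
    and keeps absolute spike times unless ``rereference`` is set.
    """
    if train.duration < equilibration_s + window_s:
        raise InsufficientRecordingError(
            f"recording of {train.duration:g} s cannot supply "
            f"{equilibration_s:g} s equilibration + {window_s:g} s window"
        )
    start = train.t0 + equilibration_s
    end = start + window_s
    kept = train.times[(train.times >= start) & (train.times < end)]
    if rereference:
        kept = kept - start
        start = 0.0
    return replace(train, times=kept, t0=start, duration=window_s)


def compute_ieis(train: SpikeTrain | Sequence[float]) -> np.ndarray:
    """Interevent intervals (seconds) between consecutive spikes."""
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("spike times must be strictly increasing")
    return np.diff(times)


def firing_rate(train: SpikeTrain) -> float:
    """Mean number of spikes per second over the train's window."""
    return train.n_spikes / train.duration


def cv_iei(ieis: Sequence[float], ddof: int = 1) -> float:
    """Coefficient of variation of the IEIs: SD divided by the mean.

    ``ddof=1`` (sample SD) is the default convention; set ``ddof=0`` for the
    population SD. Raises :class:`UndefinedCVError` below two intervals.
    """
    x = np.asarray(ieis, dtype=float)
    if x.size < 2:
        raise UndefinedCVError("CV needs at least two interevent intervals")
    return float(np.std(x, ddof=ddof) / np.mean(x))


def exclude_low_rate(
    cohort: Sequence[SpikeTrain], min_hz: float = 0.5
) -> tuple[list[SpikeTrain], list[SpikeTrain]]:
    """Partition a cohort into (kept, discarded) by the firing-rate floor.

    Cells with rates strictly less than ``min_hz`` are discarded; a cell at
    exactly the floor is kept.
    """
    kept = [t for t in cohort if firing_rate(t) >= min_hz]
    discarded = [t for t in cohort if firing_rate(t) < min_hz]
    return kept, discarded


def iei_histogram(
    ieis: Sequence[float], bin_width_s: float = 0.05
) -> list[tuple[float, float, int]]:
    """Left-closed right-open histogram of IEIs with bins anchored at zero."""
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    x = np.asarray(ieis, dtype=float)
    if x.size == 0:
        return []
    n_bins = int(np.floor(x.max() / bin_width_s)) + 1
    edges = np.arange(n_bins + 1) * bin_width_s
    idx = np.minimum((x // bin_width_s).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return [
        (float(edges[i]), float(edges[i + 1]), int(counts[i])) for i in range(n_bins)
    ]


def summarize(train: SpikeTrain, bin_width_s: float = 0.05, ddof: int = 1) -> IEISummary:
    """Full per-window IEI summary: rate, IEI mean/SD, CV, histogram."""
    ieis = compute_ieis(train)
    cv: float | None
    if ieis.size >= 2:
        cv = cv_iei(ieis, ddof=ddof)
        iei_mean = float(np.mean(ieis))
        iei_sd = float(np.std(ieis, ddof=ddof))
    else:
        cv = None
        iei_mean = float(np.mean(ieis)) if ieis.size else float("nan")
        iei_sd = float("nan")
    return IEISummary(
        n_spikes=train.n_spikes,
        rate_hz=firing_rate(train),
        iei_mean=iei_mean,
        iei_sd=iei_sd,
        cv=cv,
        histogram=iei_histogram(ieis, bin_width_s),
    )
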