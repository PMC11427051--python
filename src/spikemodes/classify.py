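"""Four-way firing-mode classification from (bursting flag, rate, CV).

The decision tree mirrors how tonically active striatal neurons are sorted in
cell-attached work: bursting is the gate, then spike-timing variability splits
the non-bursting cells and the tonic-spike fraction splits the bursting ones.

    bursting?
      yes -> tonic_fraction >= tonic_fraction_mixed_min -> mixed_mode
             otherwise                                 -> rhythmic_bursting
      no  -> cv < cv_regular_max -> regular
             otherwise           -> irregular

Non-bursting cells with CV above the usual irregular band (0.65) still land in
``irregular`` (bursting is the only gate to the bursting labels); the rule
trace marks them out-of-band.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .bursts import BurstAnnotation
from .trains import UndefinedCVError


class FiringMode(str, enum.Enum):
    REGULAR = "regular"
    IRREGULAR = "irregular"
    RHYTHMIC = "rhythmic_bursting"
    MIXED = "mixed_mode"


#: canonical class order used by proportion vectors throughout the package
MODE_ORDER: tuple[FiringMode, ...] = (
    FiringMode.REGULAR,
    FiringMode.IRREGULAR,
    FiringMode.RHYTHMIC,
    FiringMode.MIXED,
)


@dataclass(frozen=True)
class ClassifierParams:
    cv_regular_max: float = 0.30
    tonic_fraction_mixed_min: float = 0.40

    def __post_init__(self) -> None:
        if not (0 < self.cv_regular_max < 1):
            raise ValueError("cv_regular_max must lie in (0, 1)")
        if not (0 < self.tonic_fraction_mixed_min < 1):
            raise ValueError("tonic_fraction_mixed_min must lie in (0, 1)")


@dataclass(frozen=True)
class FiringClassLabel:
    label: FiringMode
    rate_hz: float
    cv: float
    is_bursting: bool
    tonic_fraction: float
    rule_trace: tuple[str, ...]


class FiringModeClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based firing-mode classifier with the sklearn estimator interface.

    Parameters
    ----------
    cv_regular_max : float, default 0.30
        Non-bursting cells with CV below this are regular; at or above,
        irregular. 0.30 is the lower edge of the irregular CV band.
    tonic_fraction_mixed_min : float, default 0.40
        Bursting cells whose fraction of spikes outside burst episodes reaches
        this are mixed mode; below it, rhythmic bursting.

    The classifier is a fixed decision rule, so :meth:`fit` only validates and
    records the class list. ``predict`` accepts an array-like or DataFrame with
    columns ``(is_bursting, rate_hz, cv, tonic_fraction)``.
    """

    def __init__(self, cv_regular_max: float = 0.30, tonic_fraction_mixed_min: float = 0.40):
        self.cv_regular_max = cv_regular_max
        self.tonic_fraction_mixed_min = tonic_fraction_mixed_min

    _FEATURES = ("is_bursting", "rate_hz", "cv", "tonic_fraction")

    def _params(self) -> ClassifierParams:
        return ClassifierParams(self.cv_regular_max, self.tonic_fraction_mixed_min)

    def fit(self, X=None, y=None) -> "FiringModeClassifier":
        self._params()  # validate
        self.classes_ = np.array([m.value for m in MODE_ORDER], dtype=object)
        return self

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X[list(self._FEATURES)]
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("X must have columns (is_bursting, rate_hz, cv, tonic_fraction)")
        return pd.DataFrame(arr, columns=list(self._FEATURES))

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "classes_"):
            self.fit()
        df = self._as_frame(X)
        out = [
            classify(
                rate_hz=row.rate_hz,
                cv=row.cv,
                is_bursting=bool(row.is_bursting),
                tonic_fraction=row.tonic_fraction,
                params=self._params(),
            ).label.value
            for row in df.itertuples()
        ]
        return np.asarray(out, dtype=object)


def classify(
    rate_hz: float,
    cv: float | None,
    is_bursting: bool | BurstAnnotation,
    tonic_fraction: float | None = None,
    params: ClassifierParams | None = None,
) -> FiringClassLabel:
    """Assign one firing-mode label with an auditable rule trace.

    ``is_bursting`` may be a :class:`BurstAnnotation`, in which case the flag
    and tonic fraction are read from it.
    """
    params = params or ClassifierParams()
    if isinstance(is_bursting, BurstAnnotation):
        ann = is_bursting
        bursting, tonic = ann.is_bursting, ann.tonic_fraction
    else:
        bursting = bool(is_bursting)
        tonic = float(tonic_fraction) if tonic_fraction is not None else 0.0
    if cv is None or not np.isfinite(cv):
        raise UndefinedCVError("cannot classify a cell with undefined CV")

    trace: list[str] = []
    if bursting:
        trace.append("bursting: >= min_bursts burst events in window")
        if tonic >= params.tonic_fraction_mixed_min:
            trace.append(
                f"tonic_fraction {tonic:.3f} >= {params.tonic_fraction_mixed_min:g} -> mixed_mode"
            )
            label = FiringMode.MIXED
        else:
            trace.append(
                f"tonic_fraction {tonic:.3f} < {params.tonic_fraction_mixed_min:g} -> rhythmic_bursting"
            )
            label = FiringMode.RHYTHMIC
    else:
        trace.append("non-bursting: fewer than min_bursts burst events")
        if cv < params.cv_regular_max:
            trace.append(f"cv {cv:.3f} < {params.cv_regular_max:g} -> regular")
            label = FiringMode.REGULAR
        else:
            trace.append(f"cv {cv:.3f} >= {params.cv_regular_max:g} -> irregular")
            label = FiringMode.IRREGULAR
            if cv > 0.65:
                trace.append("cv above the usual irregular band (0.65); out-of-band")
    return FiringClassLabel(
        label=label,
        rate_hz=float(rate_hz),
        cv=float(cv),
        is_bursting=bursting,
        tonic_fraction=tonic,
        rule_trace=tuple(trace),
    )


@dataclass(frozen=True)
class ProportionTable:
    """Per-stratum firing-mode counts and fractions (class order = MODE_ORDER)."""

    strata: tuple[str, ...]
    counts: dict[str, np.ndarray]

    @property
    def fractions(self) -> dict[str, np.ndarray]:
        out = {}
        for s, c in self.counts.items():
            total = c.sum()
            out[s] = c / total if total else np.zeros_like(c, dtype=float)
        return out

    def n(self, stratum: str = "all") -> int:
        return int(self.counts[stratum].sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        fracs = self.fractions
        for s in self.strata:
            for mode, cnt, frac in zip(MODE_ORDER, self.counts[s], fracs[s]):
                rows.append({"stratum": s, "mode": mode.value, "count": int(cnt), "fraction": frac})
        return pd.DataFrame(rows)


def classify_cohort(
    cells: pd.DataFrame,
    params: ClassifierParams | None = None,
    stratify_by: str | None = None,
) -> tuple[pd.DataFrame, ProportionTable]:
    """Classify every cell in a feature frame and tabulate mode proportions.

    ``cells`` needs columns (is_bursting, rate_hz, cv, tonic_fraction); any
    extra columns (metadata) pass through to the labelled output.
    """
    params = params or ClassifierParams()
    clf = FiringModeClassifier(
        params.cv_regular_max, params.tonic_fraction_mixed_min
    ).fit()
    labelled = cells.copy()
    labelled["label"] = clf.predict(cells)

    def _count(df: pd.DataFrame) -> np.ndarray:
        vc = df["label"].value_counts()
        return np.array([int(vc.get(m.value, 0)) for m in MODE_ORDER])

    strata = ["all"]
    counts = {"all": _count(labelled)}
    if stratify_by is not None:
        for key, grp in labelled.groupby(stratify_by, sort=True):
            strata.append(str(key))
            counts[str(key)] = _count(grp)
    return labelled, ProportionTable(strata=tuple(strata), counts=counts)
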