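"""Phenomenological neuromodulation operators and response metrics.

CRF (corticotropin releasing factor) potentiates tonically active cholinergic
interneuron firing through CRF-R1 and shifts firing modes toward regular
pacemaking; apamin (sK channel blocker) does the opposite, pushing every cell
toward rhythmic bursting while leaving the mean rate unchanged. Neither
mechanism is modelled biophysically: drugs act as parameter transforms on the
generator specs plus a row-stochastic transition matrix over firing modes.

Response metrics follow the slice-pharmacology conventions: the drug response
is the firing rate over the last minutes of application expressed as percent
of the baseline-window rate, and the CV change is the plain difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats as sstats

from .classify import MODE_ORDER, FiringMode
from .synth import (
    CalibrationTarget,
    MixedSpec,
    ModeGeneratorSpec,
    RhythmicSpec,
    TonicSpec,
    calibrate_mixed,
    calibrate_rhythmic,
    calibrate_tonic,
)
from .trains import SpikeTrain


_MODE_INDEX = {m: i for i, m in enumerate(MODE_ORDER)}


@dataclass(frozen=True)
class ModulationSpec:
    """Drug operator: per-class rate multipliers, CV deltas, mode transitions.

    ``rate_multiplier`` and ``cv_delta`` map firing mode -> effect at this
    concentration; ``transition`` is a 4x4 row-stochastic matrix in canonical
    class order giving the probability that a cell of row-class switches to
    column-class under the drug. ``rate_exponent`` adds the observed inverse
    dependence of the CRF response on baseline rate
    (multiplier scales by (rate_ref / rate)^exponent).
    """

    drug: str
    concentration_nM: float = 0.0
    rate_multiplier: dict[FiringMode, float] = field(
        default_factory=lambda: {m: 1.0 for m in MODE_ORDER}
    )
    cv_delta: dict[FiringMode, float] = field(
        default_factory=lambda: {m: 0.0 for m in MODE_ORDER}
    )
    transition: np.ndarray = field(default_factory=lambda: np.eye(4))
    rate_exponent: float = 0.0
    rate_ref_hz: float = 2.5
    response_noise_cv: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "transition", t)
        if t.shape != (4, 4) or np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1) > 1e-9):
            raise ValueError("transition must be 4x4 row-stochastic")
        if any(v <= 0 for v in self.rate_multiplier.values()):
            raise ValueError("rate multipliers must be positive")


def vehicle_spec() -> ModulationSpec:
    """Identity operator: no rate, CV, or mode change."""
    return ModulationSpec(drug="vehicle")


#: which classes respond to CRF at each concentration (qualitative sensitivity
#: pattern: 3 nM regular+irregular; 10 nM all but rhythmic; 100 nM all), with
#: response magnitudes as free configuration
_CRF_RESPONDERS = {
    3.0: (FiringMode.REGULAR, FiringMode.IRREGULAR),
    10.0: (FiringMode.REGULAR, FiringMode.IRREGULAR, FiringMode.MIXED),
    100.0: tuple(MODE_ORDER),
}
_CRF_MAGNITUDE = {3.0: 1.25, 10.0: 1.4, 100.0: 1.6}


def crf_spec(
    concentration_nM: float = 100.0,
    transition: np.ndarray | None = None,
    response_noise_cv: float = 0.15,
) -> ModulationSpec:
    """Default CRF operator at 3, 10 or 100 nM.

    At 100 nM the mode-transition matrix should be supplied from
    :func:`fit_transition_matrix` on observed pre/post distributions;
    otherwise it defaults to identity (rate/CV effects only).
    """
    if concentration_nM not in _CRF_RESPONDERS:
        raise ValueError("CRF operator is parameterised at 3, 10 and 100 nM")
    responders = _CRF_RESPONDERS[concentration_nM]
    mult = {
        m: _CRF_MAGNITUDE[concentration_nM] if m in responders else 1.0 for m in MODE_ORDER
    }
    delta = {m: 0.0 for m in MODE_ORDER}
    if concentration_nM >= 10.0:
        delta[FiringMode.IRREGULAR] = -0.10  # CRF regularises irregular cells
    return ModulationSpec(
        drug="CRF",
        concentration_nM=concentration_nM,
        rate_multiplier=mult,
        cv_delta=delta,
        transition=np.eye(4) if transition is None else transition,
        # the CRF response falls steeply with baseline rate (strong negative
        # semi-log correlation); fast pacemakers are barely potentiated
        rate_exponent=0.5,
        response_noise_cv=response_noise_cv,
    )


def apamin_spec() -> ModulationSpec:
    """Apamin operator: every mode transitions to rhythmic bursting."""
    t = np.zeros((4, 4))
    t[:, _MODE_INDEX[FiringMode.RHYTHMIC]] = 1.0
    return ModulationSpec(drug="apamin", concentration_nM=150.0, transition=t)


_CV_FLOOR = 0.05


def _spec_stats(spec: ModeGeneratorSpec) -> tuple[float, float, FiringMode]:
    """Nominal (rate, CV) a generator spec was calibrated for."""
    if isinstance(spec, TonicSpec):
        return spec.rate_hz, spec.shape**-0.5, spec.mode
    if isinstance(spec, RhythmicSpec):
        nb, ps = spec.n_spikes_per_burst, spec.p_single
        f = (1 - ps) * (nb - 1) / ((1 - ps) * (nb - 1) + 1)
        m = f * spec.intra_iei_s + (1 - f) * spec.interburst_mean_s
        from .synth import _rhythmic_mixture_cv

        return 1.0 / m, _rhythmic_mixture_cv(f, m, spec), spec.mode
    if isinstance(spec, MixedSpec):
        nb = spec.n_spikes_per_burst
        burst_rate = nb / ((nb - 1) * spec.intra_iei_s + spec.gap_s)
        w_b = spec.dwell_burst_s / (spec.dwell_burst_s + spec.dwell_tonic_s)
        rate = (1 - w_b) * spec.tonic_rate_hz + w_b * burst_rate
        # CV recovered through the mixed calibration's own mixture model
        from .synth import _MIXED_TONIC_FRACTION

        tf = _MIXED_TONIC_FRACTION
        f_t, f_i, f_g = tf, (1 - tf) * (nb - 1) / nb, (1 - tf) / nb
        m = f_t / spec.tonic_rate_hz + f_i * spec.intra_iei_s + f_g * spec.gap_s
        var = (
            f_t * ((1 / spec.tonic_rate_hz - m) ** 2 + (1 / spec.tonic_rate_hz) ** 2 / spec.tonic_shape)
            + f_i * ((spec.intra_iei_s - m) ** 2 + (spec.intra_iei_s * spec.intra_cv) ** 2)
            + f_g * ((spec.gap_s - m) ** 2 + (spec.gap_s * spec.gap_cv) ** 2)
        )
        return rate, float(np.sqrt(var) / m), spec.mode
    raise TypeError(type(spec).__name__)


def apply_modulation(
    mod: ModulationSpec,
    spec: ModeGeneratorSpec,
    mode: FiringMode | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[ModeGeneratorSpec, FiringMode]:
    """Transform one cell's generator under a drug operator.

    The new firing mode is drawn from the transition-matrix row for the cell's
    current mode; the generator is then recalibrated for that mode at the
    rate scaled by the class multiplier (with any inverse-rate dependence and
    per-cell response noise) and the CV shifted by the class delta, floored at
    a small positive value. The identity (vehicle) operator returns the spec
    unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate, cv, spec_mode = _spec_stats(spec)
    mode = mode or spec_mode
    row = mod.transition[_MODE_INDEX[mode]]
    new_mode = MODE_ORDER[rng.choice(4, p=row)] if not np.allclose(row, np.eye(4)[_MODE_INDEX[mode]]) else mode

    mult = mod.rate_multiplier[mode]
    if mod.rate_exponent:
        mult = mult * (mod.rate_ref_hz / rate) ** mod.rate_exponent
    if mod.response_noise_cv:
        mult = mult * float(rng.lognormal(0.0, mod.response_noise_cv))
    new_rate = rate * mult
    new_cv = max(cv + mod.cv_delta[mode], _CV_FLOOR)

    if mult == 1.0 and new_cv == cv and new_mode == mode:
        return spec, mode

    if new_mode != mode:
        # a class switch re-draws the cell from the destination-class
        # distributions, which describe the post-drug state directly; the
        # within-class multiplier is not stacked on top
        from .synth import sample_cell_targets

        tgt = sample_cell_targets(new_mode, rng)[0]
        new_rate, new_cv = float(tgt[0]), float(tgt[1])
        if mod.drug == "apamin":
            new_rate = rate  # apamin preserves the cell's own rate
    if new_mode in (FiringMode.REGULAR, FiringMode.IRREGULAR):
        target = CalibrationTarget(
            new_mode, new_rate, float(np.clip(new_cv, _CV_FLOOR, 0.64))
        )
        new_spec: ModeGeneratorSpec = calibrate_tonic(target)
    elif new_mode == FiringMode.RHYTHMIC:
        # the burst-pause family needs a mean IEI above the intra-burst interval
        target = CalibrationTarget(new_mode, min(new_rate, 12.0), max(new_cv, _CV_FLOOR))
        new_spec = calibrate_rhythmic(target)
    else:
        # the switching family cannot exceed its bursting-state rate
        target = CalibrationTarget(new_mode, min(new_rate, 8.5), max(new_cv, _CV_FLOOR))
        new_spec = calibrate_mixed(target)
    return new_spec, new_mode


def percent_baseline(
    baseline: SpikeTrain, drug: SpikeTrain, last_min: float = 3.0
) -> float:
    """Drug response as percent of baseline firing.

    The rate over the final ``last_min`` minutes of the drug window is divided
    by the baseline-window rate, x100.
    """
    base_rate = baseline.n_spikes / baseline.duration
    if base_rate == 0:
        raise ValueError("baseline rate is zero; percent baseline undefined")
    window = last_min * 60.0
    if drug.duration < window:
        raise ValueError("drug window shorter than the averaging window")
    start = drug.t0 + drug.duration - window
    n = int(np.count_nonzero(drug.times >= start))
    return 100.0 * (n / window) / base_rate


def delta_cv(baseline_cv: float, drug_cv: float) -> float:
    """CV change under drug; regularisation is negative."""
    return drug_cv - baseline_cv


def fit_transition_matrix(
    pre_counts, post_counts, max_iter: int = 5000, tol: float = 1e-12
) -> tuple[np.ndarray, float]:
    """Least-squares row-stochastic transition matrix between mode distributions.

    Minimises ||pre^T T - post^T||^2 over row-stochastic T by projected
    gradient descent (Euclidean projection of each row onto the simplex),
    starting from the identity. Classes absent pre-drug keep identity rows.
    Returns (T, residual).
    """
    pre = np.asarray(pre_counts, dtype=float)
    post = np.asarray(post_counts, dtype=float)
    if pre.shape != (4,) or post.shape != (4,):
        raise ValueError("pre and post must be 4-vectors in canonical class order")
    if np.any(pre < 0) or np.any(post < 0):
        raise ValueError("counts must be non-negative")
    p = pre / pre.sum()
    q = post / post.sum()

    T = np.eye(4)
    zero_rows = np.where(p == 0)[0]
    lr = 0.9 / max(np.dot(p, p), 1e-12)
    prev = np.inf
    for _ in range(max_iter):
        r = p @ T - q
        resid = float(r @ r)
        if prev - resid < tol:
            break
        prev = resid
        grad = np.outer(p, r)
        T = T - lr * grad
        for i in range(4):
            T[i] = _project_simplex(T[i])
        T[zero_rows] = np.eye(4)[zero_rows]
    resid = float(np.sum((p @ T - q) ** 2))
    return T, resid


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / (np.arange(v.size) + 1) > 0)[0][-1]
    theta = (1.0 - css[rho]) / (rho + 1)
    return np.maximum(v + theta, 0.0)


@dataclass(frozen=True)
class ResponseMetrics:
    cell_id: str
    baseline_rate_hz: float
    pct_baseline: float
    delta_cv: float
    class_pre: str
    class_post: str


def concentration_response(cells) -> tuple[float, float, float, float]:
    """Semi-log fit of the drug response against baseline rate.

    ``cells`` is a sequence of (baseline_rate_hz, pct_baseline) pairs. Returns
    (slope, intercept, r, p) for ordinary least squares of pct_baseline on
    log10(baseline rate); r is the signed Pearson correlation.
    """
    arr = np.asarray(list(cells), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least three (rate, response) pairs")
    rates, resp = arr[:, 0], arr[:, 1]
    if np.any(rates <= 0):
        raise ValueError("baseline rates must be positive")
    x = np.log10(rates)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in baseline rates")
    res = sstats.linregress(x, resp)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)
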