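"""Analysis of single-channel and macroscopic current records.

Covers the electrophysiology side of the study: ordinary-least-squares I-V
fitting (slope conductance and reversal potential), chord conductance,
half-amplitude threshold idealization of two-level single-channel traces,
dwell-weighted unitary-current estimation, channel counting from macroscopic
conductance, single-exponential inactivation fits, whole-cell current-change
rates, and Welch t-test group comparison with Bonferroni adjustment.

Units: currents in pA, voltages in mV, conductances in pS (1 pA/mV = 1 nS =
1000 pS), times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "IVSeries",
    "ConductanceFit",
    "AmplitudeEstimate",
    "InactivationFit",
    "DwellSegment",
    "fit_linear_iv",
    "chord_conductance",
    "idealize_half_amplitude",
    "mean_unitary_current",
    "estimate_channel_count",
    "percent_change",
    "fit_exponential_inactivation",
    "current_change_rate",
    "compare_groups",
]


@dataclass
class IVSeries:
    """Current-voltage pairs: (Vm mV, I pA)."""

    points: Sequence[tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        pts = [(float(v), float(i)) for v, i in self.points]
        if len({v for v, _ in pts}) < 2:
            raise ValueError("need at least 2 distinct voltages")
        self.points = pts

    @property
    def v_mV(self) -> np.ndarray:
        return np.array([v for v, _ in self.points])

    @property
    def i_pA(self) -> np.ndarray:
        return np.array([i for _, i in self.points])


@dataclass
class ConductanceFit:
    slope_pS: float
    erev_mV: float
    slope_se_pS: float
    erev_se_mV: float
    r2: float


@dataclass
class AmplitudeEstimate:
    mean_i_pA: float
    sd_pA: float
    n_events: int


@dataclass
class InactivationFit:
    tau_s: float
    amplitude_pA: float
    offset_pA: float
    rmse_pA: float
    flagged: bool = False
    note: str = ""


@dataclass
class DwellSegment:
    level: int           # 0 closed, 1 open
    start: int           # first sample index
    n_samples: int


def fit_linear_iv(series: IVSeries) -> ConductanceFit:
    """OLS line through an I-V series; Erev = −intercept/slope, slope in pS."""
    v, i = series.v_mV, series.i_pA
    res = stats.linregress(v, i)
    slope_nS = res.slope
    if abs(slope_nS) < 1e-12:
        raise ValueError("zero slope: reversal potential undefined")
    erev = -res.intercept / slope_nS
    # delta-method s.e. for −b/a with OLS standard errors
    with np.errstate(invalid="ignore"):
        erev_se = abs(erev) * math.sqrt(
            (res.stderr / slope_nS) ** 2
            + ((res.intercept_stderr / res.intercept) ** 2
               if res.intercept != 0 else 0.0))
    return ConductanceFit(slope_pS=slope_nS * 1000.0, erev_mV=erev,
                          slope_se_pS=res.stderr * 1000.0,
                          erev_se_mV=float(erev_se),
                          r2=res.rvalue ** 2)


def chord_conductance(i_pA: float, v_mV: float, erev_mV: float) -> float:
    """Chord conductance I/(V − Erev) in pS."""
    dv = v_mV - erev_mV
    if dv == 0:
        raise ValueError("V equals Erev: chord conductance undefined")
    return i_pA / dv * 1000.0


def _mode_baseline(samples: np.ndarray, nbins: int = 200) -> float:
    """Baseline as the mode of the all-points histogram."""
    counts, edges = np.histogram(samples, bins=nbins)
    j = int(np.argmax(counts))
    return 0.5 * (edges[j] + edges[j + 1])


def idealize_half_amplitude(samples, amplitude_pA: float,
                            baseline_pA: float | None = None,
                            min_dwell_samples: int = 2) -> list[DwellSegment]:
    """Half-amplitude threshold idealization of a two-level trace.

    Threshold at baseline + amplitude/2 (sign-aware); dwells shorter than
    ``min_dwell_samples`` are merged into their neighbours.  The returned
    segments partition the trace.  When no baseline is given it is estimated
    as the mode of the all-points histogram.
    """
    if amplitude_pA == 0:
        raise ValueError("amplitude must be nonzero")
    if min_dwell_samples < 1:
        raise ValueError("min_dwell_samples must be >= 1")
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        return []
    if baseline_pA is None:
        baseline_pA = _mode_baseline(x)
    thr = baseline_pA + amplitude_pA / 2.0
    state = (x > thr) if amplitude_pA > 0 else (x < thr)
    state = state.astype(np.int8)

    # iteratively absorb runs shorter than min_dwell into neighbours
    while True:
        bounds = np.flatnonzero(np.diff(state)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [state.size]])
        lengths = ends - starts
        if lengths.size <= 1:
            break
        short = np.flatnonzero(lengths < min_dwell_samples)
        if short.size == 0:
            break
        j = short[int(np.argmin(lengths[short]))]
        state[starts[j]:ends[j]] = 1 - state[starts[j]]
    bounds = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [state.size]])
    return [DwellSegment(int(state[s]), int(s), int(e - s))
            for s, e in zip(starts, ends)]


def mean_unitary_current(samples, segments: list[DwellSegment]) -> AmplitudeEstimate:
    """Dwell-weighted unitary current from an idealized trace.

    mean_i = mean(open-level samples) − mean(closed-level samples); the sd is
    that of per-opening amplitudes about the global closed mean, and n_events
    counts the openings.  Invariant to a constant baseline offset.
    """
    x = np.asarray(samples, dtype=float)
    open_segs = [s for s in segments if s.level == 1]
    closed_segs = [s for s in segments if s.level == 0]
    if not open_segs:
        raise ValueError("no openings detected")
    if not closed_segs:
        raise ValueError("no closed-level samples to reference against")
    open_idx = np.concatenate([np.arange(s.start, s.start + s.n_samples)
                               for s in open_segs])
    closed_idx = np.concatenate([np.arange(s.start, s.start + s.n_samples)
                                 for s in closed_segs])
    closed_mean = x[closed_idx].mean()
    mean_i = x[open_idx].mean() - closed_mean
    per_event = np.array([x[s.start:s.start + s.n_samples].mean() - closed_mean
                          for s in open_segs])
    sd = float(per_event.std(ddof=1)) if per_event.size > 1 else 0.0
    return AmplitudeEstimate(float(mean_i), sd, len(open_segs))


def estimate_channel_count(macro_conductance_pS: float,
                           unitary_conductance_pS: float) -> int:
    """Number of channels = round(macroscopic / unitary), half away from zero."""
    if unitary_conductance_pS <= 0:
        raise ValueError("unitary conductance must be positive")
    q = macro_conductance_pS / unitary_conductance_pS
    return int(math.floor(q + 0.5)) if q >= 0 else -int(math.floor(-q + 0.5))


def percent_change(before: float, after: float) -> float:
    """100 × (after − before)/before."""
    if before == 0:
        raise ValueError("undefined for a zero reference value")
    return 100.0 * (after - before) / before


def fit_exponential_inactivation(t_s, i_pA, fit_window: tuple[float, float] | None = None
                                 ) -> InactivationFit:
    """Least-squares fit of I(t) = A·exp(−t/tau) + C to a decaying sweep.

    Non-decaying input (A ≤ 0 or tau at the search bound) is returned flagged
    rather than raised, with the best fit found.
    """
    t = np.asarray(t_s, dtype=float)
    i = np.asarray(i_pA, dtype=float)
    if fit_window is not None:
        lo, hi = fit_window
        if lo < t.min() - 1e-12 or hi > t.max() + 1e-12:
            raise ValueError("fit window outside the sweep")
        m = (t >= lo) & (t <= hi)
        t, i = t[m], i[m]
    if t.size < 10:
        raise ValueError("need at least 10 samples in the fit window")
    t0 = t - t[0]
    span = t0[-1] if t0[-1] > 0 else 1.0
    a0 = i[0] - i[-1]
    c0 = i[-1]
    tau_hi = 100.0 * span
    if abs(a0) < 1e-12:
        resid = i - i.mean()
        return InactivationFit(tau_s=tau_hi, amplitude_pA=0.0,
                               offset_pA=float(i.mean()),
                               rmse_pA=float(np.sqrt(np.mean(resid ** 2))),
                               flagged=True, note="non-decaying (flat) sweep")
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
            t0, i, p0=[a0, span / 3.0, c0],
            bounds=([-np.inf, 1e-9 * span, -np.inf], [np.inf, tau_hi, np.inf]),
            maxfev=10000)
        a, tau, c = popt
    except RuntimeError:
        return InactivationFit(tau_s=tau_hi, amplitude_pA=float(a0),
                               offset_pA=float(c0), rmse_pA=float("inf"),
                               flagged=True, note="fit did not converge")
    resid = i - (a * np.exp(-t0 / tau) + c)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    flagged = a <= 0 or tau >= 0.99 * tau_hi
    note = "non-decaying data" if flagged else ""
    return InactivationFit(float(tau), float(a), float(c), rmse, flagged, note)


def current_change_rate(peak_series) -> float:
    """OLS slope (pA/s) of a per-pulse peak-current series [(t_s, i_pA), ...]."""
    pts = np.asarray(peak_series, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (t, I) points")
    res = stats.linregress(pts[:, 0], pts[:, 1])
    return float(res.slope)


def compare_groups(sample_a, sample_b, adjustment: str = "bonferroni",
                   n_comparisons: int = 1):
    """Two-sided Welch t-test with multiplicity adjustment.

    Returns ``(t, p_two_sided, p_adjusted)``.  Bonferroni multiplies p by the
    number of comparisons, capped at 1.  Two identical zero-variance samples
    give t = 0, p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if adjustment == "bonferroni":
        p_adj = min(1.0, p * n_comparisons)
    elif adjustment in (None, "none"):
        p_adj = p
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return float(t), float(p), float(p_adj)
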