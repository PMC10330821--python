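"""Normalization and Hill-equation fitting of light-scattering flux assays.

Vesicles loaded with KCl report chloride efflux as a valinomycin-triggered
drop in light scattering; an inhibitor (extravesicular Cl⁻ acting on the
driving force, or the blocker DIDS) reduces the plateau amplitude.  The
fractional response follows the Hill relation

    I([L]) = 1 / (1 + ([L]/k_D)^n),

strictly decreasing in ligand concentration with midpoint k_D and
cooperativity n.  Fitting is nonlinear least squares over (log k_D, log n)
with a multi-start log-spaced grid, bounds k_D ∈ [1e-6, 1e3] input units and
n ∈ [0.1, 10]; an optional case-resampling bootstrap gives percentile CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["HillFit", "hill_response", "fit_hill", "flux_amplitude",
           "dose_response_from_traces"]

KD_BOUNDS = (1e-6, 1e3)
N_BOUNDS = (0.1, 10.0)
RESPONSE_CLIP = (0.0, 1.05)


@dataclass
class HillFit:
    kD: float
    n: float
    rss: float
    ci_kD: tuple[float, float] | None = None
    ci_n: tuple[float, float] | None = None
    n_boot: int = 0


def hill_response(L, kD: float, n: float):
    """Fractional response 1/(1 + (L/kD)^n); 1 at L = 0, 0.5 at L = kD."""
    if kD <= 0 or n <= 0:
        raise ValueError("kD and n must be positive")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("concentrations must be non-negative")
    out = np.empty_like(L, dtype=float)
    pos = L > 0
    out[pos] = 1.0 / (1.0 + (L[pos] / kD) ** n)
    out[~pos] = 1.0
    return out if out.ndim else float(out)


def _fit_once(L, y, log_kd0, log_n0):
    res = least_squares(
        lambda p: 1.0 / (1.0 + np.exp(np.exp(p[1])
                                      * (np.log(np.maximum(L, 1e-300))
                                         - p[0]))) - y,
        x0=[log_kd0, log_n0],
        bounds=([np.log(KD_BOUNDS[0]), np.log(N_BOUNDS[0])],
                [np.log(KD_BOUNDS[1]), np.log(N_BOUNDS[1])]))
    return res.x, float(res.cost * 2)  # cost is 0.5*rss


def _best_fit(L, y) -> tuple[float, float, float]:
    # L = 0 rows carry no information about (kD, n) beyond the intercept of 1,
    # which the model satisfies identically; keep them in the residuals anyway.
    grid = np.log(np.geomspace(max(L[L > 0].min(), KD_BOUNDS[0]),
                               min(L.max(), KD_BOUNDS[1]), 7))
    best = None
    for lk in grid:
        for ln in (np.log(0.5), 0.0, np.log(2.0)):
            p, rss = _fit_once(L, y, lk, ln)
            if best is None or rss < best[1]:
                best = (p, rss)
    (lk, ln), rss = best
    return float(np.exp(lk)), float(np.exp(ln)), rss


def fit_hill(table: pd.DataFrame, n_boot: int = 0, seed: int = 0) -> HillFit:
    """Fit the Hill equation to a dose-response table.

    ``table`` needs columns ``ligand`` and ``response`` (``replicate`` is
    optional and used only for bootstrap resampling).  Responses are clipped
    to [0, 1.05] before fitting; at least 3 distinct concentrations are
    required and all-identical responses are rejected as unidentifiable.
    """
    L = table["ligand"].to_numpy(dtype=float)
    y = np.clip(table["response"].to_numpy(dtype=float), *RESPONSE_CLIP)
    if np.unique(L).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.allclose(y, y[0]):
        raise ValueError("all responses identical: kD and n unidentifiable")
    kd, n, rss = _best_fit(L, y)
    fit = HillFit(kd, n, rss)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        kds, ns = [], []
        idx = np.arange(L.size)
        for _ in range(n_boot):
            take = rng.choice(idx, idx.size, replace=True)
            if np.unique(L[take]).size < 3 or np.allclose(y[take], y[take][0]):
                continue
            k_b, n_b, _ = _best_fit(L[take], y[take])
            kds.append(k_b)
            ns.append(n_b)
        if kds:
            fit.ci_kD = tuple(np.percentile(kds, [2.5, 97.5]))
            fit.ci_n = tuple(np.percentile(ns, [2.5, 97.5]))
            fit.n_boot = len(kds)
    return fit


def _baseline_plateau(trace: pd.DataFrame) -> tuple[float, float]:
    """Baseline = mean of the pre-trigger (t < 0) window, else first 10%;
    plateau = mean of the final 10% of samples."""
    t = trace["t_s"].to_numpy(dtype=float)
    s = trace["signal"].to_numpy(dtype=float)
    pre = s[t < 0]
    baseline = pre.mean() if pre.size else s[: max(1, s.size // 10)].mean()
    plateau = s[-max(1, s.size // 10):].mean()
    return float(baseline), float(plateau)


def flux_amplitude(trace: pd.DataFrame, control_trace: pd.DataFrame,
                   reference_amplitude: float | None = None) -> float:
    """Control-subtracted scattering amplitude of one flux trace.

    Amplitude = (baseline − plateau) of the trace minus the same quantity for
    the solvent control; if a reference amplitude (the zero-inhibitor
    condition of the series) is given, the result is normalized by it.
    Negative control-corrected amplitudes are clipped to 0.
    """
    if len(trace) != len(control_trace) or not np.allclose(
            trace["t_s"].to_numpy(), control_trace["t_s"].to_numpy()):
        raise ValueError("trace and control must share a time base")
    b, p = _baseline_plateau(trace)
    bc, pc = _baseline_plateau(control_trace)
    amp = (b - p) - (bc - pc)
    if amp < 0:
        amp = 0.0
    if reference_amplitude is not None:
        if reference_amplitude <= 0:
            raise ValueError("reference amplitude must be positive")
        amp /= reference_amplitude
    return float(amp)


def dose_response_from_traces(traces: dict, control_key=("control", 0)
                              ) -> pd.DataFrame:
    """Build a normalized dose-response table from per-concentration traces.

    ``traces`` maps ``(ligand_concentration, replicate)`` to
    DataFrame(t_s, signal), with a solvent control under ``control_key``.
    Amplitudes are normalized to the mean amplitude of the lowest
    concentration present (the closest available zero-inhibitor condition).
    """
    control = traces[control_key]
    keys = [k for k in traces if k != control_key]
    if not keys:
        raise ValueError("no flux traces besides the control")
    raw = {k: flux_amplitude(traces[k], control) for k in keys}
    concs = sorted({k[0] for k in keys})
    ref = np.mean([raw[k] for k in keys if k[0] == concs[0]])
    if ref <= 0:
        raise ValueError("zero-inhibitor reference amplitude is not positive")
    rows = [{"ligand": k[0], "response": raw[k] / ref, "replicate": k[1]}
            for k in keys]
    return pd.DataFrame(rows).sort_values(["ligand", "replicate"],
                                          ignore_index=True)
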