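"""Seeded generators for every input the analysis stages consume.

Each generator emulates one class of raw data from the study system —
immunogold micrographs of insulin-granule fields, two-level single-channel
bilayer traces with optional slow inactivation, valinomycin-triggered
light-scattering flux decays under Hill-type inhibition, fluorescent
surface-puncta images, and depolarization-evoked stepwise whole-cell
conductance growth — together with a ground-truth record of what was drawn.

Determinism: every generator takes a single integer seed; substreams are
derived per granule / trace / replicate with ``numpy.random.SeedSequence``
so identical parameters and seed give byte-identical outputs and partial
regeneration is stable.

Immunogold field model
----------------------
Granule radii are truncated-normal (mean 90 nm, s.d. 40, bounds 40-220 nm;
mean diameter ≈ 196 nm).  Expected label counts per granule scale with the
granule cross-section, rate x (R/98)^2 — larger granules carry more labels.
Insulin labels sit in the dense core: center offset s is half-normal
(s.d. 12 nm) and the membrane distance is d = R − s.  CHGB labels are a
shell/core mixture: with probability 0.48 the label is membrane-proximal
(truncated normal, mean 25 nm, s.d. 16, bounds [−20 nm, R]); otherwise it
follows the same core model as insulin.  Gold labels are rendered as dark
anti-aliased disks (6 nm insulin-class, 12 nm CHGB-class) on a bright noisy
background, 16-bit EM contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .immunogold import GranuleRing, Micrograph

__all__ = [
    "TruncatedNormal",
    "EMFieldParams",
    "ChannelSimParams",
    "FluxSimParams",
    "SecretionSimParams",
    "SingleChannelTrace",
    "make_em_field",
    "make_em_dataset",
    "make_puncta_image",
    "make_channel_trace",
    "make_macroscopic_sweeps",
    "make_flux_series",
    "make_whole_cell_session",
]

MAX_FIELD_PX = 9.0e7  # pixel budget guarding against absurd field requests


@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated normal distribution spec (units of the caller)."""

    mean: float
    sd: float
    lower: float
    upper: float

    def sample(self, rng: np.random.Generator, n: int,
               upper: float | None = None) -> np.ndarray:
        """Draw n values; an optional per-call upper bound overrides the spec's."""
        hi = self.upper if upper is None else min(self.upper, upper)
        a = (self.lower - self.mean) / self.sd
        b = (hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


@dataclass(frozen=True)
class EMFieldParams:
    """Generative model of one immunogold micrograph field."""

    n_granules: int = 324
    radius_model: TruncatedNormal = TruncatedNormal(90.0, 40.0, 40.0, 220.0)
    chgb_count_rate: float = 3.0       # mean CHGB labels/granule at R = 98 nm
    insulin_count_rate: float = 8.0    # mean insulin labels/granule at R = 98 nm
    shell_weight: float = 0.48         # P(CHGB label is membrane-proximal)
    shell_model: TruncatedNormal = TruncatedNormal(25.0, 16.0, -20.0, math.inf)
    core_offset_sigma: float = 12.0    # half-normal s.d. of center offset (nm)
    gold_diameter_insulin: float = 6.0
    gold_diameter_chgb: float = 12.0
    nm_per_px: float = 1.0
    noise_sd: float = 800.0            # background intensity s.d. (16-bit counts)
    background: float = 30000.0
    gold_depth: float = 20000.0        # how much darker gold is than background
    ring_vertices: int = 64
    label_gap_nm: float = 0.25    # minimum clearance between gold bead surfaces
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_granules < 0:
            raise ValueError("n_granules must be non-negative")
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class ChannelSimParams:
    """Two-level single-channel simulation with optional slow inactivation."""

    unitary_conductance_pS: float = 110.0
    reversal_mV: float = -49.0
    n_channels: int = 1
    open_rate: float = 2.0             # s^-1, closed -> open
    close_rate: float = 2.0            # s^-1, open -> closed
    noise_sd_pA: float = 0.3
    tau_inact_s: float | None = None   # irreversible inactivation time constant
    sample_interval_s: float = 1e-3
    voltage_protocol: tuple = ((0.0, 2.0),)   # (level mV, duration s)
    start_open: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unitary_conductance_pS <= 0:
            raise ValueError("unitary conductance must be positive")
        if self.open_rate < 0 or self.close_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.noise_sd_pA < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tau_inact_s is not None and self.tau_inact_s <= 0:
            raise ValueError("tau_inact must be positive")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval must be positive")
        for _, dur in self.voltage_protocol:
            if dur <= 0:
                raise ValueError("protocol durations must be positive")


@dataclass(frozen=True)
class FluxSimParams:
    """Light-scattering flux assay under Hill-type inhibition."""

    ligand_concentrations: tuple = tuple(np.logspace(-2, 1, 8))  # mM
    kD_true: float = 0.47              # mM (chloride self-inhibition default)
    n_true: float = 1.0
    amplitude: float = 0.4             # fractional scattering drop at zero inhibitor
    tau_flux_s: float = 20.0
    replicate_count: int = 3
    noise_sd: float = 0.02             # s.d. on the normalized amplitude
    trace_noise_sd: float = 0.002      # per-sample scattering noise
    baseline: float = 1.0
    t_pre_s: float = 10.0
    t_post_s: float = 100.0
    dt_s: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        if len(self.ligand_concentrations) == 0:
            raise ValueError("empty concentration list")
        if any(c < 0 for c in self.ligand_concentrations):
            raise ValueError("concentrations must be non-negative")
        if self.kD_true <= 0 or self.n_true <= 0:
            raise ValueError("kD_true and n_true must be positive")

    @classmethod
    def chloride_defaults(cls, seed: int = 1) -> "FluxSimParams":
        """Extravesicular chloride titration (kD 0.47 mM, n 1.0)."""
        return cls(seed=seed)

    @classmethod
    def dids_defaults(cls, seed: int = 1) -> "FluxSimParams":
        """DIDS block titration (kD 0.43 uM, n 1.0); concentrations in uM."""
        return cls(ligand_concentrations=tuple(np.logspace(-2, 1, 8)),
                   kD_true=0.43, seed=seed)


@dataclass(frozen=True)
class SecretionSimParams:
    """Depolarization-evoked stepwise whole-cell conductance growth."""

    pulse_rate_hz: float = 1.0
    fusion_rate_per_pulse: float = 0.93   # mean fusion events per pulse
    conductance_per_event_nS: float = 0.1
    erev_mV: float = -62.0
    leak_pA: float = 350.0
    calcium_present: bool = True
    chloride_present: bool = True
    duration_s: float = 300.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.pulse_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rates and duration must be positive")
        if self.fusion_rate_per_pulse < 0:
            raise ValueError("fusion rate must be non-negative")
        if self.conductance_per_event_nS <= 0:
            raise ValueError("conductance increments must be positive")


@dataclass
class SingleChannelTrace:
    """Uniformly sampled current record."""

    samples_pA: np.ndarray
    sample_interval_s: float
    holding_mV: float
    meta: dict = field(default_factory=dict)

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.samples_pA.size) * self.sample_interval_s


# ---------------------------------------------------------------------------
# immunogold fields
# ---------------------------------------------------------------------------

def _field_layout(params: EMFieldParams):
    margin = 60.0
    cell = 2 * params.radius_model.upper + 60.0
    ncols = max(1, int(math.ceil(math.sqrt(params.n_granules))))
    nrows = max(1, int(math.ceil(params.n_granules / ncols)))
    w_nm = ncols * cell + 2 * margin
    h_nm = nrows * cell + 2 * margin
    return margin, cell, ncols, nrows, w_nm, h_nm


def _render_disk(pixels: np.ndarray, x_nm: float, y_nm: float, diam_nm: float,
                 depth: float, nm_per_px: float) -> None:
    """Subtract an anti-aliased dark disk; coverage via a linear edge ramp."""
    r = diam_nm / 2.0 / nm_per_px
    x, y = x_nm / nm_per_px, y_nm / nm_per_px
    x0 = max(0, int(x - r - 2)); x1 = min(pixels.shape[1], int(x + r + 3))
    y0 = max(0, int(y - r - 2)); y1 = min(pixels.shape[0], int(y + r + 3))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rho = np.hypot(xx + 0.5 - x, yy + 0.5 - y)
    cov = np.clip(0.5 + (r - rho), 0.0, 1.0)
    pixels[y0:y1, x0:x1] -= depth * cov


def make_em_field(params: EMFieldParams = EMFieldParams()):
    """Generate one synthetic immunogold field.

    Returns ``(micrograph, rings, truth)``: a 16-bit micrograph, circular
    granule-ring annotations (regular polygons at each granule boundary), and
    a ground-truth table with one row per gold label
    (id, class, x_nm, y_nm, d_nm, ring_id).

    Granules are laid out on a jittered grid sized so neighbouring granules
    (and their 20-nm analysis extensions) can never collide; every generated
    distance satisfies −20 <= d <= R of its granule.
    """
    margin, cell, ncols, nrows, w_nm, h_nm = _field_layout(params)
    shape = (int(round(h_nm / params.nm_per_px)), int(round(w_nm / params.nm_per_px)))
    if shape[0] * shape[1] > MAX_FIELD_PX:
        raise ValueError(
            f"granule placement failed: field of {params.n_granules} granules "
            f"needs {shape[0]}x{shape[1]} px (> {MAX_FIELD_PX:.0f} budget); "
            "split into several fields with make_em_dataset")

    ss = np.random.SeedSequence(params.seed)
    noise_stream, *granule_streams = ss.spawn(params.n_granules + 1)
    noise_rng = np.random.default_rng(noise_stream)

    pixels = (params.background
              + params.noise_sd
              * noise_rng.standard_normal(shape, dtype=np.float32))

    rings: list[GranuleRing] = []
    rows: list[dict] = []
    theta_ring = np.linspace(0, 2 * math.pi, params.ring_vertices, endpoint=False)
    pid = 0
    for g in range(params.n_granules):
        rng = np.random.default_rng(granule_streams[g])
        gi, gj = divmod(g, ncols)
        cx = margin + (gj + 0.5) * cell + rng.uniform(-10, 10)
        cy = margin + (gi + 0.5) * cell + rng.uniform(-10, 10)
        R = float(params.radius_model.sample(rng, 1)[0])
        ring_pts = np.column_stack([cx + R * np.cos(theta_ring),
                                    cy + R * np.sin(theta_ring)])
        rings.append(GranuleRing(id=g, points_nm=ring_pts))

        scale = (R / 98.0) ** 2
        n_chgb = rng.poisson(params.chgb_count_rate * scale)
        n_ins = rng.poisson(params.insulin_count_rate * scale)

        # CHGB: shell/core mixture
        d_chgb = np.empty(n_chgb)
        is_shell = rng.random(n_chgb) < params.shell_weight
        if is_shell.any():
            d_chgb[is_shell] = params.shell_model.sample(rng, int(is_shell.sum()),
                                                         upper=R)
        n_core = int((~is_shell).sum())
        if n_core:
            d_chgb[~is_shell] = R - _half_normal(rng, n_core,
                                                 params.core_offset_sigma, R + 20.0)
        d_ins = R - _half_normal(rng, n_ins, params.core_offset_sigma, R + 20.0)

        items = ([("chgb", params.gold_diameter_chgb, float(d)) for d in d_chgb]
                 + [("insulin", params.gold_diameter_insulin, float(d))
                    for d in d_ins])
        for cls, diam, x, y, d_final in _relax_positions(rng, cx, cy, R, items,
                                                         params.label_gap_nm):
            _render_disk(pixels, x, y, diam, params.gold_depth, params.nm_per_px)
            rows.append({"id": pid, "class": cls, "x_nm": x, "y_nm": y,
                         "d_nm": d_final, "ring_id": g})
            pid += 1

    pixels = np.clip(pixels, 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(rows, columns=["id", "class", "x_nm", "y_nm",
                                        "d_nm", "ring_id"])
    mg = Micrograph(pixels, params.nm_per_px,
                    meta={"seed": params.seed, "n_granules": params.n_granules})
    return mg, rings, truth


_ANGLE_TRIES = 24
_RADIAL_STEP_NM = 1.0
_RADIAL_TRIES = 80


def _relax_positions(rng: np.random.Generator, cx: float, cy: float, R: float,
                     items: list[tuple[str, float, float]], gap_nm: float = 0.25):
    """Steric-exclusion placement of one granule's gold beads.

    Gold beads are solid, so two labels cannot interpenetrate.  Beads are
    placed innermost-first at their drawn membrane distance d; at each radius
    the azimuth with the largest clearance from already-placed beads is taken
    (keeps neighbours resolvable), and only when no azimuth is collision-free is the
    bead nudged radially outward in 1-nm steps (inward once the −20 nm
    analysis floor is reached).  The marginal distance distribution is thus
    preserved except for the unavoidable hard-core spreading of crowded
    granule cores, and the truth table records the rendered geometry exactly.

    Returns a list of ``(class, diameter, x, y, d_final)`` in the input order.
    """
    order = sorted(range(len(items)), key=lambda i: R - items[i][2])
    placed: list[tuple[float, float, float]] = []
    out: list = [None] * len(items)
    for i in order:
        cls, diam, d = items[i]
        x, y, d_final = _place_label(rng, cx, cy, R, float(d), diam / 2.0,
                                     placed, gap_nm)
        placed.append((x, y, diam / 2.0))
        out[i] = (cls, diam, x, y, d_final)
    return out


def _place_label(rng: np.random.Generator, cx: float, cy: float, R: float,
                 d: float, r_bead: float,
                 placed: list[tuple[float, float, float]], gap_nm: float):
    d_try = d
    direction = -_RADIAL_STEP_NM   # outward: rho grows, d shrinks
    for _ in range(_RADIAL_TRIES + 1):
        rho = R - d_try
        best = None
        for _ in range(_ANGLE_TRIES):
            theta = rng.uniform(0, 2 * math.pi)
            x = cx + rho * math.cos(theta)
            y = cy + rho * math.sin(theta)
            clearance = min(
                (math.hypot(x - px, y - py) - (r_bead + pr + gap_nm)
                 for px, py, pr in placed), default=math.inf)
            if clearance >= 0 and (best is None or clearance > best[0]):
                # most-clear azimuth keeps beads apart for clean segmentation
                best = (clearance, x, y)
        if best is not None:
            return best[1], best[2], d_try
        d_next = d_try + direction
        if d_next < -20.0:
            direction = _RADIAL_STEP_NM
            d_next = d_try + direction
        d_try = min(d_next, R)
    theta = rng.uniform(0, 2 * math.pi)   # last resort: accept the overlap
    rho = R - d
    return cx + rho * math.cos(theta), cy + rho * math.sin(theta), d


def _half_normal(rng: np.random.Generator, n: int, sigma: float,
                 upper: float) -> np.ndarray:
    """|N(0, sigma)| truncated to [0, upper] by redraw (keeps d >= −20)."""
    s = np.abs(rng.normal(0.0, sigma, n))
    bad = s > upper
    while bad.any():
        s[bad] = np.abs(rng.normal(0.0, sigma, int(bad.sum())))
        bad = s > upper
    return s


def make_em_dataset(params: EMFieldParams = EMFieldParams(), n_fields: int = 3):
    """Split ``params.n_granules`` granules across ``n_fields`` micrographs.

    Emulates pooling several independent labeling experiments; per-field seeds
    are spawned from the master seed.  Returns a list of
    ``(micrograph, rings, truth)`` tuples; ring and particle ids are offset so
    they stay unique across the dataset.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    base = params.n_granules // n_fields
    extra = params.n_granules % n_fields
    seeds = np.random.SeedSequence(params.seed).spawn(n_fields)
    out = []
    ring_offset = 0
    for i in range(n_fields):
        n_i = base + (1 if i < extra else 0)
        sub = replace(params, n_granules=n_i,
                      seed=int(seeds[i].generate_state(1)[0] % (2 ** 31)))
        mg, rings, truth = make_em_field(sub)
        for r in rings:
            r.id += ring_offset
        truth["ring_id"] += ring_offset
        out.append((mg, rings, truth))
        ring_offset += n_i
    return out


# ---------------------------------------------------------------------------
# fluorescent puncta
# ---------------------------------------------------------------------------

def make_puncta_image(n_puncta: int, spot_sigma_nm: float = 200.0,
                      intensity: float = 1000.0, noise_sd: float = 20.0,
                      seed: int = 0, shape: tuple[int, int] = (512, 512),
                      nm_per_px: float = 100.0, min_separation_nm: float = 1500.0,
                      max_tries: int = 10000):
    """Isolated 2-D Gaussian spots on a noisy background + truth centroids.

    Spots are placed by bounded rejection sampling with a minimum pairwise
    separation; exceeding ``max_tries`` raises (placement failure).
    """
    if n_puncta < 0:
        raise ValueError("n_puncta must be non-negative")
    rng = np.random.default_rng(seed)
    h_nm, w_nm = shape[0] * nm_per_px, shape[1] * nm_per_px
    pad = 4 * spot_sigma_nm
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_puncta:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("puncta placement failed: field too crowded")
        x = rng.uniform(pad, w_nm - pad)
        y = rng.uniform(pad, h_nm - pad)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_separation_nm ** 2
               for cx, cy in centers):
            centers.append((x, y))
    pixels = rng.normal(100.0, noise_sd, shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    x_nm = (xx + 0.5) * nm_per_px
    y_nm = (yy + 0.5) * nm_per_px
    for cx, cy in centers:
        pixels += intensity * np.exp(-((x_nm - cx) ** 2 + (y_nm - cy) ** 2)
                                     / (2 * spot_sigma_nm ** 2))
    truth = pd.DataFrame(centers, columns=["x_nm", "y_nm"])
    return Micrograph(pixels, nm_per_px, meta={"seed": seed}), truth


# ---------------------------------------------------------------------------
# single-channel and macroscopic traces
# ---------------------------------------------------------------------------

def _simulate_channel_path(rng: np.random.Generator, n_samples: int, dt: float,
                           open_rate: float, close_rate: float,
                           tau_inact: float | None, start_open: bool) -> np.ndarray:
    """Exact event-driven two-state path sampled on the grid (1 = open)."""
    total = n_samples * dt
    t = 0.0
    state = bool(start_open)
    t_inact = (rng.exponential(tau_inact) if tau_inact is not None else math.inf)
    path = np.zeros(n_samples, dtype=np.int8)
    while t < total:
        rate = close_rate if state else open_rate
        dwell = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        t_next = min(t + dwell, total, t_inact)
        if state:
            i0 = int(math.ceil(t / dt - 1e-12))
            i1 = min(n_samples, int(math.ceil(t_next / dt - 1e-12)))
            path[i0:i1] = 1
        if t_next >= t_inact:
            break
        t = t_next
        state = not state
    return path


def make_channel_trace(params: ChannelSimParams = ChannelSimParams()):
    """Simulate a two-level multichannel current trace.

    Current = (number of open channels) x g x (V − Erev) + Gaussian noise,
    g in pS and V in mV giving pA.  With ``tau_inact_s`` set each channel
    inactivates irreversibly at rate 1/tau.  Returns ``(trace, truth_path)``
    where the truth path holds the open-channel count per sample.
    """
    dt = params.sample_interval_s
    levels = np.concatenate([
        np.full(max(1, int(round(dur / dt))), lvl)
        for lvl, dur in params.voltage_protocol])
    n = levels.size
    ss = np.random.SeedSequence(params.seed)
    noise_stream, *chan_streams = ss.spawn(params.n_channels + 1)
    n_open = np.zeros(n, dtype=np.int32)
    for c in range(params.n_channels):
        rng = np.random.default_rng(chan_streams[c])
        n_open += _simulate_channel_path(rng, n, dt, params.open_rate,
                                         params.close_rate, params.tau_inact_s,
                                         params.start_open)
    i_unitary = params.unitary_conductance_pS * (levels - params.reversal_mV) / 1000.0
    samples = n_open * i_unitary
    if params.noise_sd_pA > 0:
        samples = samples + np.random.default_rng(noise_stream).normal(
            0.0, params.noise_sd_pA, n)
    holding = params.voltage_protocol[0][0]
    trace = SingleChannelTrace(samples.astype(float), dt, holding,
                               meta={"seed": params.seed,
                                     "n_channels": params.n_channels})
    return trace, n_open


def make_macroscopic_sweeps(params: ChannelSimParams):
    """One trace per protocol step (long-step inactivation protocols).

    Each ``(level, duration)`` of the voltage protocol becomes an independent
    sweep holding all channels at that level; seeds are spawned per sweep.
    """
    seeds = np.random.SeedSequence(params.seed).spawn(len(params.voltage_protocol))
    sweeps = []
    for (lvl, dur), s in zip(params.voltage_protocol, seeds):
        sub = replace(params, voltage_protocol=((lvl, dur),),
                      seed=int(s.generate_state(1)[0] % (2 ** 31)))
        sweeps.append(make_channel_trace(sub))
    return sweeps


# ---------------------------------------------------------------------------
# flux assays
# ---------------------------------------------------------------------------

def hill_truth(L: float, kD: float, n: float) -> float:
    return 1.0 / (1.0 + (L / kD) ** n) if L > 0 else 1.0


def make_flux_series(params: FluxSimParams = FluxSimParams()):
    """Per-concentration light-scattering traces plus amplitude table.

    Each trace follows ``baseline − A·Hill([L])·(1 − exp(−t/tau))`` after the
    valinomycin trigger at t = 0, with a pre-trigger baseline window and a
    zero-amplitude solvent control.  Amplitude noise (s.d. ``noise_sd``)
    perturbs the normalized response of each replicate.

    Returns ``(traces, table)``: traces is a dict mapping
    ``(concentration, replicate)`` -> DataFrame(t_s, signal), with the control
    under key ``("control", 0)``; table is a DataFrame
    (ligand, response, replicate) of normalized truth+noise amplitudes.
    """
    p = params
    t = np.arange(-p.t_pre_s, p.t_post_s + p.dt_s / 2, p.dt_s)
    decay = np.where(t >= 0, 1.0 - np.exp(-np.maximum(t, 0) / p.tau_flux_s), 0.0)
    ss = np.random.SeedSequence(p.seed)
    streams = ss.spawn(len(p.ligand_concentrations) * p.replicate_count + 1)
    traces: dict = {}
    rows = []
    k = 0
    for conc in p.ligand_concentrations:
        resp_true = hill_truth(conc, p.kD_true, p.n_true)
        for rep in range(p.replicate_count):
            rng = np.random.default_rng(streams[k]); k += 1
            resp = resp_true + rng.normal(0.0, p.noise_sd)
            sig = (p.baseline - p.amplitude * resp * decay
                   + rng.normal(0.0, p.trace_noise_sd, t.size))
            traces[(float(conc), rep)] = pd.DataFrame({"t_s": t, "signal": sig})
            rows.append({"ligand": float(conc), "response": resp, "replicate": rep})
    ctl_rng = np.random.default_rng(streams[k])
    traces[("control", 0)] = pd.DataFrame({
        "t_s": t,
        "signal": p.baseline + ctl_rng.normal(0.0, p.trace_noise_sd, t.size)})
    table = pd.DataFrame(rows, columns=["ligand", "response", "replicate"])
    return traces, table


# ---------------------------------------------------------------------------
# whole-cell secretion sessions
# ---------------------------------------------------------------------------

def make_whole_cell_session(params: SecretionSimParams = SecretionSimParams()):
    """Per-pulse peak currents at ±80 mV during stimulated granule release.

    Cumulative conductance grows by a compound-Poisson staircase — each
    depolarizing pulse fuses a Poisson number of granules, each adding a fixed
    anionic conductance — only while calcium is present.  Peak current is
    ``G(t)·(V − Erev) + leak``; removing extracellular chloride zeroes the
    anionic driving-force term (current returns to leak).
    """
    p = params
    n_pulses = int(round(p.duration_s * p.pulse_rate_hz))
    rng = np.random.default_rng(p.seed)
    events = (rng.poisson(p.fusion_rate_per_pulse, n_pulses)
              if p.calcium_present else np.zeros(n_pulses, dtype=int))
    G = np.cumsum(events) * p.conductance_per_event_nS  # nS
    t = (np.arange(n_pulses) + 1) / p.pulse_rate_hz
    drive = 1.0 if p.chloride_present else 0.0
    i_pos = drive * G * (80.0 - p.erev_mV) + p.leak_pA
    i_neg = drive * G * (-80.0 - p.erev_mV) - p.leak_pA
    return pd.DataFrame({"t_s": t, "i_plus80_pA": i_pos, "i_minus80_pA": i_neg,
                         "g_nS": G})
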