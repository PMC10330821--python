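"""Nernst/Goldman-Hodgkin-Katz selectivity math and exocytosis charge estimates.

Sign convention: the trans compartment is the reference ("inner") side, so the
single-ion equilibrium potential is E = (RT/zF)·ln(C_cis/C_trans).  With
150/30 mM KCl (cis/trans) this gives −41.2 mV for Cl⁻ and +41.2 mV for K⁺ at
the default temperature.  The default temperature of 297.1 K is the one
consistent with those printed reversal potentials (RT/F ≈ 25.6 mV); it is an
explicit parameter everywhere.

The GHK voltage and current relations here handle monovalent ions only;
divalent species are rejected rather than approximated.  Charge-balance
estimates for the exocytosis site (ion counts in a femtoliter volume, the
membrane-patch charging potential) handle valence explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy.optimize import brentq

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "AVOGADRO",
    "ELEMENTARY_CHARGE",
    "DEFAULT_TEMPERATURE_K",
    "IonSpecies",
    "RecordingCondition",
    "nernst_potential",
    "ghk_reversal",
    "solve_permeability_ratio",
    "ghk_current_shares",
    "ions_in_volume",
    "disk_charging_potential",
]

GAS_CONSTANT = 8.314462618       # J / (mol K)
FARADAY = 96485.33212            # C / mol
AVOGADRO = 6.02214076e23         # 1 / mol
ELEMENTARY_CHARGE = 1.602176634e-19   # C
DEFAULT_TEMPERATURE_K = 297.1


@dataclass(frozen=True)
class IonSpecies:
    """One permeant ion: valence, two-sided concentrations (mM), permeability."""

    name: str
    z: int
    conc_cis: float
    conc_trans: float
    rel_permeability: float = 1.0

    def __post_init__(self) -> None:
        if self.z == 0 or abs(self.z) > 2:
            raise ValueError("valence must be ±1 or ±2")
        if self.conc_cis < 0 or self.conc_trans < 0:
            raise ValueError("concentrations must be non-negative")
        if self.rel_permeability < 0:
            raise ValueError("relative permeability must be non-negative")


@dataclass(frozen=True)
class RecordingCondition:
    """Ionic composition on both sides plus temperature."""

    species: tuple
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "species", tuple(self.species))

    def thermal_voltage_mV(self) -> float:
        return 1000.0 * GAS_CONSTANT * self.temperature_K / FARADAY

    def swapped(self) -> "RecordingCondition":
        """Condition with cis and trans exchanged on every species."""
        return RecordingCondition(
            tuple(replace(s, conc_cis=s.conc_trans, conc_trans=s.conc_cis)
                  for s in self.species),
            self.temperature_K)


def nernst_potential(z: int, conc_cis: float, conc_trans: float,
                     temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Single-ion equilibrium potential E = (RT/zF)·ln(C_cis/C_trans), in mV."""
    if z == 0:
        raise ValueError("valence must be nonzero")
    if conc_cis <= 0 or conc_trans <= 0:
        raise ValueError("concentrations must be positive for a Nernst potential")
    rt_f = 1000.0 * GAS_CONSTANT * temperature_K / FARADAY
    return rt_f / z * math.log(conc_cis / conc_trans)


def _check_monovalent(cond: RecordingCondition) -> None:
    for s in cond.species:
        if abs(s.z) != 1:
            raise ValueError(
                f"GHK voltage/current relations support monovalent ions only "
                f"(got z={s.z} for {s.name})")


def ghk_reversal(cond: RecordingCondition) -> float:
    """GHK reversal potential (mV) of a multi-ion monovalent condition.

    Erev = (RT/F)·ln[(Σ_cat P·C_cis + Σ_an P·C_trans) /
                     (Σ_cat P·C_trans + Σ_an P·C_cis)]

    Reduces exactly to the Nernst potential when a single species is permeant.
    """
    _check_monovalent(cond)
    if all(s.rel_permeability == 0 for s in cond.species):
        raise ValueError("all permeabilities are zero")
    num = den = 0.0
    for s in cond.species:
        if s.z > 0:
            num += s.rel_permeability * s.conc_cis
            den += s.rel_permeability * s.conc_trans
        else:
            num += s.rel_permeability * s.conc_trans
            den += s.rel_permeability * s.conc_cis
    if num <= 0 or den <= 0:
        raise ValueError("GHK quotient undefined for these concentrations")
    return cond.thermal_voltage_mV() * math.log(num / den)


def solve_permeability_ratio(erev_mV: float, cond: RecordingCondition,
                             target_ion: str, reference_ion: str,
                             tol_mV: float = 1e-9) -> float:
    """Permeability ratio P_target/P_reference reproducing a measured Erev.

    Solves, by monotone bracketing/bisection, for the r such that setting
    ``rel_permeability(target) = r × rel_permeability(reference)`` makes
    ``ghk_reversal`` equal the measured reversal potential within ``tol_mV``.
    The measured Erev must lie strictly between the two single-ion Nernst
    limits of the template.
    """
    names = [s.name for s in cond.species]
    if target_ion not in names or reference_ion not in names:
        raise ValueError("target and reference ions must be in the condition")
    tgt = next(s for s in cond.species if s.name == target_ion)
    ref = next(s for s in cond.species if s.name == reference_ion)
    if ref.rel_permeability <= 0:
        raise ValueError("reference ion must have positive permeability")
    lim_tgt = nernst_potential(tgt.z, tgt.conc_cis, tgt.conc_trans,
                               cond.temperature_K)
    lim_ref = nernst_potential(ref.z, ref.conc_cis, ref.conc_trans,
                               cond.temperature_K)
    lo, hi = sorted((lim_tgt, lim_ref))
    if not (lo < erev_mV < hi):
        raise ValueError(
            f"reversal potential {erev_mV} mV must lie strictly between the "
            f"single-ion Nernst limits ({lo:.4f}, {hi:.4f}) mV")

    def at_ratio(log_r: float) -> float:
        r = math.exp(log_r)
        species = tuple(
            replace(s, rel_permeability=r * ref.rel_permeability)
            if s.name == target_ion else s
            for s in cond.species)
        return ghk_reversal(RecordingCondition(species, cond.temperature_K)) - erev_mV

    lo_lr, hi_lr = -40.0, 40.0
    f_lo, f_hi = at_ratio(lo_lr), at_ratio(hi_lr)
    if f_lo * f_hi > 0:
        raise ValueError("no permeability ratio reproduces this Erev")
    log_r = brentq(at_ratio, lo_lr, hi_lr, xtol=1e-14, rtol=8.9e-16)
    # polish until within the stated voltage tolerance
    if abs(at_ratio(log_r)) > tol_mV:  # pragma: no cover - brentq is ample
        raise RuntimeError("permeability solve did not reach tolerance")
    return math.exp(log_r)


def ghk_current_shares(cond: RecordingCondition, v_mV: float):
    """Per-ion GHK currents (arbitrary common units) and absolute-current shares.

    I_S ∝ P_S z² (F²V/RT) (C_in − C_out·e^(−zFV/RT)) / (1 − e^(−zFV/RT)),
    with trans as the inner side and the analytic V→0 limit.  Shares are
    |I_S| / Σ|I| and sum to 1; the net current changes sign at the GHK
    reversal potential.
    """
    _check_monovalent(cond)
    if not math.isfinite(v_mV):
        raise ValueError("V must be finite")
    permeant = [s for s in cond.species if s.rel_permeability > 0
                and (s.conc_cis > 0 or s.conc_trans > 0)]
    if not permeant:
        raise ValueError("no permeant species")
    vt = cond.thermal_voltage_mV()
    currents: dict[str, float] = {}
    for s in cond.species:
        c_in, c_out = s.conc_trans, s.conc_cis
        u = s.z * v_mV / vt
        if abs(u) < 1e-10:
            # first-order limit: V(C_in − C_out e^{−u})/(1 − e^{−u})
            #   → (vt/z)(C_in − C_out) + V·C_out  as V → 0
            term = vt / s.z * (c_in - c_out) + v_mV * c_out
        else:
            term = v_mV * (c_in - c_out * math.exp(-u)) / (1.0 - math.exp(-u))
        currents[s.name] = s.rel_permeability * s.z ** 2 * term
    total = sum(abs(i) for i in currents.values())
    shares = {k: (abs(i) / total if total > 0 else 0.0)
              for k, i in currents.items()}
    return currents, shares


def ions_in_volume(concentration_M: float, volume_L: float) -> float:
    """Number of ions at molar concentration C in volume V: N = N_A·C·V."""
    if concentration_M < 0 or volume_L < 0:
        raise ValueError("concentration and volume must be non-negative")
    return AVOGADRO * concentration_M * volume_L


def disk_charging_potential(n_ions: float, valence: int, disk_diameter_um: float,
                            specific_capacitance_uF_cm2: float = 1.0) -> float:
    """Potential (V) from n ions charging a circular membrane patch.

    V = n·|z|·e / (C_spec·π(d/2)²) — the charging effect of a local ion load
    spread over a granular punctum of the given diameter.
    """
    if disk_diameter_um <= 0 or specific_capacitance_uF_cm2 <= 0:
        raise ValueError("diameter and capacitance must be positive")
    if n_ions < 0:
        raise ValueError("ion count must be non-negative")
    area_cm2 = math.pi * (disk_diameter_um * 1e-4 / 2.0) ** 2
    cap_F = specific_capacitance_uF_cm2 * 1e-6 * area_cm2
    charge_C = n_ions * abs(valence) * ELEMENTARY_CHARGE
    return charge_C / cap_F
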