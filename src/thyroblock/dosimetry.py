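"""Thyroid equivalent dose from accumulated I-131 decays.

The kinetics module collects the amount of radioiodine that decays inside
each thyroid gland into a cumulative sink (µmol).  The β component of the
dose follows directly from the number of decays:

    D_β (mGy) = n_decays · Ē_β · 1.602e-13 J/MeV / m_gland(kg) · 1e3

with Ē_β = 0.18 MeV per decay.  For β radiation the quality factor is one,
so the equivalent dose in mSv is numerically identical.

I-131 also emits γ rays.  Their share of the *total* absorbed dose is taken
from the Marinelli/Quimby formulation combined with the Hine geometric
factor ḡ = 3πr for a sphere of radius r < 10 cm (one thyroid lobe):

    f_γ = 0.0346·Ƭ·ḡ / (73.8·Ē_β + 0.0346·Ƭ·ḡ),   Ƭ = 2.2 R·mCi⁻¹·h⁻¹

The total equivalent dose is therefore D = D_β / (1 − f_γ).  The common
(C_max · T_eff) prefactor of the Marinelli equation cancels in the fraction
and is never needed: the absolute dose always comes from the decay sink.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import constants

from .kinetics import RADIO, Trajectory
from .parameters import ModelParameters

#: Mean β energy of I-131, MeV per decay.
MEAN_BETA_ENERGY_MEV = 0.18
#: Specific γ-ray constant of I-131, R·mCi⁻¹·h⁻¹ at 1 cm.
GAMMA_RAY_CONSTANT = 2.2
#: Marinelli/Quimby coefficients (β and γ terms).
BETA_COEFFICIENT = 73.8
GAMMA_COEFFICIENT = 0.0346

_MEV_TO_J = constants.electron_volt * 1e6
_AVOGADRO = constants.Avogadro


@dataclass(frozen=True)
class DoseResult:
    """Committed thyroid equivalent doses for one scenario (mSv)."""

    week: int
    dose_maternal_msv: float
    dose_fetal_msv: Optional[float]
    gamma_fraction_maternal: float
    gamma_fraction_fetal: Optional[float]
    uptake_fraction_24h_maternal: Optional[float]
    uptake_fraction_24h_fetal: Optional[float]


def beta_dose(decayed_umol: float, gland_mass_g: float) -> float:
    """β dose (mGy ≡ mSv) from a number of decays given as µmol of I-131."""
    if decayed_umol < 0:
        raise ValueError("decayed amount must be non-negative")
    if gland_mass_g <= 0:
        raise ValueError("gland mass must be positive")
    n_decays = decayed_umol * 1e-6 * _AVOGADRO
    energy_j = n_decays * MEAN_BETA_ENERGY_MEV * _MEV_TO_J
    return energy_j / (gland_mass_g * 1e-3) * 1e3  # Gy -> mGy


def gamma_fraction(r_cm: float) -> float:
    """γ share of the total absorbed dose for a lobe of radius r (cm)."""
    if not 0 < r_cm < 10:
        raise ValueError("geometric factor 3*pi*r is valid only for 0 < r < 10 cm")
    g = 3.0 * math.pi * r_cm
    gamma_term = GAMMA_COEFFICIENT * GAMMA_RAY_CONSTANT * g
    return gamma_term / (BETA_COEFFICIENT * MEAN_BETA_ENERGY_MEV + gamma_term)


def _sink_at(traj: Trajectory, which: str, t: float) -> float:
    import numpy as np

    sink = traj.sink_maternal if which == "maternal" else traj.sink_fetal
    return float(np.interp(t, traj.times, sink))


def total_dose(
    traj: Trajectory,
    params: ModelParameters | None = None,
    *,
    include_gamma: bool = True,
    at_time: float | None = None,
) -> DoseResult:
    """Committed thyroid equivalent doses from an integrated trajectory.

    ``at_time`` reports the dose accrued up to an intermediate time (days);
    by default the dose at the trajectory horizon is returned.  With
    ``include_gamma=False`` the result is the pure β dose (used when
    comparing against dose tabulations that omit the γ correction).
    """
    if params is None:
        params = traj.params
    phys = params.physiology
    t_end = traj.times[-1] if at_time is None else at_time

    f_m = gamma_fraction(phys.lobe_radius_maternal_cm)
    d_m = beta_dose(_sink_at(traj, "maternal", t_end), phys.thyroid_weight_maternal_g)
    if include_gamma:
        d_m /= 1.0 - f_m

    d_f = None
    f_f = None
    if phys.has_fetal_thyroid:
        f_f = gamma_fraction(phys.lobe_radius_fetal_cm)
        d_f = beta_dose(_sink_at(traj, "fetal", t_end), phys.thyroid_weight_fetal_g)
        if include_gamma:
            d_f /= 1.0 - f_f

    administered = traj.scenario.activity_bq
    upt_m = upt_f = None
    if administered > 0 and traj.times[-1] >= 1.0:
        from .kinetics import bq_to_umol

        total0 = bq_to_umol(administered)
        state = traj.at(1.0)
        from .kinetics import _MATERNAL_GLAND, _FETAL_GLAND

        upt_m = sum(state[i, RADIO] for i in _MATERNAL_GLAND) / total0
        if phys.has_fetal_thyroid:
            upt_f = sum(state[i, RADIO] for i in _FETAL_GLAND) / total0

    return DoseResult(
        week=params.week,
        dose_maternal_msv=d_m,
        dose_fetal_msv=d_f,
        gamma_fraction_maternal=f_m,
        gamma_fraction_fetal=f_f,
        uptake_fraction_24h_maternal=upt_m,
        uptake_fraction_24h_fetal=upt_f,
    )
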