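"""Reference implementations used for cross-checking the saturable model.

Two independent routes are provided:

* :func:`first_order_parameters` rescales every carrier flow so that the
  Michaelis–Menten machinery runs in its linear regime at any attainable
  amount (Km# multiplied by a huge factor with Tmax/Km# = k held fixed).
  This reproduces the original all-first-order pregnancy model through the
  exact same code path as the main model.

* :func:`committed_dose_linear` solves the purely linear system (first-order
  flows + decay + thyroid decay sinks) in closed form with a matrix
  exponential, with no ODE solver involved.  It is the fully independent
  oracle for committed doses in the linear regime.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import kinetics
from .dosimetry import total_dose
from .kinetics import (
    ExposureScenario,
    Trajectory,
    bq_to_umol,
    simulate,
)
from .parameters import COMPARTMENTS, ModelParameters, load_parameters

#: Km# inflation factor putting every carrier flow deep in its linear regime.
LINEAR_SCALE = 1e12


def first_order_parameters(
    params: ModelParameters, scale: float = LINEAR_SCALE
) -> ModelParameters:
    """Parameters with every carrier flow effectively first-order.

    Each Michaelis–Menten flow keeps its linear-regime slope k = Tmax/Km#
    while Km# is inflated by ``scale``, so the flux is k·m for any realistic
    amount.  Structure and code path are identical to the main model.
    """
    flows = []
    for f in params.flows:
        if f.law == "michaelis_menten" and f.active:
            flows.append(
                replace(f, km_abs=f.km_abs * scale, tmax=f.tmax * scale)
            )
        else:
            flows.append(f)
    return replace(params, flows=tuple(flows))


def simulate_first_order(
    scenario: ExposureScenario, params: ModelParameters | None = None, **kw
) -> Trajectory:
    """Integrate the original first-order model (no saturation, no WC)."""
    if params is None:
        params = load_parameters(scenario.week)
    lin = first_order_parameters(params)
    scenario = replace(scenario, wc_enabled=False)
    return simulate(scenario, lin, **kw)


def _linear_matrix(params: ModelParameters) -> np.ndarray:
    """Generator of the augmented linear radio-species system.

    States: 23 compartment amounts plus the two thyroid decay sinks.  Every
    flow contributes its first-order constant (carrier flows enter with
    their linear-regime k = Tmax/Km#); decay removes −λ everywhere and
    feeds the gland sinks.
    """
    n = len(COMPARTMENTS)
    idx = {c: i for i, c in enumerate(COMPARTMENTS)}
    M = np.zeros((n + 2, n + 2))
    for f in params.flows:
        if not f.active:
            continue
        k = f.k if f.law == "first_order" else f.tmax / f.km_abs
        i, j = idx[f.source], idx[f.target]
        M[i, i] -= k
        M[j, i] += k
    lam = params.decay_constant
    if params.decay_scope == "all":
        for i in range(n):
            M[i, i] -= lam
    else:
        for c in ("thyroid_iodide", "thyroid_organic", "fetal_thyroid"):
            M[idx[c], idx[c]] -= lam
    M[n, idx["thyroid_iodide"]] += lam
    M[n, idx["thyroid_organic"]] += lam
    M[n + 1, idx["fetal_thyroid"]] += lam
    return M


def committed_dose_linear(
    week: int,
    activity_bq: float,
    horizon_d: float = 60.0,
    *,
    include_gamma: bool = False,
) -> dict:
    """Closed-form committed doses of the linear model via expm.

    Returns a dict with maternal and (where defined) fetal committed thyroid
    equivalent doses in mSv, plus the decayed amounts (µmol).
    """
    from .dosimetry import beta_dose, gamma_fraction

    params = load_parameters(week)
    M = _linear_matrix(params)
    n = len(COMPARTMENTS)
    y0 = np.zeros(n + 2)
    y0[COMPARTMENTS.index("blood")] = bq_to_umol(activity_bq)
    y = expm(M * horizon_d) @ y0

    phys = params.physiology
    d_m = beta_dose(y[n], phys.thyroid_weight_maternal_g)
    if include_gamma:
        d_m /= 1.0 - gamma_fraction(phys.lobe_radius_maternal_cm)
    out = {
        "dose_maternal_msv": d_m,
        "decayed_maternal_umol": y[n],
        "dose_fetal_msv": None,
        "decayed_fetal_umol": y[n + 1],
    }
    if phys.has_fetal_thyroid:
        d_f = beta_dose(y[n + 1], phys.thyroid_weight_fetal_g)
        if include_gamma:
            d_f /= 1.0 - gamma_fraction(phys.lobe_radius_fetal_cm)
        out["dose_fetal_msv"] = d_f
    return out


def crosscheck(
    activity_grid_bq,
    week: int = 0,
    horizon_d: float = 60.0,
) -> pd.DataFrame:
    """Saturable-model vs first-order-model committed doses over activities.

    In the linear regime (≲1e11 Bq) the ratio is 1; above ~1e14 Bq the
    saturable model falls below the first-order one as the carrier
    saturates.  Doses are β-only (the γ correction cancels in the ratio).
    """
    params = load_parameters(week)
    rows = []
    for act in activity_grid_bq:
        scen = ExposureScenario(
            week=week, activity_bq=float(act), horizon_d=horizon_d,
            wc_enabled=False,
        )
        mm = total_dose(simulate(scen, params), params, include_gamma=False)
        fo = total_dose(
            simulate_first_order(scen, params), params, include_gamma=False
        )
        rows.append(
            {
                "activity_bq": float(act),
                "dose_mm_msv": mm.dose_maternal_msv,
                "dose_first_order_msv": fo.dose_maternal_msv,
                "ratio": mm.dose_maternal_msv / fo.dose_maternal_msv,
            }
        )
    return pd.DataFrame(rows)
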