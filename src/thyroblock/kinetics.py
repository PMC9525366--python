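"""Two-species biokinetic ODE system with saturable transport and
Wolff–Chaikoff gating.

Radioiodide (I-131) and stable iodide move through the same compartment
network.  First-order flows act on each species independently; the
carrier-mediated (NIS) flows are shared-capacity Michaelis–Menten routes in
which the two species compete:

    T_radio = Tmax · m_radio / (Km# + m_radio + m_stable)

Radioactive decay (λ = ln2/8.02 d⁻¹) removes radioiodine from every
compartment; decays occurring inside the maternal or fetal thyroid are
accumulated in dedicated sinks, from which the dosimetry module computes
the absorbed dose.

The Wolff–Chaikoff effect is modelled as an event-driven switch: when the
cumulative carrier influx of iodine (both species) into a gland since the
start (or since the last escape) reaches the gland's saturation threshold,
all carrier flows into that gland are shut; the block is released 36 h
later.  Integration is performed piecewise between switch events with a
stiff solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import (
    COMPARTMENTS,
    FIRST_FETAL_WEEK,
    I131_SPECIFIC_ACTIVITY_BQ_PER_G,
    MOLAR_MASS_I131,
    MOLAR_MASS_STABLE,
    ModelParameters,
    load_parameters,
)

N_COMP = len(COMPARTMENTS)
_IDX = {c: i for i, c in enumerate(COMPARTMENTS)}
_MATERNAL_GLAND = (_IDX["thyroid_iodide"], _IDX["thyroid_organic"])
_FETAL_GLAND = (_IDX["fetal_thyroid"],)

# state vector layout: radio amounts | stable amounts | decay sinks (maternal,
# fetal) | cumulative gland carrier influx counters (maternal, fetal)
_I_SINK_M = 2 * N_COMP
_I_SINK_F = 2 * N_COMP + 1
_I_CUM_M = 2 * N_COMP + 2
_I_CUM_F = 2 * N_COMP + 3
N_STATE = 2 * N_COMP + 4

RADIO, STABLE = 0, 1


def mm_rate(tmax: float, km_abs: float, m: float) -> float:
    """Michaelis–Menten transport rate Tmax·m/(Km# + m), µmol·d⁻¹."""
    if tmax < 0 or km_abs < 0 or m < 0:
        raise ValueError("mm_rate arguments must be non-negative")
    if m == 0.0:
        return 0.0
    return tmax * m / (km_abs + m)


def competitive_rate(tmax: float, km_abs: float, m1: float, m2: float) -> float:
    """Carrier rate for substrate 1 with substrate 2 competing.

    Both substrates are chemically identical iodide, so they share Km#:
    T1 = Tmax·m1/(Km# + m1 + m2).
    """
    if min(tmax, km_abs, m1, m2) < 0:
        raise ValueError("competitive_rate arguments must be non-negative")
    if m1 == 0.0:
        return 0.0
    return tmax * m1 / (km_abs + m1 + m2)


def bq_to_umol(activity_bq: float) -> float:
    """Convert an I-131 activity (Bq) to an amount of substance (µmol)."""
    if activity_bq < 0:
        raise ValueError("activity must be non-negative")
    grams = activity_bq / I131_SPECIFIC_ACTIVITY_BQ_PER_G
    return grams / MOLAR_MASS_I131 * 1e6


def mg_to_umol(mass_mg: float) -> float:
    """Convert a stable-iodine mass (mg) to µmol (126.904 g·mol⁻¹)."""
    if mass_mg < 0:
        raise ValueError("mass must be non-negative")
    return mass_mg * 1e3 / MOLAR_MASS_STABLE


@dataclass(frozen=True)
class ExposureScenario:
    """One acute exposure: a radioiodine bolus and an optional stable-iodine
    bolus, both injected into the maternal blood compartment."""

    week: int
    activity_bq: float = 0.0
    stable_dose_mg: float = 0.0
    t_admin_radio_d: float = 0.0
    t_admin_stable_d: float = 0.0
    horizon_d: float = 100.0
    wc_enabled: bool = True

    def __post_init__(self):
        if self.activity_bq < 0 or self.stable_dose_mg < 0:
            raise ValueError("activity and stable dose must be non-negative")
        if self.horizon_d <= 0:
            raise ValueError("horizon must be positive")


@dataclass(frozen=True)
class WCEvent:
    """One Wolff–Chaikoff block episode of a gland."""

    gland: str  # "maternal" | "fetal"
    t_on_d: float
    t_off_d: Optional[float]  # None when still active at the horizon


@dataclass
class Trajectory:
    """Integrated time course of the two-species system.

    ``amounts`` has shape (n_times, n_compartments, 2) with the species axis
    ordered (radio, stable), in µmol.
    """

    times: np.ndarray
    amounts: np.ndarray
    sink_maternal: np.ndarray
    sink_fetal: np.ndarray
    events: list[WCEvent]
    scenario: ExposureScenario
    params: ModelParameters
    solver_stats: dict = field(default_factory=dict)

    def amount(self, compartment: str, species: int) -> np.ndarray:
        return self.amounts[:, _IDX[compartment], species]

    def gland_content(self, gland: str, species: int) -> np.ndarray:
        idx = _MATERNAL_GLAND if gland == "maternal" else _FETAL_GLAND
        return self.amounts[:, list(idx), species].sum(axis=1)

    def at(self, t: float) -> np.ndarray:
        """Full state row at time t (linear interpolation on the grid)."""
        out = np.empty((self.amounts.shape[1], 2))
        for s in (RADIO, STABLE):
            for c in range(self.amounts.shape[1]):
                out[c, s] = np.interp(t, self.times, self.amounts[:, c, s])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (time, compartment, species)."""
        recs = []
        for s, name in ((RADIO, "radio"), (STABLE, "stable")):
            for c, comp in enumerate(COMPARTMENTS):
                recs.append(
                    pd.DataFrame(
                        {
                            "time_d": self.times,
                            "compartment": comp,
                            "species": name,
                            "amount_umol": self.amounts[:, c, s],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)


def _first_order_matrix(params: ModelParameters) -> np.ndarray:
    A = np.zeros((N_COMP, N_COMP))
    for f in params.flows:
        if f.law != "first_order" or not f.active:
            continue
        i, j = _IDX[f.source], _IDX[f.target]
        A[i, i] -= f.k
        A[j, i] += f.k
    return A


def _mm_arrays(params: ModelParameters):
    src, tgt, tmax, km = [], [], [], []
    gland = []
    for f in params.flows:
        if f.law != "michaelis_menten" or not f.active:
            continue
        src.append(_IDX[f.source])
        tgt.append(_IDX[f.target])
        tmax.append(f.tmax)
        km.append(f.km_abs)
        gland.append(f.gland if f.wc_gated else None)
    return (
        np.array(src, dtype=int),
        np.array(tgt, dtype=int),
        np.array(tmax),
        np.array(km),
        gland,
    )


def build_rhs(
    params: ModelParameters, blocked: dict[str, bool] | None = None
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Assemble the derivative function for the full state vector.

    ``blocked`` gives the current Wolff–Chaikoff switch state per gland;
    carrier flows into a blocked gland are multiplied by zero.  Efflux and
    first-order flows are never gated.
    """
    blocked = blocked or {}
    for f in params.flows:
        if f.source not in _IDX or f.target not in _IDX:
            raise ValueError(f"unknown compartment in flow {f.name}")

    A = _first_order_matrix(params)
    src, tgt, tmax, km, glands = _mm_arrays(params)
    gate = np.array(
        [0.0 if (g is not None and blocked.get(g, False)) else 1.0 for g in glands]
    )
    lam = params.decay_constant
    if params.decay_scope not in ("thyroid", "all"):
        raise ValueError(f"unknown decay_scope {params.decay_scope!r}")
    decay_mask = np.zeros(N_COMP)
    if params.decay_scope == "all":
        decay_mask[:] = 1.0
    else:
        for i in _MATERNAL_GLAND + _FETAL_GLAND:
            decay_mask[i] = 1.0
    is_maternal_target = np.array([t in _MATERNAL_GLAND for t in tgt])
    is_fetal_target = np.array([t in _FETAL_GLAND for t in tgt])

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        m_r = y[:N_COMP]
        m_s = y[N_COMP : 2 * N_COMP]
        dy = np.zeros(N_STATE)
        d_r = A @ m_r
        d_s = A @ m_s

        if src.size:
            mr = np.maximum(m_r[src], 0.0)
            ms = np.maximum(m_s[src], 0.0)
            denom = km + mr + ms
            rate_r = gate * tmax * mr / denom
            rate_s = gate * tmax * ms / denom
            np.subtract.at(d_r, src, rate_r)
            np.add.at(d_r, tgt, rate_r)
            np.subtract.at(d_s, src, rate_s)
            np.add.at(d_s, tgt, rate_s)
            total = rate_r + rate_s
            dy[_I_CUM_M] = total[is_maternal_target].sum()
            dy[_I_CUM_F] = total[is_fetal_target].sum()

        d_r -= lam * decay_mask * m_r
        dy[:N_COMP] = d_r
        dy[N_COMP : 2 * N_COMP] = d_s
        dy[_I_SINK_M] = lam * (
            m_r[_MATERNAL_GLAND[0]] + m_r[_MATERNAL_GLAND[1]]
        )
        dy[_I_SINK_F] = lam * m_r[_FETAL_GLAND[0]]
        return dy

    return rhs


@dataclass
class _WCState:
    active: bool = False
    t_on: Optional[float] = None
    ref: float = 0.0  # cumulative-influx reference for the next switch-on


def simulate(
    scenario: ExposureScenario,
    params: ModelParameters | None = None,
    *,
    rtol: float = 1e-8,
    atol: float | np.ndarray | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate an exposure scenario from t = 0 to the horizon.

    Boluses are instantaneous additions to the maternal blood compartment at
    their administration times.  The integration is segmented at bolus times
    and at Wolff–Chaikoff switch events, which are located by the solver's
    root finding on the cumulative gland-influx counters.
    """
    if params is None:
        params = load_parameters(scenario.week)
    if params.week != scenario.week:
        raise ValueError("scenario and parameters disagree on the week")

    radio_umol = bq_to_umol(scenario.activity_bq)
    stable_umol = mg_to_umol(scenario.stable_dose_mg)

    if atol is None:
        atol = np.empty(N_STATE)
        a_r = max(1e-24, 1e-13 * radio_umol)
        a_s = max(1e-18, 1e-13 * max(stable_umol, 1.0))
        atol[:N_COMP] = a_r
        atol[N_COMP : 2 * N_COMP] = a_s
        atol[_I_SINK_M : _I_SINK_F + 1] = a_r
        atol[_I_CUM_M : _I_CUM_F + 1] = max(a_r, a_s)

    thresholds = {"maternal": params.wc_threshold_maternal_umol}
    if params.wc_threshold_fetal_umol is not None:
        thresholds["fetal"] = params.wc_threshold_fetal_umol
    cum_index = {"maternal": _I_CUM_M, "fetal": _I_CUM_F}
    wc = {g: _WCState() for g in thresholds}

    boluses: list[tuple[float, int, float]] = []
    if radio_umol > 0:
        boluses.append((scenario.t_admin_radio_d, RADIO, radio_umol))
    if stable_umol > 0:
        boluses.append((scenario.t_admin_stable_d, STABLE, stable_umol))
    boundaries = sorted(
        {0.0, scenario.horizon_d}
        | {t for t, _, _ in boluses if t < scenario.horizon_d}
        | ({1.0} if scenario.horizon_d > 1.0 else set())
    )

    y = np.zeros(N_STATE)
    for t_b, species, amount in boluses:
        if t_b <= 0.0:
            y[_IDX["blood"] + species * N_COMP] += amount

    times = [0.0]
    states = [y.copy()]
    events_log: list[WCEvent] = []
    nfev = 0

    t = 0.0
    while t < scenario.horizon_d - 1e-12:
        # Next hard stop: bolus boundary or the horizon.  An engaged
        # Wolff-Chaikoff block needs no stop of its own: the switch-on
        # condition is an increase of the gland's cumulative uptake above
        # the saturation threshold since the exposure started, and as the
        # cumulative uptake never decreases, the condition still holds at
        # the 36 h escape and the gland re-saturates immediately -- the
        # block persists through the horizon.
        t_stop = min(b for b in boundaries if b > t + 1e-12)

        event_glands = []
        event_fns = []
        if scenario.wc_enabled:
            for g, state in wc.items():
                if state.active:
                    continue

                def make_event(idx, ref, thr):
                    def ev(tt, yy):
                        return (yy[idx] - ref) - thr

                    ev.terminal = True
                    ev.direction = 1
                    return ev

                event_glands.append(g)
                event_fns.append(
                    make_event(cum_index[g], wc[g].ref, thresholds[g])
                )

        rhs = build_rhs(params, {g: s.active for g, s in wc.items()})
        sol = solve_ivp(
            rhs,
            (t, t_stop),
            y,
            method=method,
            rtol=rtol,
            atol=atol,
            events=event_fns or None,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed at week {scenario.week}, t={t:.4g} d: "
                f"{sol.message}"
            )
        nfev += sol.nfev

        times.extend(sol.t[1:].tolist())
        for k in range(1, sol.t.size):
            states.append(sol.y[:, k].copy())
        y = sol.y[:, -1].copy()
        t = sol.t[-1]

        fired = None
        if sol.status == 1:  # a switch-on event terminated the segment
            for gi, te in enumerate(sol.t_events):
                if te.size:
                    fired = event_glands[gi]
                    t = float(te[0])
                    y = sol.y_events[gi][0].copy()
                    if times[-1] != t:
                        times.append(t)
                        states.append(y.copy())
                    break
        if fired is not None:
            wc[fired].active = True
            wc[fired].t_on = t
            events_log.append(WCEvent(gland=fired, t_on_d=t, t_off_d=None))
            continue

        # apply any bolus scheduled exactly at this boundary
        for t_b, species, amount in boluses:
            if 0.0 < t_b <= t + 1e-12 and abs(t_b - t) <= 1e-9:
                y[_IDX["blood"] + species * N_COMP] += amount
                states[-1] = y.copy()

    times_arr = np.array(times)
    states_arr = np.array(states)
    amounts = np.stack(
        (states_arr[:, :N_COMP], states_arr[:, N_COMP : 2 * N_COMP]), axis=2
    )
    return Trajectory(
        times=times_arr,
        amounts=amounts,
        sink_maternal=states_arr[:, _I_SINK_M],
        sink_fetal=states_arr[:, _I_SINK_F],
        events=events_log,
        scenario=scenario,
        params=params,
        solver_stats={"nfev": nfev, "method": method, "rtol": rtol},
    )
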