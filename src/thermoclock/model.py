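"""Right-hand side and single-cell integration of the 11-state ODE model.

State ordering follows :data:`thermoclock.params.STATE_NAMES`:

* ``TS1``, ``TS2`` — thermosensor/transductor intermediates of the
  indirect-response temperature-sensing cascade.  TS1 is produced in
  proportion to the temperature magnitude (cycle average ``Tavg``) and its
  deviation ``T - Tavg``; TS2 follows TS1 through a Hill surge.
* ``actHSF1``, ``indHSP`` — heat-shock-response module: activation of the
  free HSF1 pool is stimulated by TS2 and inhibited by the HSF1-induced HSP
  (which also feeds back on its own production).
* ``PerCry_mRNA`` … ``CLOCKBMAL1`` — the peripheral clock gene network
  (Per/Cry–Bmal1 interlocked feedback loops).  Active HSF1 multiplies the
  CLOCK/BMAL1-driven Per/Cry transcription through a saturating entrainment
  factor in which HSP competes with CLOCK/BMAL1 for the HSF1 activity.

The square-wave zeitgeber is honoured exactly: integration proceeds piecewise
between schedule discontinuities with a solver restart at every temperature
switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import DomainError, SimulationError
from .params import ModelParameters, STATE_NAMES
from .schedules import Schedule

__all__ = [
    "DEFAULT_INITIAL_STATE",
    "Trajectory",
    "cascade_rhs",
    "clock_rhs",
    "rhs",
    "simulate",
    "cascade_fixed_point",
]

#: Default initial condition: 1 nM for every component.  The entrained limit
#: cycle is globally attracting for nominal parameters; a burn-in (default
#: 480 h) is discarded before any metric is computed.
DEFAULT_INITIAL_STATE = np.ones(len(STATE_NAMES))


def cascade_rhs(state, T: float, Tavg: float, params: ModelParameters) -> np.ndarray:
    """Time derivatives (nM/h) of TS1, TS2, actHSF1, indHSP.

    ``state`` may be the full 11-vector or just the 4 cascade components.
    """
    y = np.asarray(state, dtype=float)
    TS1, TS2, aH, H = y[0], y[1], y[2], y[3]
    if H <= 0:
        raise DomainError(f"indHSP must be > 0 (got {H}); it appears in a denominator")
    pm = params
    dTS1 = pm.vact0_ts1 * Tavg + pm.vact1_ts1 * (T - Tavg) - pm.vina_ts1 * TS1
    ts1n = TS1 ** pm.n
    dTS2 = pm.vb_ts2 * ts1n / (pm.kb_ts2 ** pm.n + ts1n) - pm.vd_ts2 * TS2
    stim = 1.0 + pm.kT * TS2 / (pm.KT + TS2)
    daH = pm.vact_hsf1 * (pm.HSF1tot - aH) / H * stim - pm.vina_hsf1 * aH
    dH = pm.vb_hsp * aH / H - pm.vd_hsp * H
    return np.array([dTS1, dTS2, daH, dH])


def clock_rhs(state, params: ModelParameters) -> np.ndarray:
    """Time derivatives (nM/h) of the 7 clock components.

    Needs the full 11-vector: active HSF1 and induced HSP enter the Per/Cry
    transcription term.
    """
    y = np.asarray(state, dtype=float)
    aH, H = y[2], y[3]
    y1, y2, y3, y4, y5, y6, y7 = y[4:11]
    if y7 <= 0:
        raise DomainError(
            f"CLOCKBMAL1 must be > 0 (got {y7}); it appears in the "
            "competitive-inhibition denominator of the HSF1 entrainment term")
    pm = params
    ent = 1.0 + pm.khsf1 * aH / (pm.Khsf1 + aH + pm.khsf1_ci * H / y7)
    act = (y7 + pm.c) / (pm.k1b * (1.0 + (y3 / pm.k1i) ** pm.p) + y7 + pm.c)
    dy1 = pm.v1b * act * ent - pm.k1d * y1
    dy2 = pm.k2b * y1 ** pm.q - pm.k2d * y2 - pm.k2t * y2 + pm.k3t * y3
    dy3 = pm.k2t * y2 - pm.k3t * y3 - pm.k3d * y3
    y3r = y3 ** pm.r
    dy4 = pm.v4b * y3r / (pm.k4b ** pm.r + y3r) - pm.k4d * y4
    dy5 = pm.k5b * y4 - pm.k5d * y5 - pm.k5t * y5 + pm.k6t * y6
    dy6 = (pm.k5t * y5 - pm.k6t * y6 - pm.k6d * y6
           + pm.k7a * y7 - pm.k6a * y6)
    dy7 = pm.k6a * y6 - pm.k7a * y7 - pm.k7d * y7
    return np.array([dy1, dy2, dy3, dy4, dy5, dy6, dy7])


def rhs(state, T: float, Tavg: float, params: ModelParameters) -> np.ndarray:
    """Full 11-component right-hand side at temperature ``T``."""
    return np.concatenate([cascade_rhs(state, T, Tavg, params),
                           clock_rhs(state, params)])


@dataclass
class Trajectory:
    """Single-cell trajectory: time grid (h) and states (time x 11, nM)."""

    time: np.ndarray
    states: np.ndarray
    schedule: Schedule
    params: ModelParameters

    def __getitem__(self, component: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(component)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.time)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rhs_for_solver(t, y, T, Tavg, pm: ModelParameters):
    # Same equations as cascade_rhs/clock_rhs, written without the guards:
    # the solver may probe slightly negative trial states; admissibility is
    # checked on the output grid instead.
    TS1, TS2, aH, H, y1, y2, y3, y4, y5, y6, y7 = y
    dTS1 = pm.vact0_ts1 * Tavg + pm.vact1_ts1 * (T - Tavg) - pm.vina_ts1 * TS1
    ts1n = TS1 ** pm.n
    dTS2 = pm.vb_ts2 * ts1n / (pm.kb_ts2 ** pm.n + ts1n) - pm.vd_ts2 * TS2
    stim = 1.0 + pm.kT * TS2 / (pm.KT + TS2)
    daH = pm.vact_hsf1 * (pm.HSF1tot - aH) / H * stim - pm.vina_hsf1 * aH
    dH = pm.vb_hsp * aH / H - pm.vd_hsp * H
    ent = 1.0 + pm.khsf1 * aH / (pm.Khsf1 + aH + pm.khsf1_ci * H / y7)
    act = (y7 + pm.c) / (pm.k1b * (1.0 + (y3 / pm.k1i) ** pm.p) + y7 + pm.c)
    dy1 = pm.v1b * act * ent - pm.k1d * y1
    dy2 = pm.k2b * y1 ** pm.q - pm.k2d * y2 - pm.k2t * y2 + pm.k3t * y3
    dy3 = pm.k2t * y2 - pm.k3t * y3 - pm.k3d * y3
    y3r = y3 ** pm.r
    dy4 = pm.v4b * y3r / (pm.k4b ** pm.r + y3r) - pm.k4d * y4
    dy5 = pm.k5b * y4 - pm.k5d * y5 - pm.k5t * y5 + pm.k6t * y6
    dy6 = pm.k5t * y5 - pm.k6t * y6 - pm.k6d * y6 + pm.k7a * y7 - pm.k6a * y6
    dy7 = pm.k6a * y6 - pm.k7a * y7 - pm.k7d * y7
    return (dTS1, dTS2, daH, dH, dy1, dy2, dy3, dy4, dy5, dy6, dy7)


def simulate(params: ModelParameters, schedule: Schedule,
             t_span: tuple[float, float] | None = None, *,
             init=None, dt_out: float = 0.1,
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA") -> Trajectory:
    """Integrate one cell under ``schedule``.

    Piecewise integration with a restart at every schedule discontinuity so
    the Heaviside square wave is represented exactly (no smoothing).  Output
    on a uniform grid of spacing ``dt_out``.
    """
    if t_span is None:
        t_span = (schedule.t_start, schedule.t_end)
    a, b = t_span
    if b <= a:
        raise SimulationError(f"t_span {t_span} must have positive length")
    y = DEFAULT_INITIAL_STATE.copy() if init is None else np.asarray(init, float).copy()
    if y.shape != (11,) or np.any(y <= 0):
        raise SimulationError("initial state must be 11 strictly positive values")

    pieces = schedule.piecewise((a, b))
    ts, ys = [], []
    for lo, hi, T, tavg in pieces:
        grid = a + dt_out * np.arange(int(np.ceil((lo - a) / dt_out - 1e-9)),
                                      int(np.floor((hi - a) / dt_out + 1e-9)) + 1)
        grid = grid[(grid >= lo - 1e-12) & (grid <= hi + 1e-12)]
        t_eval = np.clip(grid, lo, hi)
        sol = solve_ivp(_rhs_for_solver, (lo, hi), y, method=method,
                        t_eval=t_eval if len(t_eval) else None,
                        rtol=rtol, atol=atol, args=(T, tavg, params))
        if not sol.success:
            raise SimulationError(
                f"integration failed in piece [{lo}, {hi}] h: {sol.message}")
        # state handed to the next piece comes from integrating to hi exactly
        if len(sol.t) == 0 or abs(sol.t[-1] - hi) > 1e-9:
            tail = solve_ivp(_rhs_for_solver, (sol.t[-1] if len(sol.t) else lo, hi),
                             sol.y[:, -1] if len(sol.t) else y, method=method,
                             rtol=rtol, atol=atol, args=(T, tavg, params))
            if not tail.success:
                raise SimulationError(
                    f"integration failed in piece [{lo}, {hi}] h: {tail.message}")
            y = tail.y[:, -1]
        else:
            y = sol.y[:, -1]
        if len(sol.t):
            keep = sol.t < hi - 1e-12
            ts.append(sol.t[keep])
            ys.append(sol.y[:, keep].T)
    ts.append(np.array([b]))
    ys.append(y[None, :])
    time = np.concatenate(ts)
    states = np.vstack(ys)

    bad = ~np.isfinite(states) | (states <= 0)
    if bad.any():
        it, ic = np.argwhere(bad)[0]
        raise SimulationError(
            f"state {STATE_NAMES[ic]} became non-positive or non-finite at "
            f"t = {time[it]:.3f} h")
    return Trajectory(time=time, states=states, schedule=schedule, params=params)


def cascade_fixed_point(params: ModelParameters, t_const: float) -> dict:
    """Algebraic steady state of the cascade at constant temperature.

    TS1 and TS2 are closed-form; the actHSF1/indHSP pair is reduced to a 1-D
    root find (indHSP eliminated via its own balance).  Serves as an
    independent oracle for long-horizon integrations.
    """
    if t_const <= 0:
        raise DomainError(f"constant temperature must be > 0, got {t_const}")
    pm = params
    if pm.vina_ts1 <= 0 or pm.vd_ts2 <= 0 or pm.vd_hsp <= 0 or pm.vina_hsf1 <= 0:
        raise DomainError("cascade fixed point needs positive loss rates")
    ts1 = pm.vact0_ts1 * t_const / pm.vina_ts1
    ts1n = ts1 ** pm.n
    ts2 = pm.vb_ts2 / pm.vd_ts2 * ts1n / (pm.kb_ts2 ** pm.n + ts1n) if ts1 > 0 else 0.0
    stim = 1.0 + pm.kT * ts2 / (pm.KT + ts2)

    if pm.vb_hsp == 0:
        raise DomainError("no positive indHSP steady state when vb_hsp = 0")

    def h_of(a):
        # indHSP balance: vb_hsp*a/H = vd_hsp*H
        return np.sqrt(pm.vb_hsp * a / pm.vd_hsp)

    def g(a):
        return (pm.vact_hsf1 * (pm.HSF1tot - a) / h_of(a) * stim
                - pm.vina_hsf1 * a)

    lo, hi = 1e-12 * pm.HSF1tot, pm.HSF1tot * (1 - 1e-12)
    if g(lo) <= 0 or g(hi) >= 0:
        raise DomainError("no positive actHSF1 root in (0, HSF1tot)")
    a_star = brentq(g, lo, hi, xtol=1e-14, rtol=1e-14)
    return {"TS1": ts1, "TS2": ts2, "actHSF1": a_star, "indHSP": h_of(a_star)}
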