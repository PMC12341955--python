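"""End-to-end in-silico experiments and their summary tables.

Each experiment is a pure function of its configuration and seeds: it draws a
population, simulates it under the relevant temperature schedules, and
reduces the trajectories to synchronization summaries.

Desk-scale defaults (200 cells; 40 subjects x 50 cells with a 20-day
pre-entrainment for the individual sweep) keep any experiment within a few
minutes on one core; paper-scale sizes (1,000 cells, 50-day pre-entrainment)
are plain arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationError
from .metrics import (DEFAULT_BURN_IN, peaks, period_of, phase_of,
                      phase_shift, r_syn, sync_report, windowed_r_syn,
                      _circular_mean)
from .params import ModelParameters
from .population import (IndividualSpec, PopulationSpec, sample_individuals,
                         sample_population, simulate_population)
from .schedules import (Schedule, TemperaturePattern, ass_protocol,
                        validation_protocol)

__all__ = [
    "ValidationResult",
    "SweepResult",
    "ASSResult",
    "RegressionResult",
    "run_validation",
    "run_amplitude_sweep",
    "run_mean_sweep",
    "run_arnold_grid",
    "run_ass",
    "run_individual_sweep",
    "fit_sensitivity_regression",
]


# ---------------------------------------------------------------------------
# validation: constant -> rhythmic -> constant protocol
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    """Per-orientation ensemble traces and synchronization timescales."""

    averages: dict            # orientation -> DataFrame(time_h, PerCry_mRNA)
    windowed: dict            # orientation -> DataFrame(t_center, r_syn), 720 h windows
    windowed_fine: dict       # orientation -> same with 24 h windows (timescales)
    phases: dict              # orientation -> per-cell phase array (rhythmic span)
    periods: dict             # orientation -> per-cell period array
    sync_time_h: dict         # time for the 24 h-window R_syn to rise past 0.5
    desync_time_h: dict       # time to fall below 0.5 after rhythm removal
    schedule: dict


def _crossing(centers, values, t0, rising: bool, level: float = 0.5):
    after = centers >= t0
    v = values[after]
    c = centers[after]
    hit = v > level if rising else v < level
    if not hit.any():
        return float("nan")
    return float(c[np.argmax(hit)] - t0)


def run_validation(pop_spec: PopulationSpec | None = None,
                   nominal: ModelParameters | None = None, *,
                   amplitude: float = 3.0, mean: float = 37.0,
                   const_until_day: float = 10.0,
                   rhythmic_until_day: float = 65.0, end_day: float = 90.0,
                   window_h: float = 720.0, step_h: float = 24.0,
                   orientations=("normal", "reversed")) -> ValidationResult:
    """On/off-rhythm validation: constant 37 degC, then a square-wave rhythm
    (normal and reversed variants), then constant again.

    Reports ensemble averages, sliding-window R_syn (the long 720 h windows
    plus a 24 h-window trace that can resolve transition timescales), the
    phase/period distributions during the rhythmic span, and the times for
    the 24 h-window R_syn to cross 0.5 on the way up (synchronization) and
    down (desynchronization).
    """
    pop_spec = pop_spec or PopulationSpec()
    mat = sample_population(pop_spec, nominal)
    out = ValidationResult({}, {}, {}, {}, {}, {}, {}, {})
    for orient in orientations:
        sched = validation_protocol(
            amplitude=amplitude, mean=mean, reversed_=(orient == "reversed"),
            const_until_day=const_until_day,
            rhythmic_until_day=rhythmic_until_day, end_day=end_day)
        ens = simulate_population(mat, sched, components=("PerCry_mRNA",))
        avg = ens.average("PerCry_mRNA")
        w = windowed_r_syn(ens, "PerCry_mRNA", window_h=window_h, step_h=step_h)
        wf = windowed_r_syn(ens, "PerCry_mRNA", window_h=24.0, step_h=24.0)
        t_on, t_off = const_until_day * 24.0, rhythmic_until_day * 24.0
        rep = sync_report(ens, "PerCry_mRNA",
                          window=(t_on + DEFAULT_BURN_IN, t_off))
        out.averages[orient] = pd.DataFrame(
            {"time_h": ens.time, "PerCry_mRNA": avg})
        out.windowed[orient] = w
        out.windowed_fine[orient] = wf
        out.phases[orient] = rep.phases
        out.periods[orient] = rep.periods
        c = wf["t_center"].to_numpy()
        v = wf["r_syn"].to_numpy()
        out.sync_time_h[orient] = _crossing(c, v, t_on, rising=True)
        out.desync_time_h[orient] = _crossing(c, v, t_off, rising=False)
        out.schedule[orient] = sched
    return out


# ---------------------------------------------------------------------------
# amplitude / mean / Arnold sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """One record per grid point plus the per-point SyncReports."""

    table: pd.DataFrame
    reports: dict = field(default_factory=dict)


def _steady_amplitude(series, time, burn_in):
    m = time >= burn_in
    return float(series[m].max() - series[m].min())


def run_amplitude_sweep(pop_spec: PopulationSpec | None = None,
                        nominal: ModelParameters | None = None, *,
                        amplitudes=(0.0, 1.0, 3.0, 5.0),
                        include_khsf1_zero: bool = True,
                        mean: float = 37.0, t_end: float = 1680.0,
                        burn_in: float = DEFAULT_BURN_IN) -> SweepResult:
    """Zeitgeber-strength sweep: R_syn of actHSF1 and Per/Cry mRNA versus
    temperature amplitude, including the constant-temperature point (0) and
    the decoupled control (khsf1 = 0)."""
    pop_spec = pop_spec or PopulationSpec()
    nominal = nominal or ModelParameters()
    mat = sample_population(pop_spec, nominal)
    window = (burn_in, t_end)
    rows, reports = [], {}

    def one(label, cells, amplitude):
        sched = Schedule.rhythmic(
            TemperaturePattern(mean=mean, amplitude=amplitude), t_end=t_end) \
            if amplitude > 0 else Schedule.constant(mean, t_end)
        ens = simulate_population(cells, sched,
                                  components=("actHSF1", "PerCry_mRNA"))
        rec = {"label": label, "amplitude": amplitude,
               "khsf1_zero": label == "khsf1=0"}
        for comp in ("actHSF1", "PerCry_mRNA"):
            rep = sync_report(ens, comp, window=window)
            reports[(label, comp)] = rep
            rec[f"r_syn_{comp}"] = rep.r_syn
            rec[f"ensemble_period_{comp}"] = rep.ensemble_period
            rec[f"ensemble_phase_{comp}"] = rep.ensemble_phase
            rec[f"ensemble_amplitude_{comp}"] = _steady_amplitude(
                ens.average(comp), ens.time, burn_in)
        rows.append(rec)

    for dT in amplitudes:
        one(f"dT={dT:g}", mat, float(dT))
    if include_khsf1_zero:
        dec = mat.copy()
        from .params import PARAM_NAMES

        dec[:, PARAM_NAMES.index("khsf1")] = 0.0
        one("khsf1=0", dec, 3.0)
    return SweepResult(pd.DataFrame(rows), reports)


def run_mean_sweep(pop_spec: PopulationSpec | None = None,
                   nominal: ModelParameters | None = None, *,
                   means=(32.0, 34.0, 37.0, 40.0), amplitude: float = 3.0,
                   t_end: float = 1680.0,
                   burn_in: float = DEFAULT_BURN_IN) -> SweepResult:
    """Zeitgeber-average sweep at fixed amplitude: single-cell actHSF1 level
    scales with the mean temperature while Per/Cry synchronization stays
    approximately flat."""
    pop_spec = pop_spec or PopulationSpec()
    mat = sample_population(pop_spec, nominal)
    window = (burn_in, t_end)
    rows, reports = [], {}
    for tm in means:
        sched = Schedule.rhythmic(
            TemperaturePattern(mean=float(tm), amplitude=amplitude), t_end=t_end)
        ens = simulate_population(mat, sched,
                                  components=("actHSF1", "PerCry_mRNA"))
        rep = sync_report(ens, "PerCry_mRNA", window=window)
        reports[(float(tm), "PerCry_mRNA")] = rep
        m = ens.time >= burn_in
        rows.append({
            "mean_temperature": float(tm),
            "actHSF1_cell_average": float(ens.component("actHSF1")[:, m].mean()),
            "r_syn_actHSF1": r_syn(ens, "actHSF1", window=window),
            "r_syn_PerCry_mRNA": rep.r_syn,
            "ensemble_phase_PerCry_mRNA": rep.ensemble_phase,
        })
    return SweepResult(pd.DataFrame(rows), reports)


def run_arnold_grid(pop_spec: PopulationSpec | None = None,
                    nominal: ModelParameters | None = None, *,
                    periods=(20.0, 22.0, 24.0, 26.0, 28.0),
                    amplitudes=(1.0, 3.0, 5.0), mean: float = 37.0,
                    t_end: float = 1680.0, burn_in: float = DEFAULT_BURN_IN,
                    entrain_tol_h: float = 0.1) -> SweepResult:
    """Entrainment region on the zeitgeber period x amplitude plane.

    A grid point counts as entrained when the realized ensemble Per/Cry
    period matches the zeitgeber period within ``entrain_tol_h`` over the
    steady stage.  The ensemble phase is reported relative to the cold-phase
    onset.
    """
    pop_spec = pop_spec or PopulationSpec()
    mat = sample_population(pop_spec, nominal)
    rows, reports = [], {}
    for tau in periods:
        for dT in amplitudes:
            pat = TemperaturePattern(mean=mean, amplitude=float(dT),
                                     period=float(tau))
            sched = Schedule.rhythmic(pat, t_end=t_end)
            ens = simulate_population(mat, sched, components=("PerCry_mRNA",))
            window = (burn_in, t_end)
            rep = sync_report(ens, "PerCry_mRNA", window=window,
                              reference="cold")
            reports[(float(tau), float(dT))] = rep
            per = rep.ensemble_period
            rows.append({
                "zeitgeber_period": float(tau),
                "amplitude": float(dT),
                "ensemble_period": per,
                "entrained": bool(np.isfinite(per)
                                  and abs(per - tau) < entrain_tol_h),
                "r_syn_PerCry_mRNA": rep.r_syn,
                "ensemble_phase_vs_cold_onset": rep.ensemble_phase,
            })
    return SweepResult(pd.DataFrame(rows), reports)


# ---------------------------------------------------------------------------
# alternating shift schedules
# ---------------------------------------------------------------------------

@dataclass
class ASSResult:
    """Phase dynamics and 24 h-windowed synchrony under a shift schedule."""

    spec: str
    windowed: pd.DataFrame        # t_center, r_syn (24 h windows, whole run)
    ensemble_peaks: pd.DataFrame  # peak_time_h, phase_h of the mean field
    pre_phase_h: float
    post_phase_h: float
    phase_shift_h: float
    mean_post_r_syn: float
    schedule: Schedule


def run_ass(spec: str, pop_spec: PopulationSpec | None = None,
            nominal: ModelParameters | None = None, *,
            pre_days: float = 50.0, post_days: float = 100.0,
            dTr: float | None = None, pattern: TemperaturePattern | None = None,
            window_h: float = 24.0, post_phase_units: int = 3) -> ASSResult:
    """Simulate the shift-work protocol: ``pre_days`` of the normal pattern,
    then the alternating schedule ``spec`` ("N-n1:n2", R:N order).

    ``dTr`` overrides the amplitude of the reversed-pattern blocks.  The
    long-run phase is the circular-mean Per/Cry mean-field peak phase over
    the final ``post_phase_units`` schedule units, referenced to the normal
    pattern's warm onset (ZT0) so the shift against the pre-shift phase is
    well defined.
    """
    pop_spec = pop_spec or PopulationSpec()
    pattern = pattern or TemperaturePattern()
    rev = (TemperaturePattern(mean=pattern.mean, amplitude=dTr,
                              period=pattern.period, reversed_=True)
           if dTr is not None else None)
    sched = ass_protocol(spec, pre_days=pre_days, post_days=post_days,
                         pattern=pattern, reversed_pattern=rev)
    mat = sample_population(pop_spec, nominal)
    ens = simulate_population(mat, sched, components=("PerCry_mRNA",))
    t, avg = ens.time, ens.average("PerCry_mRNA")
    t_switch = pre_days * 24.0

    pre_mask = t <= t_switch
    pre_phase = phase_of(avg[pre_mask], t[pre_mask], sched,
                         burn_in=max(t_switch - 72.0, 0.0))

    unit_h = float(spec.split("-")[0]) * 24.0
    pk = peaks(avg, t, burn_in=0.0)
    phases = pk % pattern.period
    tail = pk >= t[-1] - post_phase_units * unit_h
    post_phase = (_circular_mean(phases[tail], pattern.period)
                  if tail.sum() >= 2 else float("nan"))

    w = windowed_r_syn(ens, "PerCry_mRNA", window_h=window_h)
    post = w["t_center"] >= t_switch
    return ASSResult(
        spec=spec,
        windowed=w,
        ensemble_peaks=pd.DataFrame({"peak_time_h": pk, "phase_h": phases}),
        pre_phase_h=pre_phase,
        post_phase_h=post_phase,
        phase_shift_h=phase_shift(post_phase, pre_phase, pattern.period),
        mean_post_r_syn=float(w.loc[post, "r_syn"].mean()),
        schedule=sched,
    )


# ---------------------------------------------------------------------------
# individualized responses
# ---------------------------------------------------------------------------

DEFAULT_SUBJECT_SCHEDULES = ("nominal", "7-6:1", "7-5:2", "7-3:4")


def run_individual_sweep(ind_spec: IndividualSpec | None = None,
                         nominal: ModelParameters | None = None, *,
                         cells_per_subject: int = 50,
                         schedules=DEFAULT_SUBJECT_SCHEDULES,
                         pre_days: float = 20.0, post_days: float = 28.0,
                         rel_width: float = 0.10,
                         window_h: float = 24.0) -> pd.DataFrame:
    """Mean Per/Cry R_syn per subject and schedule.

    Each subject is a sensing triple (``vact0_ts1``, ``vact1_ts1``,
    ``kb_ts2``); its cell population is drawn around the subject's modified
    nominal parameters (seeded per subject).  The reported quantity is the
    time-average of the 24 h-windowed R_syn over the whole post-switch
    course ("nominal" uses the normal pattern throughout and the same
    averaging span).
    """
    ind_spec = ind_spec or IndividualSpec()
    nominal = nominal or ModelParameters()
    subjects = sample_individuals(ind_spec, nominal)
    t_end = (pre_days + post_days) * 24.0

    built = {}
    for name in schedules:
        if name == "nominal":
            built[name] = Schedule.rhythmic(TemperaturePattern(), t_end=t_end)
        else:
            built[name] = ass_protocol(name, pre_days=pre_days,
                                       post_days=post_days)

    rows = []
    for s, (_, triple) in enumerate(subjects.iterrows()):
        subj_nominal = nominal.replace(**triple.to_dict())
        mat = sample_population(
            PopulationSpec(n_cells=cells_per_subject, rel_width=rel_width,
                           seed=ind_spec.seed * 100003 + s), subj_nominal)
        rec = dict(triple)
        for name, sched in built.items():
            ens = simulate_population(mat, sched, components=("PerCry_mRNA",))
            w = windowed_r_syn(ens, "PerCry_mRNA", window_h=window_h,
                               t_start=pre_days * 24.0)
            rec[f"mean_r_syn[{name}]"] = float(w["r_syn"].mean())
        rows.append(rec)
    df = pd.DataFrame(rows)
    df.index.name = "subject"
    return df


@dataclass
class RegressionResult:
    """OLS of mean R_syn on the sensing triple, one schedule at a time."""

    schedule: str
    coefficients: pd.Series   # const, vact0_ts1, vact1_ts1, kb_ts2
    pvalues: pd.Series
    n_subjects: int
    rsquared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coefficient": self.coefficients,
                             "p_value": self.pvalues})


def fit_sensitivity_regression(table: pd.DataFrame,
                               schedule: str) -> RegressionResult:
    """Ordinary least squares: mean R_syn ~ vact0_ts1 + vact1_ts1 + kb_ts2.

    ``table`` is the output of :func:`run_individual_sweep`.  Standard OLS
    t-test p-values, no multiple-testing correction.
    """
    import statsmodels.api as sm

    ycol = f"mean_r_syn[{schedule}]"
    if ycol not in table.columns:
        raise KeyError(f"no column {ycol!r} in the sweep table")
    X = table[["vact0_ts1", "vact1_ts1", "kb_ts2"]].to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < 4:
        raise SimulationError("design matrix is rank deficient")
    Xc = sm.add_constant(table[["vact0_ts1", "vact1_ts1", "kb_ts2"]])
    res = sm.OLS(table[ycol], Xc).fit()
    return RegressionResult(
        schedule=schedule,
        coefficients=res.params,
        pvalues=res.pvalues,
        n_subjects=int(res.nobs),
        rsquared=float(res.rsquared),
    )
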