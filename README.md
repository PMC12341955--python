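# thermoclock

Simulation of temperature entrainment of peripheral circadian clocks.

Body temperature is a systemic cue that can entrain the autonomous molecular
clocks of peripheral cells, and imposed temperature rhythms can induce,
sustain or disrupt circadian gene expression in cultured cells.
`thermoclock` implements a semi-mechanistic ODE model of this process for
people studying circadian entrainment in vitro or in silico: a square-wave
temperature *zeitgeber* drives a thermosensing cascade (two indirect-response
intermediates TS₁, TS₂ standing in for thermo-TRP activation), which feeds an
HSF1/HSP heat-shock-response module; active HSF1 then entrains a prototypical
Per/Cry–Bmal1 clock gene network by boosting *Per/Cry* transcription.

The package simulates single cells, heterogeneous cell populations
(quasi-random Sobol parameter sampling), and "shift work" style alternating
temperature schedules, and quantifies population synchrony.

## Model

One cell is an 11-state ODE system (concentrations in nM, time in h):

- Sensing: dTS₁/dt = v_act0·T̄ + v_act1·(T − T̄) − v_ina·TS₁, so both the
  magnitude (cycle average T̄) and the variation of the temperature input are
  detected; TS₂ follows TS₁ through a Hill surge.
- Heat-shock response: activation of the free HSF1 pool
  (HSF1_tot − actHSF1) is stimulated by TS₂ and inhibited by the
  HSF1-induced HSP, which also suppresses its own production — the classical
  HSF1/HSP negative feedback.
- Clock network: interlocked feedback loops of *Per/Cry* and *Bmal1*
  transcription, translation, nuclear shuttling and CLOCK/BMAL1 complex
  formation. Active HSF1 multiplies the CLOCK/BMAL1-driven *Per/Cry*
  transcription by a saturating entrainment factor
  1 + k_hsf1·actHSF1 / (K_hsf1 + actHSF1 + k_hsf1,ci·indHSP/CLOCKBMAL1),
  in which HSP competes with CLOCK/BMAL1 for HSF1 activity.

With nominal parameters the isolated clock free-runs at ≈ 23.8 h and a
12 h warm / 12 h cold (W12/C12) 37 ± 1.5 °C square wave entrains every
component to exactly 24 h.

Population synchrony of a component *j* over a time window is the
variance-ratio index

    R_syn,j = Var_t(ȳ_j) / [ (1/N) Σ_i Var_t(y_j,i) ],

the variance of the mean field divided by the mean per-cell variance:
0 = fully desynchronized, 1 = perfect synchrony.

Alternating shift schedules (ASS) are written `"N-n1:n2"`: a repeating
N-day unit spending n₁:n₂ of its days in the reversed (12 h-inverted) and
then the normal pattern, e.g. `7-5:2` = 5 days reversed + 2 days normal
each week.

## Worked example

```python
import thermoclock as tc

params = tc.ModelParameters()                      # nominal parameter set
sched = tc.Schedule.rhythmic(tc.TemperaturePattern(), t_end=1200.0)
traj = tc.simulate(params, sched)                  # one cell, 50 days

per = tc.period_of(traj["PerCry_mRNA"], traj.time)
phi = tc.phase_of(traj["PerCry_mRNA"], traj.time, sched)
print(f"Per/Cry mRNA period: {per:.2f} h")
print(f"Per/Cry mRNA phase (vs warm onset): {phi:.1f} h")

free = tc.simulate(params.replace(khsf1=0.0), tc.Schedule.constant(37.0, 1200.0))
print(f"free-running period: {tc.period_of(free['PerCry_mRNA'], free.time):.1f} h")

mat = tc.sample_population(tc.PopulationSpec(n_cells=200, seed=0))
ens = tc.simulate_population(mat, sched, components=("PerCry_mRNA", "actHSF1"))
print(f"R_syn(actHSF1)     = {tc.r_syn(ens, 'actHSF1', window=(480, 1200)):.3f}")
print(f"R_syn(Per/Cry mRNA) = {tc.r_syn(ens, 'PerCry_mRNA', window=(480, 1200)):.3f}")
```

prints

```
Per/Cry mRNA period: 24.00 h
Per/Cry mRNA phase (vs warm onset): 14.1 h
free-running period: 23.8 h
R_syn(actHSF1)     = 0.998
R_syn(Per/Cry mRNA) = 0.812
```

The entrained *Per/Cry* mRNA peaks 2.1 h after the cold-phase onset and the
rhythm locks a 200-cell heterogeneous population to high synchrony, while
the cascade output actHSF1 tracks the temperature cycle almost perfectly.

Higher-level experiments live in `thermoclock.experiments` (on/off rhythm
validation, amplitude/mean sweeps, Arnold-tongue grids, alternating shift
schedules, and the individualized-sensitivity regression) and are also
exposed as a CLI:

```bash
thermoclock ass 7-5:2 --seed 0 --cells 200 --out-dir runs/ass52
thermoclock individuals --seed 0 --out-dir runs/subjects
thermoclock regress runs/subjects/individual_sweep.csv --out-dir runs/subjects
```

Each command writes CSV tables plus a JSON run manifest (config hash, seed,
output hashes) for bit-for-bit replay.

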