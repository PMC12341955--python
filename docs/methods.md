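# Methods

## Model structure and assumptions

One peripheral cell is modelled as 11 coupled ODEs in three layers.

**Temperature sensing (TS₁, TS₂).** The temperature input is a square wave
(warm plateau T̄ + ΔT/2, cold plateau T̄ − ΔT/2); intermediate TS₁ is produced
in proportion to the cycle mean T̄ ("magnitude sensing", rate `vact0_ts1`)
and to the instantaneous deviation T − T̄ ("variation sensing", `vact1_ts1`),
and decays first-order. This is an indirect-response abstraction of
thermo-TRP channel activation: no specific channel, ion flux or membrane
mechanism is resolved. TS₂ converts TS₁ into a saturating, cooperative
signal (Hill coefficient `n = 3`) — the "surge" of the effector. T̄ is an
explicit input (the mean of the currently active pattern), so experiments
that sweep the zeitgeber mean change it consistently.

**Heat-shock response (actHSF1, indHSP).** The free fraction of a fixed
total HSF1 pool is activated at a rate stimulated by TS₂
(factor 1 + kT·TS₂/(KT + TS₂)) and inhibited multiplicatively by the
HSF1-induced HSP pool (factor 1/indHSP) — the chaperone-sequestration
feedback. HSP production is driven by active HSF1 and inhibited by HSP
itself (`vb_hsp·actHSF1/indHSP`), with first-order decay. Total HSF1 is
constant (only the active fraction cycles), consistent with HSF1 protein
levels being non-rhythmic while HSF1 *activity* is.

**Clock gene network.** A compact Per/Cry–Bmal1 network: CLOCK/BMAL1
activates *Per/Cry* transcription (with a constitutive leak `c` and
cooperative repression by nuclear PER/CRY, exponent `p = 8`); PER/CRY
dimerizes (`q = 2`), shuttles into the nucleus and represses its own
transcription; nuclear PER/CRY activates *Bmal1* (Hill `r = 3`), closing
the positive limb through BMAL1 translation, nuclear import and
CLOCK/BMAL1 complex formation. Temperature enters only through active
HSF1, which multiplies the CLOCK/BMAL1-driven *Per/Cry* transcription by

    1 + khsf1·actHSF1 / (Khsf1 + actHSF1 + khsf1_ci·indHSP/CLOCKBMAL1)

— HSF1 induction saturates, and HSP competes with CLOCK/BMAL1 for HSF1
activity (the non-canonical HSP function). Setting `khsf1 = 0` severs the
cascade→clock coupling entirely; the isolated network is autonomous with a
free-running period of 23.84 h at nominal parameters. With the coupling
active, a constant 37 °C input produces a constant elevated actHSF1
(≈ 1.01 nM) and the single cell free-runs at 24.27 h; the intrinsic-period
statements in the tests therefore use the decoupled configuration.

All 41 parameters carry their conventional printed names
(`thermoclock.params`); rates and capacities must be non-negative and the
Hill/stoichiometry exponents at least 1. Not modelled (out of scope): the
CIRBP/cold-inducible branch of temperature signalling, temperature
compensation (PER phosphoswitch), and any thermoregulatory or SCN feedback
onto the temperature input — the temperature schedule is an exogenous,
imposed signal, as in a culture incubator.

## Numerical integration

The square wave is honoured exactly: integration proceeds piecewise between
schedule discontinuities (warm/cold edges, pattern inversions), restarting
the solver at every switch; no smoothing is applied. Two paths:

- **Single cell** (`thermoclock.simulate`): adaptive LSODA with
  rtol 1e-8 / atol 1e-10 (configurable), dense output every 0.1 h.
  Tolerances this tight are needed for period estimates at the 0.01 h
  level.
- **Populations** (`simulate_population`): a numba-compiled classical RK4
  integrator with a fixed 0.05 h step, recording every 0.25 h. The step is
  well inside the stability region of the stiffest rate (HSF1 inactivation,
  20.65 h⁻¹) and matches the adaptive reference to ~1e-4 h in realized
  period and ~5e-4 nM along the trajectory (asserted in the tests). Fixed
  stepping makes every cell's arithmetic independent of the batch, so
  populations are bit-reproducible, order-independent, and unchanged by
  removing cells.

Positivity is a model requirement (TS₂, indHSP and CLOCK/BMAL1 appear in
denominators). No epsilon guards are added and nothing is clipped — that
would change the dynamics; instead every output state is checked and a
violation raises an error naming the component, time and (for populations)
cell. Initial conditions are unspecified by the underlying model; the
package starts every component at 1 nM and discards a 480 h burn-in before
any metric, which is ample for the globally attracting limit cycle at
nominal parameters.

## Phases, periods, synchrony

Peaks are interior local maxima with prominence ≥ 5% of the post-burn-in
peak-to-trough range (rejecting ripple near the square-wave kinks), refined
by quadratic interpolation. The *steady stage* is the trailing run of
peaks whose spacings vary < 2%; the period is their mean spacing and the
phase is the circular-mean offset of peak times from the most recent
warm-phase onset (the methods-level definition; the cold onset is available
via `reference="cold"`, and the two differ by exactly 12 h for symmetric
patterns). A flat series or a drifting phase (successive cycle phases
differing by more than 0.5 h) is flagged — NaN, never a silent 0. Phase
*differences* are mapped circularly to [−12, 12), so a half-cycle inversion
reports as −12 h (a phase advance).

R_syn windows: 1200 h for steady-state characterization, sliding 720 h
windows for the long on/off validation protocol, and sliding 24 h windows
for shift-schedule dynamics. A window over which every cell is constant
makes the index 0/0; it is reported as NaN with a degeneracy flag.

## Populations, subjects, and calibrated heterogeneity

A cell population shares the schedule and initial state; heterogeneity
comes only from parameters, sampled with a scrambled Sobol sequence
(deterministic per seed). The 37 continuous kinetic parameters are varied
uniformly within ±`rel_width` of nominal; the integer Hill exponents
(n, p, q, r) are held fixed — perturbing cooperativity integers has no
clean biological reading in an ensemble.

The sampling width is not identifiable from first principles, so it was
calibrated once against the reported synchronization regimes and then
frozen: `rel_width = 0.035` yields steady-state Per/Cry R_syn ≈ 0.83 under
the nominal W12/C12 rhythm (high synchrony), ≈ 0.44 mean windowed R_syn
under the 7-5:2 schedule (partial synchrony, reported ≈ 0.5–0.6), ≈ 0.74
when the reversed-block amplitude is raised to 5 °C (reported ≈ 0.8–0.9)
and ≈ 0.10 falling to ≈ 0.03 when it is lowered to 1 °C (reported decrease
to 0). Free-running periods then disperse with SD ≈ 0.25 h around 24.3 h.
The width is an explicit `PopulationSpec` field.

Subjects are defined by an individualized sensing triple
(`vact0_ts1`, `vact1_ts1`, `kb_ts2`), sampled log-uniformly within
0.5–2 × nominal; each subject carries its own cell population drawn around
its modified nominal parameters.

What the generated populations emulate: dispersed intrinsic periods and
phases, amplitude-dependent entrainment, and schedule-dependent
(de)synchronization. What they do not: intercellular coupling, stochastic
single-cell gene expression, cell division or death, and any real tissue's
parameter covariance structure — so a passing suite shows the model's
population logic is implemented faithfully, not that a particular tissue
behaves quantitatively like this.

## Experiments and default problem sizes

All experiments are pure functions of configuration + seeds. Defaults are
desk-scale — 200-cell populations; the subject sweep uses 40 subjects ×
50 cells with 20 days of pre-entrainment plus 28 days on each alternating
schedule — chosen so that any experiment completes in minutes on one core;
1,000-cell populations and 50-day pre-entrainment are plain configuration.
Sweep summaries report R_syn, ensemble amplitude/period/phase per grid
point. The Arnold-tongue entrainment call is
|ensemble period − zeitgeber period| < 0.1 h over the steady stage.
Alternating shift schedules follow the R:N order (reversed block first in
each unit) with block boundaries on whole days, and the protocol runs the
normal pattern for 50 days before the schedule starts.

The sensitivity regression is ordinary least squares of a subject's mean
windowed R_syn on its sensing triple, with an intercept; standard t-test
p-values and no multiple-testing correction. With the default sampling the
magnitude-sensing coefficient (on `vact0_ts1`) is negative for the nominal
schedule and all three 7-day alternating schedules: tonically elevated TS₁
saturates the downstream Hill stages and the entrainment factor, so the
*rhythmic* component of the HSF1 signal — and with it entrainability —
shrinks.

## Known limitations

- The long-run ensemble phase under 7-5:2 settles ≈ 1.1 h later than a pure
  12 h inversion (shift ≈ −10.9 h rather than −12 h): during each weekly
  cycle the phase relaxes toward the reversed attractor for 5 days and is
  pulled back during the 2 normal days, and the balance point is offset.
  The offset is a single-cell property (independent of population width).
- Synchronization/desynchronization timescales from the on/off validation
  protocol depend on the sliding-window length; the package reports
  crossings of R_syn = 0.5 from 24 h windows, and the population starts
  from a common initial state, so the first constant span begins coherent
  and disperses before the rhythm starts.
- Fixed-step RK4 assumes the stiffest rate is bounded; raising rates such
  as `vina_hsf1` by more than ~2.5× the nominal value would require a
  smaller `dt`.
- Exact ensemble statistics depend on the calibrated sampling width; only
  signs, orderings and entrainment invariants should be read
  quantitatively.
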