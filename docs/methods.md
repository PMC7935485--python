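# Methods

## The receptor model

The AMPAR population is described by a single 13-state continuous-time
Markov scheme. Five closed states C0–C4 represent occupation of the four
glutamate binding sites; each bound level k = 1..4 has one open state O_k
and one desensitized state D_k reachable only from C_k. The only
ligand-dependent transitions are the binding steps C_i → C_{i+1}, whose
pseudo-first-order rate is a rate constant (/ms/µM) times the free
glutamate concentration. Statistical factors for the four identical sites
(4,3,2,1 forward; 1,2,3,4 backward) are written explicitly in the rate
table rather than implied, so an externally supplied table can encode any
convention.

Occupancy evolves by the master equation `dp/dt = A(glu(t)) p`, where the
generator has `A[j,i]` equal to the i→j rate and columns summing to zero.
Because the connectivity is a tree (a chain with leaves), the stationary
distribution is unique at every concentration and satisfies detailed
balance; it is computed from the null space of `A`. Macroscopic current is
ohmic: `I = g_max · Σ_k w_k P(O_k) · (v − E_rev)` with defaults
v = −70 mV, E_rev = 0 mV. The four open states carry equal conductance
weights by default — the alternative of occupancy-graded conductance is
not resolvable from the behaviour the model must reproduce, and the
overall scale is carried by the separately fitted g_max (nS).

Temperature enters as a single Q10 = 2.4 applied multiplicatively to every
rate. This speeds all relaxations by a common factor while leaving every
equilibrium quantity — including the whole dose–response curve — exactly
unchanged, which is also a free consistency check used in the tests. The
shipped table is referenced to 23 °C; simulations of slice recordings use
34 °C (factor 2.4^1.1 ≈ 2.620).

### The calibrated default rate table

The table shipped in `data/default_rates.yaml` is produced by
`scripts/calibrate_rate_table.py`. The tree topology makes equilibrium
occupancies depend only on the per-site dissociation constant
K_d = k_off/k_on and the branch equilibrium constants E_k = β_k/α_k
(open/closed) and F_k = δ_k/γ_k (desensitized/closed), with closed-state
weights binomial in glu/K_d. The calibration solves
(K_d, E_12, E_34, F_12, F_34) exactly against three equilibrium targets:

* the steady-state dose–response peaks at 32 µM (stationarity of the
  current there);
* 54.2% of receptors are agonist-free (C0) at 5 µM glutamate;
* the 1 mM steady-state current is 40% of the peak value (a bell shape
  with substantial, but incomplete, high-concentration desensitization —
  the 0.40 ratio is a package choice, since only the inequality is
  documented behaviour).

The solution (K_d = 100 µM, E_12 = 2.20, E_34 = 1.50, F_12 = 0.71,
F_34 = 6.16) places the deep desensitization on the 3–4-bound branches:
receptors with three or four glutamates bound have a lower equilibrium
open fraction (0.17) than receptors with one or two (0.56), which is what
makes the dose–response non-monotonic. Absolute rates then set the time
scales: k_on = 0.01 /µM/ms per free site, channel closing α = 3 /ms
(deactivation after transmitter removal in a few ms at 23 °C), recovery
from shallow desensitization γ_12 = 0.06 /ms (~17 ms) and from deep
desensitization γ_34 = 0.008 /ms (125 ms), giving slow recovery of the
fast EPSC and a long memory of high-concentration exposure. These kinetic
values are package choices constrained by qualitative behaviour, not fits
to any recording.

## Propagation paths

Three integrators are exposed and cross-checked against each other:

* `expm` (reference): per-sample matrix exponential of `A(c)·dt`,
  treating the concentration as piecewise-constant over each sampling
  interval (left-sample value). Exactly probability-conserving.
* `ode`: LSODA on the same piecewise-constant concentration with
  `max_step = dt`, tolerances down to 1e-10; agrees with `expm` to <1e-5
  on stiff step protocols.
* `grid` (fast path, used inside fitting): `expm(A(c)·dt)` precomputed on
  a 512-point logarithmic concentration grid spanning 1e-3–1e5 µM; each
  sample step applies the propagator interpolated linearly (in log c)
  between the two bracketing grid entries, in a numba kernel. Exact zeros
  bypass the grid via the zero-concentration propagator. Interpolated
  convex combinations of column-stochastic matrices remain
  column-stochastic, so probability conservation is exact; the
  interpolation error against `expm` is ~1e-5 in occupancy on train
  stimuli. The grid depends only on (scheme, dt) and is cached across a
  fit's objective evaluations.

## The glutamate field

A release event deposits M molecules at a point; the concentration at
distance r follows the instantaneous point-source solution with effective
diffusion coefficient D_eff = D/λ² and the released amount concentrated by
the extracellular volume fraction: C = (M/α)(4πD_eff τ)^{-3/2}
exp(−r²/4D_eff τ). Defaults α = 0.21, λ = 1.55, and D = 0.33 µm²/ms (the
standard free-solution value for glutamate; note 0.33 µm²/ms ≡ 0.33e-5
cm²/s). The kernel peaks at τ* = r²/6D_eff and satisfies the mass balance
α∫(C − ambient)dV = M exactly (checked by quadrature to <0.5%). Trains
superpose linearly with no presynaptic depression; the ambient floor is a
flat additive constant added once per train — it stands for the
EAAT-buffered steady state, not a diffusing species, and there is no
uptake term inside the kernel (EAAT manipulations enter only through the
fitted M and ambient, and optionally g_max).

M is specified in molecules. The synthetic-data default M = 5e6 at
r = 1.23 µm puts the per-event peak concentration at the receptors above
1 mM, the regime the model's current trajectory requires (the slow EPSC
emerges as the concentration decays from >1 mM down through the 32 µM
dose–response peak); single-vesicle contents are orders of magnitude
smaller, but M here is the glutamate *available for diffusion to the
receptors* from the many release sites of the giant MF–UBC contact.

## Stimulus generation and phase convention

The modulated protocol is 5 s silence, 10 s conditioning at the 26 Hz
carrier, then 10 s with instantaneous rate `carrier + d·cos(2πft)`
((f, d) ∈ {(0.3, 6), (1, 40), (3, 120)} Hz). Events are placed at integer-
cycle crossings of the phase `φ(t) = 2π·carrier·t + (d/f)·sin(2πft)`,
refined by bracketed root finding to 0.1 µs; generation is deterministic.
The cosine convention starts the modulated segment at the maximal rate
(continuing the conditioning rhythm with an event at segment onset) and is
recorded as a convention flag in the train metadata. Where d > carrier the
rate goes negative, the phase retreats, and a cycle boundary fires only at
its first forward crossing — no events during silent stretches and no
double events on re-advance. A consequence worth stating: with phase
retreat the mean event rate over whole cycles equals the *net* phase gain
(the carrier rate), which is strictly below the rectified mean of the
instantaneous rate; the two coincide only while the rate stays
nonnegative.

Phase analysis uses the matching convention: the peak stimulus rate maps
to 90° and the trough to 270°, computed from the same rate function the
generator uses, so stimulus and analysis cannot drift apart. PSTHs fold
spikes from the modulated segment over cycles (default 10° bins), spikes
in silent stretches folding normally. The sine fit
`offset + A·sin(2π·k·θ/360 + φ₀)` leaves the cycles-per-period k free
(bounded 0.25–4.5), seeding a bounded least-squares from a half-integer
grid of k with the amplitude/phase obtained by linear projection at each
seed; flat PSTHs return an amplitude-zero fit flagged `flat`. The offset-
response phase is read as the maximum of the fitted curve over the 90–360°
half (on a 0.01° grid), not from raw bins — the declared resolution of the
two-peaked-PSTH ambiguity.

## Fitting

Recorded traces are trial-averaged, artifact-blanked (linear interpolation
over declared windows, *before* filtering so artifact energy cannot ring
through), and low-pass filtered at 1 kHz with a zero-phase 4th-order
Butterworth. The objective is the square norm of residuals between the
preprocessed data and the forward model — stimulus train → diffusion
transient → receptor propagation (initialized at the ambient-concentration
equilibrium, so tonic desensitization is part of every prediction) →
ohmic current plus a constant leak offset. Two numerical points matter for
unbiased estimation and are enforced: the simulated current passes through
the *identical* blank-interpolate-then-filter chain as the data (without
this, the smoothing the blanks impose near window edges biases the fitted
distance r by several percent even at zero noise), and blanked samples are
excluded from the residual. Fits discretize at 10 kHz (2× decimation of
the 20 kHz synthetic acquisition).

The optimizer is a bounded Powell (principal-axis) search on
log-transformed positive parameters with jittered restarts (default 3,
log-sd 0.3, deterministic per seed). The conductance scale and leak enter
the model linearly, so they are profiled out by exact linear least squares
at every objective evaluation; this removes the two best-behaved
directions from the derivative-free search without changing the minimum.
The two-stage protocol mirrors the experimental design: the control fit
frees {M, r, ambient, g_max, leak}; the transporter-block refit frees only
{ambient, M} (optionally g_max, for the spillover-to-extra-receptors
case), inheriting everything else frozen from the paired control fit. The
(M, r) pair covaries strongly — amplitude-versus-width trade-offs of the
transient — which is why r carries the loosest recovery expectation and
its cohort mean is reported only as a qualitative check. Restart spread is
the only uncertainty surrogate; there is no global optimizer and no formal
confidence interval. Non-convergence is flagged on the result, not raised.

## Synthetic data: what it does and does not emulate

`generate_recording` emulates the recording chain: forward-model current
at 20 kHz, white Gaussian noise scaled so its post-1-kHz-filter standard
deviation equals `noise_sd` (default 2 pA per trial — the bandwidth the
fit actually sees; no 1/f component is modelled), a constant leak offset,
biphasic stimulation artifacts at each shock (blanked by preprocessing),
and 6 repeated trials for averaging. Ground truth is always serialized
beside the traces. Paired conditions apply fold changes to one cell's
parameters (defaults: ambient ×2.4, M ×2.3, g_max ×1.0). Cohorts draw
per-cell parameters log-normally around centers (ambient 4.7 µM,
M 5e6, r 1.23 µm, g_max 10 nS; log-sd 0.2–0.35).

`generate_spike_response` is an inhomogeneous Poisson process (thinning)
whose rate is a baseline plus wrapped-Gaussian components locked to the
modulation cycle (onset at 90°, offset at a configurable phase, width 30°).
It is a statistical emulation of UBC firing, not a biophysical neuron:
passing phase-recovery tests shows the analysis chain is correct and
unbiased, not that a conductance-based UBC would produce these PSTHs.
Likewise, recovery of fitting parameters on synthetic cohorts shows the
estimator is consistent when the forward model is the generating model;
real recordings add receptor heterogeneity, multi-site release geometry,
series-resistance artifacts and drift that the generator deliberately
omits, so recovery errors here are a lower bound on real-data uncertainty.

## Validation experiments and problem sizes

`ambientglu.experiments` packages the two closed-loop studies that the
test suite and `scripts/acceptance.py` both run:

* `recovery_study`: 10 synthetic cells × 2 noise realizations (20
  datasets); per dataset a control fit, a paired block refit, and a
  control fit with the ambient parameter pinned at its lower bound for
  the nested error comparison. The protocol is a 50 Hz × 10 train with a
  100 ms baseline and a 1.2 s tail. Median relative errors at default
  noise are ~0.1% (ambient, M) and ~1% (r); recovered fold changes are
  2.40 / 2.30; removing the ambient parameter increases the fit error on
  every dataset.
* `phase_recovery_study`: offset-only spike responses at 205.9° and
  282.9° (10 sweeps of the 1 Hz / depth-40 protocol), recovered through
  PSTH → sine fit → offset-peak phase within 5°.

These sizes keep the full study at a few minutes on one CPU; enlarging
the cohort or the per-cell replication changes none of the conclusions,
only the runtime.

## Degenerate inputs and numerical conventions

Zero concentration is exact (no log-grid clipping); empty trains yield
flat ambient concentration and flat leak current; a flat PSTH is flagged
rather than fitted; disconnected rate tables, negative rates, off-topology
edges, overlapping artifact windows, unsorted event lists and malformed
trace files all raise named validation errors. Probability conservation is
checked at 1e-6 on every propagation and raises on violation. All
randomness flows through explicit integer seeds (numpy Generator); fits,
generators and the pipeline are bit-reproducible given seed and config.

## Known limitations

Single release point and single detection distance per cell; no uptake
term in the diffusion kernel; no NMDAR/mGluR2/GIRK branches; no spike
detection or biophysical spiking model; equal open-state conductances; the
calibrated rate table reproduces documented equilibrium behaviour but is
not the (unpublished) original parameter set, so absolute kinetic
quantities carry the corresponding uncertainty even where equilibrium
quantities are exact.
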