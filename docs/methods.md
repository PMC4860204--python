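# Methods

## The detailed neuron model

`matreduce.hh_core` simulates a single-compartment conductance-based cortical
neuron with six ionic currents:

    C_m dV/dt = -I_L - I_Na - I_Kd - I_M - I_Ca - I_AHP + I_ex

with Hodgkin–Huxley gating `dw/dt = alpha_w(1-w) - beta_w w` for
w ∈ {m, h, n, p, q, r, s} and intracellular Ca²⁺ dynamics

    d[Ca]/dt = -1e5 · I_Ca/(2F) - ([Ca] - [Ca]_inf)/tau_Ca .

Spike-frequency adaptation is carried by two slow K⁺ currents:

- **I_M = g_M p (V - E_K)** — the muscarinic (M-type) current. Its gate p has
  a voltage-dependent time constant `tau_p(V) = tau_max / (3.3 e^{(V+35)/20}
  + e^{-(V+35)/20})`, peaking near 0.28·tau_max around V ≈ -47 mV.
- **I_AHP = g_AHP s (V - E_K)** — the Ca²⁺-activated afterhyperpolarization
  current. Its gate s opens at rate 0.01·[Ca] /ms and closes at rate beta_s,
  so its effective time constant is roughly `tau_s = 1/beta_s`.

Units are ms, mV, µA/cm², µF/cm², mS/cm², µM throughout. Parameter defaults
(`ConductanceParams`): C_m = 1, g_L = 0.1, g_Na = 50, g_Kd = 5, g_M = 0.1,
g_Ca = 0.001, g_AHP = 0.2, E_L = -80, E_Na = 50, E_K = -90, E_Ca = 120,
tau_max = 1000 ms, beta_s = 0.02 /ms, tau_Ca = 200 ms, [Ca]_inf = 0.05 µM.
The physiological ranges explored by the kernel-scaling analyses are
g_M, g_AHP ∈ [0.05, 0.4] mS/cm², tau_max ∈ [0.5, 4] s, beta_s ∈ [0.01, 0.09]
/ms, tau_Ca ∈ [100, 900] ms.

### Numerics

- **Forward Euler at dt = 0.025 ms** (numba-compiled). No adaptive stepping.
  Euler's O(dt) phase error accumulates over long spike trains, so absolute
  spike times drift between dt = 0.025 and dt = 0.01 even though spike
  counts, onset latencies and the interspike-interval sequence agree; the
  convergence tests assert those dt-robust observables.
- Rate functions with removable singularities (alpha_m at -45 mV, alpha_n at
  -43, alpha_q at -27, beta_m at -18) switch to their series limit when the
  scaled argument is below 1e-7.
- Gates are clamped to [0, 1] after each step (excursions are at rounding
  level for the default dt); |V| > 1000 mV is treated as divergence and
  reported with the offending step.
- Spikes are upward 0 mV crossings, linearly interpolated between samples,
  with a 2 ms debounce so one action potential yields one spike time.
- `steady_state` relaxes from a gate-equilibrium initialization until every
  state derivative falls below 1e-9 per ms (up to 30 s simulated time); a
  0 mV crossing during relaxation raises an error, since a "steady state"
  under a spiking current does not exist.

## Input currents

Two stimulus classes (`matreduce.stimuli`):

- **Constant current with a delta pulse.** The holding current that fixes the
  membrane at V_c is computed in closed form from the gate equilibria at V_c
  (the external current must cancel the total ionic current at the fixed
  point), verified by relaxation and refined by bisection if needed — the
  realized steady voltage is within 0.05 mV of V_c. The delta pulse is one
  grid sample of extra amplitude q_c/dt, so the discrete charge is exactly
  q_c = C_m(-45 - V_c): it shifts the voltage to -45 mV, above threshold.
- **Ornstein–Uhlenbeck current** with mean mu, stationary SD sigma and
  correlation time tau_syn = 2 ms, generated with the exact AR(1)
  discretization (stationary initialization), so its moments are unbiased at
  any dt and the series is bit-reproducible under a seed.

`tune_mean_for_rate` brackets and bisects mu (with sigma slaved as sigma = mu
or sigma = 2mu) until the simulated rate is within 10 % of the target.

## The spike-threshold probe

The instantaneous spike threshold theta_V(t0) is measured by bisection on a
candidate post-shift voltage c ∈ [-80, 0] mV: the probe sets V → c at t0
(gates and [Ca] untouched — equivalent to an instantaneous charge injection),
watches 50 ms for a spike, and keeps the subinterval that brackets the
spiking/non-spiking transition, terminating at 1e-4 mV. The probe is
deterministic; repeated probes agree exactly.

Built on the probe and a holding-plus-pulse protocol (hold at V_c = -70 mV,
evoke exactly one spike):

- **Spike-triggered currents** eta_ion(t) = I_ion(t_sp + t) - baseline. The
  analysis window is [4, 500] ms after spike onset because the fast Na⁺, Kd
  and Ca²⁺ transients vanish within a few ms. eta_M is a single exponential
  in tau_p(v̄) (v̄ = mean voltage over the window); eta_AHP is the
  double-exponential a(e^{-t/tau_Ca} - e^{-t/tau_s}), peaking at
  ln(tau_Ca/tau_s)·tau_Ca·tau_s/(tau_Ca - tau_s) ≈ 92 ms for the defaults.
- **Threshold variation** h_ion(lag) compares the post-spike threshold decay
  of a neuron with the slow conductance against the same neuron without it.
  Each neuron's own *resting* threshold (probed before the evoked spike) is
  subtracted first: the slow conductance also shifts the resting threshold
  tonically, and that offset belongs to theta_V_inf, not to the
  spike-triggered kernel. With this convention h_M is a clean single
  exponential (R² > 0.99) and h_AHP shows the characteristic delayed hump.
- Per-spike increments delta_p and delta_Ca are read directly from the
  simulation (value 4 ms post-spike minus the pre-pulse baseline); the spike
  width w_sp and spike voltage change delta_V are measured from the waveform
  (time above -45 mV around the 0 mV crossing; ≈ 1.8 ms and ≈ -24 mV here).

## The reduced model

The multi-timescale adaptive threshold (MAT) neuron integrates the input
without reset,

    du/dt = -u/tau_m + I_ex/C_m,

and spikes when u reaches theta_u(t) = theta_inf + Σ_k H_u(t - t_k) with the
kernel

    H_u(t) = alpha_0 e^{-t/tau_m} + alpha_M e^{-t/tau_p(v̄)}
             + alpha_AHP (e^{-t/tau_Ca} - e^{-t/tau_s}),   t > 0.

Subthreshold integration is exact (exponential update per step); each kernel
exponential is a decaying accumulator incremented at spikes, giving O(1) cost
per step independent of the spike history. Spike times are reported at the
grid point of the first crossing (no sub-step interpolation, matching the
4 ms evaluation granularity). A 2 ms refractory period (configurable, 0
allowed) prevents same-step re-crossing, since u is never reset.

`assemble_theory_kernel` builds H_u bottom-up from the probe measurements:
the spike-shape term -delta_V e^{-(t-w_sp)/tau_m}, the membrane-filtered
spike-triggered currents (the convolution of an exponential with
e^{-t/tau_m}/C_m has the closed form a·tau·tau_m/(tau - tau_m)·(e^{-t/tau} -
e^{-t/tau_m})), and the threshold variations h_ion, projected onto the MAT
family by least squares. Because this construction is deterministic, it is
the estimator used for the kernel-scaling trend checks (alpha_M ∝ g_M,
decreasing in tau_max; alpha_AHP decreasing in beta_s and tau_Ca).

## Fitting by coincidence-factor maximization

The spike-prediction benchmark uses the coincidence factor

    Gamma = (N_c - <N_c>)/(N_d + N_m) · 2/(1 - 2 nu Delta),  Delta = 4 ms,

with N_c counted by greedy in-order one-to-one matching (equal to the
maximum bipartite matching for this interval structure; verified against a
brute-force oracle) and <N_c> = 2 nu N_d Delta the Poisson chance term at
the prediction's rate nu. Note the one-to-one count is marginally below the
Poisson chance term, so independent trains score ≈ 0 with a small negative
offset of order (2 nu Delta)²; Gamma(x, x) = 1 exactly.

The structural parameters are fixed from biophysics: C_m = 1 µF/cm²,
tau_m = C_m/g_tot ≈ 10 ms, tau_Ca = 200 ms, tau_s = 1/beta_s = 50 ms, and
tau_p evaluated at the mean subthreshold voltage of the training trace
(samples below -40 mV; 150 ms when no trace is supplied). The free threshold
parameters — {theta_inf, alpha_0, alpha_M} or {theta_inf, alpha_0,
alpha_AHP} — maximize Gamma on 50 s of training data.

Gamma is piecewise constant, so a single simplex run stalls on plateaus and
on the curved (theta_inf, alpha_slow) valley that fixes the tonic threshold
level. The optimizer therefore runs in stages: a coarse grid around the
initial guess (30, 35, 3) mV, a chain of Nelder–Mead runs re-expanded from
the incumbent, seeded jittered restarts (5 by default), and two
per-coordinate refinement sweeps. On synthetic data with planted parameters
this recovers theta_inf and alpha_M within a few percent and alpha_0 within
~5 %, with training Gamma ≈ 0.96 (the exact-parameter point Gamma = 1 is a
measure-zero needle on the plateau).

## Analytics

Under constant drive I_0 the periodic solution satisfies
theta_inf + eta_T_inf(T) = I_0 tau_m, where eta_T_inf sums the kernel over
the infinite periodic spike history (geometric series per exponential). The
period is found by a log-spaced bracket scan plus Brent root-finding; with
an AHP kernel eta_T_inf can be non-monotone, and the smallest root with
negative threshold slope — the attracting orbit — is taken. Without slow
terms the rate has the closed form f = 1/(tau_m log(1 + alpha_0/(I_0 tau_m -
theta_inf))), which vanishes only logarithmically at rheobase.

Noise sensitivity: a potential perturbation delta_u present at the spike
time shifts the next spike by delta_T = delta_u/(d eta_T_inf/dt)(T); the
package reports |delta_T|/T (delta_u = 1 mV by default). Two caveats pinned
by tests: the full periodic finite difference differs from this one-interval
expression by a factor (1 - e^{-T/tau_m}), so quantitative agreement holds
for T ≫ tau_m; and in simulation the bump must be injected shortly before
the upcoming spike (it decays with tau_m). The ISI coefficient of variation
has no closed form here and is obtained by simulation via `isi_stats`, which
also computes the lag-1 serial ISI correlation rho_1 (the slow kernels make
it negative under OU drive).

## The synthetic-data generator and what passing tests mean

All data are generated internally; `matreduce.fixtures` pins the study
conditions: the three canonical neurons (no adaptation; I_M with g_M = 0.2
for the benchmark, 0.1 for the rectangular-current demonstration; I_AHP with
g_AHP = 0.2), the rectangular-current protocol (200–1300 ms, 2.5/3.2/3.1
µA/cm²), and the OU input grids — (mu, sigma) = (1.98, 1.98), (2.45, 2.45),
(3.24, 3.24), (1.33, 2.66), (1.65, 3.30), (2.22, 4.44) for the I_M neuron
and (1.84, 1.84), (2.15, 2.15), (2.75, 2.75), (1.28, 2.56), (1.58, 3.16),
(2.10, 4.20) for the I_AHP neuron — which drive the neurons at ≈ 5, 10 and
20 Hz under sigma = mu (moderate noise) and sigma = 2mu (high noise).

The generator emulates in-vivo-like current statistics, not real recordings:
there is no channel noise, no conductance (multiplicative) synaptic input,
no dendritic structure, and the "ground truth" spike trains come from the
same model family that is being reduced. Passing tests therefore demonstrate
the internal consistency and predictive power of the reduction for this
model class, not performance on experimental data.

### Problem sizes

The spike-prediction benchmark runs the full protocol: 6 conditions × (50 s
train + 50 s test) per neuron at dt = 0.025 ms. Deterministic probe analyses
use single evoked spikes and ≤ 1 s windows. The MAT recovery dataset is 50 s.
The kernel-trend checks use the deterministic probe estimator rather than
repeated stochastic fits, whose per-condition scatter (± ~1 mV in the slow
weight) would otherwise mask the parameter trends.

## Known limitations

- Only spike-triggered components of the slow currents enter the reduction;
  subthreshold activation of I_M under large voltage fluctuations degrades
  the approximation (visible as slightly lower Gamma at sigma = 2mu).
- The proportionality constants linking (g_M, tau_max, beta_s, tau_Ca) to
  the kernel weights are fitted numerically; only scaling relations are
  asserted.
- Na⁺-inactivation threshold modulation (fast, voltage-dependent) is outside
  the model; the probe measures only the slow, spike-triggered variation.
- Gamma depends on the evaluation granularity: spike times of the reduced
  model are grid-resolved, and the greedy coincidence count carries the
  small negative chance offset noted above.
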