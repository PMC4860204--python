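# matreduce

Reduction of detailed conductance-based cortical neuron models with slow K⁺
currents to multi-timescale adaptive threshold (MAT) models.

Cortical pyramidal neurons adapt: under a sustained stimulus their firing
rate drops, driven mostly by two slow K⁺ currents — the voltage-gated
M-type current I_M and the Ca²⁺-activated afterhyperpolarization current
I_AHP. `matreduce` is for computational neuroscientists who want to know how
these biophysical mechanisms shape spike generation without carrying a full
Hodgkin–Huxley model around. It simulates the detailed neuron, measures its
instantaneous spike threshold, and reduces it to a linear, analytically
tractable model:

    du/dt = -u/τ_m + I_ex/C_m          (no reset after spikes)
    spike when u(t) ≥ θ(t)
    θ(t) = θ∞ + Σ_k H(t - t_k)
    H(t) = α₀ e^(-t/τ_m) + α_M e^(-t/τ_p) + α_AHP (e^(-t/τ_Ca) - e^(-t/τ_s))

The adaptation currents become exponential components of a spike-triggered
threshold kernel H(t): I_M contributes a monotonically decaying term with the
p-gate time constant τ_p, I_AHP a delayed hump set by the Ca²⁺ and s-gate
time constants. The package covers the full chain:

- `hh_core` — conductance-based simulation (forward Euler, numba-compiled)
  and spike detection;
- `stimuli` — pulse and Ornstein–Uhlenbeck input currents, with holding- and
  rate-calibration routines;
- `threshold_probe` — bisection measurement of the instantaneous spike
  threshold, spike-triggered currents η_ion(t), threshold variations
  h_ion(t), and their exponential fits;
- `mat_model` — exact-integration simulation of the reduced model;
- `reduction` — fitting {θ∞, α₀, α_slow} by coincidence-factor (Γ)
  maximization, and assembling the kernel bottom-up from probe measurements;
- `evaluation` — coincidence factor Γ (window Δ = 4 ms) and ISI statistics
  (rate, Cv, lag-1 serial correlation ρ₁);
- `analytics` — closed-form f-I curves, periodic solutions, and the noise
  sensitivity δT/T of the reduced model.

## Worked example

Fit a reduced model to an I_M neuron driven by in-vivo-like noise, then
predict its spike times on unseen input:

```python
import numpy as np
from matreduce import ConductanceParams, simulate, detect_spikes, steady_state
from matreduce.stimuli import OUSpec, ou_current
from matreduce.reduction import fit_mat
from matreduce.mat_model import simulate_mat
from matreduce.evaluation import coincidence_factor, isi_stats

neuron = ConductanceParams(g_m=0.2, g_ahp=0.0)   # adaptation via I_M
rest = steady_state(neuron, 0.0)

drive = OUSpec(mu=2.45, sigma=2.45, tau_syn=2.0, seed=42)
current = ou_current(drive, 50_000.0)            # 50 s, dt = 0.025 ms
trace = simulate(neuron, current, init=rest)
spikes = detect_spikes(trace)
print(f"detailed model: {spikes.n} spikes, {spikes.rate_hz:.1f} Hz")

fit = fit_mat((current, spikes), v_trace=trace.v)
k = fit.mat.kernel
print(f"fitted threshold: theta_inf = {fit.mat.theta_inf:.1f} mV, "
      f"alpha_0 = {k.alpha_0:.1f} mV, alpha_M = {k.alpha_m:.2f} mV "
      f"(tau_p = {fit.tau_p:.0f} ms)")

test_current = ou_current(OUSpec(mu=2.45, sigma=2.45, seed=43), 50_000.0)
test_spikes = detect_spikes(simulate(neuron, test_current, init=rest))
pred, _, _ = simulate_mat(fit.mat, test_current)
gamma = coincidence_factor(test_spikes, pred, delta=4.0)
print(f"test-set prediction: Gamma = {gamma.gamma:.3f} "
      f"({gamma.n_c}/{gamma.n_d} coincidences)")
```

Output:

```
detailed model: 500 spikes, 10.0 Hz
fitted threshold: theta_inf = 31.7 mV, alpha_0 = 25.8 mV, alpha_M = 4.50 mV (tau_p = 188 ms)
test-set prediction: Gamma = 0.822 (418/519 coincidences)
```

Reading the numbers: the OU mean μ = 2.45 µA/cm² is calibrated so the
detailed neuron fires at 10 Hz. The fitted resting threshold θ∞ and fast
weight α₀ set the overall excitability; the slow weight α_M ≈ 4.5 mV is the
per-spike threshold increment decaying with τ_p ≈ 190 ms — the reduced
fingerprint of the M-current. Γ = 0.82 means 82 % of spikes (after chance
correction) are predicted to within ±4 ms on data the fit never saw; a
rate-matched Poisson train would score Γ ≈ 0. The same trace gives
Cv ≈ 0.72 and a negative serial ISI correlation (ρ₁ ≈ -0.17), the signature
of threshold fatigue: a long interval lets the threshold decay, shortening
the next one.

A thin CLI mirrors the stages (`matreduce simulate | probe-threshold |
extract-kernel | fit-mat | evaluate | isi-stats | fi-curve | fixtures |
run`); all outputs are columnar text or JSON with provenance sidecars.

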