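# Methods

This note documents the model, the numerical choices, and which numbers
in the shipped parameter sets are measured versus synthetic. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Channel models

Gating variables relax first-order toward Boltzmann steady states,

    m∞(V) = 1/(1 + e^((V½,act − V)/q_act)),
    h∞(V) = 1/(1 + e^((V − V½,inact)/q_inact)),

with voltage-dependent time constants from a rate scheme
τ(V) = 1/(α(V)+β(V)). Rates use the linoid ("trap") form
α = r·(V−θ)/(1−e^(−(V−θ)/q)): 4 parameters (r_a, r_b, θ, q) for
activation kinetics and 6 (r_d, r_g, θ₁, θ₂, q_d, q_g) for inactivation
kinetics, whose two half-points allow asymmetric onset and recovery
limbs. Decoupling steady states from rates is deliberate: it lets
species differences in voltage dependence and in kinetics be fitted,
compared and swapped independently (the hybrid-channel analyses depend
on it).

The Na⁺ conductance is gmax·m³h. The activation exponent p = 3 is a
configurable default (`NaChannelModel.p`): it is the standard choice for
this model family and is not independently constrained by the feature
set we fit.

The K⁺ conductance is the sum of three fractions sharing one activation
gate (exponent 2): a fast-inactivating fraction (gate h₁), a
slow-inactivating fraction (gate h₂) and a non-inactivating remainder,

    g_K = gmax·m²·[0.85·(0.6·h₁ + 0.4·h₂) + 0.15].

h₂ has no resolved voltage dependence of its time constant; it uses a
two-regime constant τ — onset when h₂ > h∞, recovery when h₂ < h∞
(defaults 280 / 120 ms). Human and mouse K⁺ models share identical h₁
and h₂ kinetics by construction (`shared_inactivation_k`); only their
steady-state inactivation curves differ.

### What is measured, what is synthetic

The preset V½ values are published cohort means (Na⁺ activation
−32.1/−37.9 mV, inactivation −66.0/−74.8 mV; K⁺ activation −3.0/−7.9 mV,
inactivation −52.7/−65.0 mV; human/mouse). Everything else is a
synthetic reference set, because the full fitted parameter tables are
not publicly available:

* Boltzmann slopes: Na⁺ 5 mV (act) / 7 mV (inact); K⁺ 9 / 6 mV.
* Rate parameters chosen so τ(V) lands in the experimentally reported
  ranges: Na⁺ inactivation τ ≈ 1.0 ms (human) vs 0.55 ms (mouse) at
  0 mV; recovery τ at −80 mV ≈ 4 ms (human) vs ≈ 10 ms (mouse); K⁺
  activation τ ≈ 1.3–1.5 ms at 0 mV, faster in human at hyperpolarized
  potentials.
* The Na⁺ activation *gate* τ is set ~2.5× faster than the τ values
  measured from current traces. An m³ current rises sigmoidally, so a
  compound exponential fit to it systematically overstates the gate
  relaxation time; with gate τ equal to the trace-fit values the model
  cannot reach physiological upstroke speeds at any realistic density.
  The shipped rates make the *protocol-measured* activation τ (slower in
  human than mouse) land in the reported range while the model reaches
  ~420 mV/ms rise speeds.

`species_preset(..., source="table_s2")` fails with an explicit pointer
to this fallback, so code paths that require the original fitted tables
cannot silently run on the synthetic stand-ins.

Temperature is not modeled (no Q10 machinery); the presets are a single
self-consistent kinetic set.

## Compartment and integrator

A single isopotential sphere, diameter 10 μm with the spherical-surface
convention area = π·d² (≈ 314 μm²), Cm = 1 μF cm⁻² (≈ 3.14 pF),
ENa = 53 mV, EK = −101 mV, leak 1 pS μm⁻². Axial resistance (200 Ω·cm)
is carried in the record but plays no role in one compartment. For long
phase-locking runs the conventional variant raises the leak to
2.5 pS μm⁻² and ENa to 100 mV, which prevents depolarization block
during sustained stimulation. We read the phase-locking leak value as
pS μm⁻² (a leak of 2.5 pS cm⁻² would be physically negligible —
~8·10⁻⁹ nS for this compartment).

The leak reversal defaults to −80 mV, the junction-corrected resting
potential of the current-clamp experiments. This choice matters: at
−80 mV the presets reproduce the reported resting Na⁺ availabilities
(G/Gmax ≈ 0.81 human, ≈ 0.63 mouse), whereas resting the mouse model at
−70 mV puts it at h ≈ 0.34 and makes the first AP of every train
anomalously slow (post-AP hyperpolarization then *raises* availability
and every relative-speed ratio exceeds 1). It is configurable.

Integration: gates update analytically (exponential update toward x∞ at
the voltage frozen within the step) and the membrane potential updates
by backward Euler, which is linear in V once conductances are fixed.
Both schemes are unconditionally stable; gate values are clamped to
[0, 1] after each step to absorb floating-point overshoot. Default
dt = 0.025 ms for current clamp, 0.005–0.02 ms for Na⁺ kinetics
protocols. Convergence is tested: halving dt changes the peak Na⁺
current by < 0.5% and the AP peak time by less than one sample. In
current clamp the model settles for 200 ms (gates initialized at steady
state for the starting voltage) before the stimulus; in voltage clamp
gates start at steady state for the first command sample, which makes
equilibrated prepulses exact by construction.

The hot loops are compiled with numba; channel populations are packed
into flat parameter rows (`_kernel.py`). The Python-level gate functions
(`gates.py`) are an independent numpy implementation of the same
formulas, and the test suite cross-checks the two (clamped-gate
relaxation against the closed form).

## Protocols

* **Steady-state activation**: holding −90 mV, steps −80…+60 mV in
  10-mV increments; peak (Na⁺) or late-plateau (K⁺) current converted to
  conductance G = I/(V−E_rev), normalized to the maximum. Steps within
  1 mV of the reversal are excluded. The exact grids are configurable —
  the experimental grids are not fully enumerated in the source
  material.
* **Steady-state inactivation**: 500-ms prepulses −120…−30 mV, test
  pulse 0 mV, normalized peak test current.
* **Recovery from inactivation**: 100-ms conditioning at 0 mV, delays
  (default log-spaced 1–300 ms) at the recovery potential, test pulse;
  the fraction-versus-delay curve is fitted with a single exponential
  toward its asymptote. Fractions are normalized to the rested reference
  peak measured from the same recovery potential, so the long-delay
  limit is 1. For a single-h-gate channel the fitted τ_rec equals
  τ_h(V_rec); the suite asserts agreement within 1%.
* **AP-clamp**: replay of an AP-train voltage command (the synthetic
  stand-in is generated by the spiking model itself and carries its AP
  peak times); per-AP peak ionic currents normalized to AP1. Commands
  are replayed unshifted — the experimental −10 mV junction offset is a
  recording artifact, not model physics.
* **Rheobase**: smallest 3-ms pulse amplitude on a precision grid
  (10 pA for trains, 0.1 pA for phase-locking) that yields an AP (peak
  above 0 mV), found by bisection, which equals the exhaustive grid scan
  because spiking is monotone in the pulse amplitude here.
* **Trains**: n pulses at 150% rheobase, onsets exactly 1000/f ms apart;
  any pulse that fails to fire raises with the failed indices.

## Curve fitting and AP analysis

Monoexponential decay I(t) = a·e^(−t/τ)+b; compound activation fit
I(t) = [1−e^(−(t−d)/τm)]·[a·e^(−(t−d)/τh)+b]; double-exponential decay
with τ_fast < τ_slow enforced by ordering and near-degenerate optima
collapsed to the monoexponential with a flag. All nonlinear fits are
bounded least squares with three starts and 10⁻⁸ tolerances; R² =
1 − SS_res/SS_tot with the uniform inclusion rule R² > 0.9. Offline
filters (zero-phase Butterworth; 14/6/2 kHz for Na⁺ activation /
Na⁺ inactivation / K⁺, 20 kHz for voltage traces) apply only to traces
marked `raw` — clean model output is used unfiltered.

AP threshold: voltage at the last upward crossing of dV/dt = 23 mV/ms
before the dV/dt maximum of each AP (APs segmented at local maxima above
0 mV; derivative by central differences). Rise/fall speeds come as both
the derivative extremum and the 30–70% (70–30%) window linear-fit
variants; amplitude is threshold→peak. Cohort statistics are limited to
seeded percentile-bootstrap CIs.

## Parameter fitting

**CMA-ES channel fits.** Each of m∞, h∞, τm(V), τh(V) is fitted
separately (dimension 2–6) to keep the search well-conditioned. The
starting point comes from a direct least-squares fit; CMA-ES (an
in-package minimal (μ/μ_w, λ) implementation with rank-one and rank-μ
updates, seeded and reproducible) then minimizes the sum of squared
normalized differences to the target means. Residuals are normalized
pointwise by the target magnitude, floored at 5% of the curve maximum —
a per-curve-max normalization would let the small-τ part of a curve
spanning 0.3–13 ms drift by tens of percent while reporting a tiny
error. Parameters are scaled to unit order; σ₀ = 0.3 in scaled units,
population size the standard 4+⌊3 ln n⌋. With `protocol_emulation=on`
the steady-state error is computed by running the actual
activation/availability protocols on each candidate and comparing the
derived curves with a free scale (protocol curves are self-normalized;
the free scale is the Boltzmann gmax_norm convention); τ targets are
always compared on the rate functions directly, which keeps the
emulation affordable and avoids compounding the trace-fit bias discussed
above.

**Powell density fits.** (gmax_Na, gmax_K) are fitted in log space
(positivity by construction; start 100/50 pS μm⁻²) to minimize the plain
sum of squared differences between the first evoked AP's (amplitude,
rise speed, fall speed) and the targets (48.4 mV, 420 mV/ms,
73.1 mV/ms). With unnormalized residuals the rise-speed term dominates,
so the optimizer meets rise and fall closely while the amplitude term
settles at a compromise (~88–93 mV threshold-to-peak for the shipped
presets); the consistency of the objective — re-simulating at the
optimum reproduces exactly the features the optimizer saw, and ±5%
density perturbations increase the error — is what the acceptance suite
asserts.

## Phase-locking

Stimulus: DC + sinusoid (amplitude 15% of rheobase) + Gaussian noise
filtered with a first-order 5-ms exponential filter and rescaled *after*
filtering to SD = 30% of rheobase. The noise stream depends only on
(seed, n, dt): identical seeds give bit-identical traces, so the same
frozen noise is replayed across models. Spike times fold by the cycle
(t mod 1/f) into a 30-bin histogram; a single-cycle sinusoid
(offset + cos + sin, linear least squares) gives M (amplitude) and R
(offset, scaled to Hz by the observation span), and M/R is the locking
index. The closed-form Fourier-coefficient expression on the bin centers
is used as the test oracle. Cutoff: linear interpolation of the first
downward crossing of M/R = 0.4; default scan grid 1–100 Hz.

DC calibration has two exposed modes: the published fixed fractions of
rheobase (0.84 human / 0.94 mouse / 0.83 equal-input), and auto-tuning
the DC to a 12.5-Hz target rate. The fixed fractions are calibrated to
the original fitted channel tables; applied to the synthetic presets
they produce tonic ~90-Hz firing (human) or near-block (mouse), so the
matched-rate pipeline auto-tunes. Because sustained depolarization can
silence the model through Na⁺ inactivation, firing rate is not monotone
in DC; the tuner scans up the rising flank of the rate–DC curve before
bisecting. The first 1 s of each run is discarded as transient (the
source material does not state a discard window).

Pre-AP Na⁺ availability is the mean of the (density-weighted) h gate in
the window 0.8–2.8 ms before each AP peak — we read the garbled printed
window "0.8 to 0.2.8 ms" as this 2-ms window, consistent with the
accompanying "2 ms preceding AP onset" description. APs whose window
precedes the trace start are excluded.

## Synthetic data

The cohort generator draws per-cell channel models around a species
preset: V½ jitter with the published cohort SDs (e.g. Na⁺ 4.9/7.8 mV
human act/inact), slope jitter 0.5 mV, log-normal τ scaling (SD 0.1),
zero covariance (the covariance structure is unknown). Raw traces are
clean protocol simulations plus a linear leak, biexponential capacitive
transients at step edges scaling linearly with step size, and white
Gaussian recording noise; five P/−5 sweeps (command deflection scaled by
−1/5, baseline-subtracted, independently noisy) accompany every trace so
the leak-subtraction path is exercised — subtraction removes the
injected artifacts exactly by construction (linearity), up to the
constant holding-level offset. Every dataset carries its generating
ground truth, and all recovery tests compare against that ground truth,
never against published cohort values.

What the generator does *not* emulate: series-resistance and
capacitance-compensation artifacts, temperature or electrode drift,
inter-parameter covariances, and real channel heterogeneity beyond the
HH model class. Passing recovery tests therefore demonstrate that the
analysis pipeline is correct and unbiased for HH-generated data with
additive artifacts — not that the HH model class captures every feature
of real recordings (slow inactivation modes of K⁺ channels, in
particular, are known to be imperfectly captured).

## Known limitations

* Without the original fitted parameter tables, absolute endpoints tied
  to them (best-fit densities of ~114/29 and ~149/65 pS μm⁻², cutoff
  frequencies of 73 vs 38–42 Hz, pre-AP h medians 0.55/0.45) are not
  reproduced numerically; the package reproduces the protocol structure
  and the species orderings (AP-clamp amplitude stability, train rise
  stability at fitted densities, matched-rate M/R, falling-phase Na⁺
  charge, pre-AP availability). With the synthetic presets both species
  phase-lock out to ~300 Hz, so the interpolated cutoffs land far above
  the published values and their species ordering is seed-dependent;
  they are reported but not asserted.
* The K⁺ density ordering from the Powell fit (human vs mouse) is
  sensitive to the synthetic K⁺ kinetics and is not asserted; the Na⁺
  ordering is.
* Single compartment only: no axon initial segment, no morphology, no
  series-resistance artifacts.
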