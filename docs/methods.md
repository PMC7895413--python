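# Methods

This note documents the model implemented by `nanostim`, the numerical
choices behind the simulator, the open design decisions and how they were
resolved, and the limits of what the desk-scale test suite demonstrates.

## The recurrent network (BCN)

The network stands for the ~200 µm surroundings of a stimulated cell in the
rat barrel cortex, where connection probabilities are approximately
distance-independent: 2000 regular-spiking (RS) excitatory neurons, 400
fast-spiking (FS) and 200 SOM-LTS inhibitory interneurons, randomly
connected with fixed in-degrees.

Each neuron is a leaky integrate-and-fire unit,
τ_m,k dv_k/dt = −v_k + R_m,k I_total,k(t), with R_m,k = τ_m,k/C_m and
C_m = 150 pF for all cells. At threshold v_T,k a spike is emitted and v_k is
clamped at v_R = 10 mV for the refractory time τ_ref,k. RS and SOM neurons
carry a spike-triggered adaptation current a_k that jumps by Δa_k per spike
and decays with τ_a,k; FS neurons do not adapt.

Heterogeneity (per neuron, frozen in a *realization*):

| parameter | RS | FS | SOM | law |
|---|---|---|---|---|
| τ_m [ms] | 20 | 10 | 20 | lognormal, SD 20% of mean |
| v_T [mV] | 20 | 20 | 14 | Gaussian, SD 10% of mean, redrawn until > v_R |
| τ_ref [ms] | 4 + X, X lognormal(mean 2, SD 1) | same | same | |
| τ_a [ms] / Δa [nA] | 100 / 0.3 | — | 50 / 0.2 | lognormal, SD 20% |

Lognormal "mean ± SD" is interpreted as the *arithmetic* moments of the
lognormal (σ² = ln(1+cv²), µ = ln(mean) − σ²/2), since the quoted values
are physiological averages. Thresholds violating v_T > v_R are redrawn, not
truncated, to avoid piling probability mass at the reset value (the redraw
probability is negligible at these parameters).

Connectivity (in-degree per target; peak weights exponential with the given
mean; conduction delays uniform in [0.5, 1.0] ms):

| target ← source | fan-in | J̄ [mV] | plasticity |
|---|---|---|---|
| RS ← RS | 300 | 0.10 | strong depression |
| RS ← FS | 200 | 0.50 | strong |
| RS ← SOM | 100 | 0.25 | weak |
| FS ← RS | 800 | 0.20 | strong |
| FS ← FS | 200 | 1.00 | strong |
| FS ← SOM | 50 | 0.10 | weak |
| SOM ← RS | 1000 | 0.10 | facilitating + failures |
| SOM ← FS | 100 | 0.25 | strong |
| SOM ← SOM | — | — | no chemical synapses |

Sources are drawn uniformly without replacement (self-connections
excluded); SOM→FS sources are likewise drawn without replacement, a choice
the source literature leaves open. The FS→SOM class is never assigned
printed plasticity parameters in the source literature; we assign it the
strong-depression class — the reading under which the simulated spontaneous
rates land on the published 0.8/10/3 Hz values — and expose it as
configuration.

Gap junctions within FS and within SOM are reduced to their suprathreshold
effect: an all-to-all (no self) excitatory spiking coupling with
exponential amplitudes of mean 0.05 mV and delays uniform in [0.1, 0.5] ms;
the subthreshold Ohmic coupling is neglected (it is known to matter far
less than the spikelet component at network level).

External input: every RS/FS neuron receives a constant bias R_m I_0 = 10 mV
plus two Poisson shot-noise streams — "thalamic" lines (fan-in 500 at
10 Hz) and "cortical-surround" lines (2000 at 2 Hz for RS, 1000 at 2 Hz
for FS) — each event depolarizing by an exponentially distributed amplitude
(mean 0.1 mV for RS targets, 0.2 mV for FS; both streams share the target's
amplitude scale). SOM neurons receive no external shot noise.

## Short-term plasticity

All synaptic weights are dynamic. Depressing synapses follow the
Tsodyks–Markram resource variable R(t): between presynaptic spikes
R relaxes to 1 with τ_D; each spike reads the amplitude factor R(t⁻) and
depletes R ← (1−U_se) R. Strong class: τ_D = 150 ms, U_se = 0.2 (the eighth
PSP of a 40 Hz train is ≈ 0.51 of the first); weak class: τ_D = 50 ms,
U_se = 0.05.

The facilitating RS→SOM class replaces U_se with a facilitation variable
u(t) (baseline U_b = 0.01, jump (1−u)U with U = 0.03, recovery
τ_F = 300 ms) and normalizes amplitudes by U_b: the amplitude factor of a
spike is R(t⁻)·u(t⁺)/U_b (≈ 3.97 for a rested synapse; the static weight
J_se is a scale parameter, not the literal first-PSP amplitude). The
update order follows the printed equations: u jumps first, the amplitude
uses the post-jump u, the resource is depleted with the *pre*-jump u
(R ← R − u(t⁻)R(t⁻)). Transmission failures gate these synapses with a
binary variable: a spike is transmitted with probability 1 − p_f(t⁻),
where p_f relaxes to 0.5 with τ = 250 ms and drops by up to 0.1 per spike,
floored at 0.1. Failure draws are independent across postsynaptic targets
(cross-target correlation is unspecified in the source material).

With the mean failure gate included, the eighth RS→SOM PSP of a 40 Hz
train comes out ≈ 5–6× the first under direct iteration of these update
rules. The source text quotes "about eight times"; we implement the printed
equations and report the measured ratio rather than forcing agreement —
an unprinted convention (e.g. which u enters the depletion) could explain
the difference, and either value expresses strong net amplification.

Because (τ_D, U_se) depend only on the connection class, every synapse's
R(t) is an exact time-shifted copy of one master variable per presynaptic
neuron; the simulator stores three masters per neuron (strong, weak,
facilitating incl. u and p_f), advanced event-wise in closed form. A
brute-force per-synapse oracle verifies the identity to 10⁻¹² at event
times.

## Integration scheme

Exponential-Euler per step (exact for the piecewise-constant-plus-delta
input within a step) with dt = 0.05 ms; synaptic events are delivered as
instantaneous voltage jumps of J (mV) through per-delay ring buffers,
delays quantized to the nearest step (minimum one step). Threshold
crossings are detected at step boundaries without interpolation; a test
verifies that halving dt leaves the population rates unchanged within
Monte-Carlo error. Initial conditions per trial: v uniform in [0, v_T),
a = 0, plasticity at rest; each trial simulates 1200 ms of warm-up before
the stimulus onset at t = 0 so the initial state is forgotten. Input
arriving during the refractory clamp is discarded.

External shot noise is generated per neuron by next-event sampling with a
xorshift128+ generator and a ziggurat exponential sampler inside the
numba kernel. The Monte-Carlo oracles use numba's independent
Mersenne-Twister stream, so implementation and oracle share no RNG code.
Per-trial seeds derive from a master seed via `numpy.random.SeedSequence`,
keeping realizations frozen while noise and initial conditions are fresh
every trial.

## Stimulation protocols

The stimulus is an additional current into one randomly selected RS cell,
on at t = 0, expressed as a fraction of ΔI_max = 5 nA. Protocols: steps of
100/200/400 ms at 25%; the charge-matched set (100 ms@100%, 200@50%,
400@25%); and irregular stimuli — a fresh uniformly random permutation, per
trial, of six fixed steps (10, 20, 40, 80, 160, 90 ms at 100, 50, 25, 12.5,
6.25, −50%), 400 ms total, 720 possible signals whose ensemble mean is
time-reversal symmetric. The hyperpolarizing step may drive the voltage
negative; no floor is applied. A slow-nonstationarity proxy replaces the
thalamic rate per trial by a lognormal draw with mean 10 Hz and SD
σ_r,ext.

## Readouts

*Integrator (IR).* Fixed random readout subsets (1000 RS, 100 FS, 100 SOM)
project to one leaky integrator with τ = 20 ms: RS spikes depolarize, FS
and SOM spikes hyperpolarize, each by an exponentially distributed readout
weight (class means J_ee, J_ei, 1.2·J_es) times the source's depression
factor. The trace is reconstructed exactly from recorded spikes in
post-processing. The printed readout equation carries a resistance factor
where the in-network equations carry τ_m; we use the network convention
(jump = J in mV), a pure scale that cancels in all standardized and
calibrated statistics.

*Differentiator (DR).* A_dr(t) = [A_ir(t) − A_ir(t−ΔT)] ⋆ e^{−t/τ_f}/τ_f
with ΔT = 10 ms (the lag is not printed for the DR itself; we default it to
the DNR's delay) and τ_f = 15 ms (the rate-filter constant; both exposed as
configuration). On a ramp c·t the steady response is c·ΔT exactly.

*Differentiator network (DNR).* 10000 RS-type readout neurons (SB) and 2000
FS-type inhibitory neurons (I); each DNR neuron receives feed-forward input
from independently sampled readout-set-sized subsets of the BCN, with the
BCN→I pathway delayed by an extra ΔT = 10 ms; I provides 200 recurrent
inhibitory synapses to every DNR neuron. SB adaptation is weakened
(Δa = 0.1 nA, τ_a = 50 ms) and the cortical background rate halved.
Feed-forward weights use the BCN class means (the 20% SOM boost applies
only to the IR's grandmother readout). A_dnr is the filtered mean SB rate.

The mean I→SB weight follows from linear response: the static change of
the SB input through the direct pathway must cancel the delayed inhibitory
pathway. The inhibitory population's spontaneous rate solves the
self-consistency r_I = φ_sn(a_e, a_i, R_e, C r_I, I_0) where φ_sn is the
exact rate of a LIF neuron under white shot noise with exponential
amplitudes (quadrature of the closed form, validated against Monte-Carlo
to ≲3%; the integrand's printed grouping was disambiguated by that
comparison, not by typography). The DC susceptibility dφ_sn/dµ is a central
finite difference. The pipeline yields J_ei_R ≈ 0.65 mV at the default
operating point (r_e ≈ 0.8 Hz, total excitatory input rate 7800 Hz using
the RS-class external counts with the halved cortical rate); the shipped
default is deliberately 0.6 mV — imperfect cancellation matches behavior
better. The self-consistency condition uses the printed arguments (no
depression factor inside the fixed point; depression enters the
cancellation formula via R̄(r) = 1/(1+τ_D U_se r)).

## Detection

A detection event is a boundary crossing of the readout trace at any 1 ms
grid point in the open window (0, 600 ms): a lower boundary for the IR, an
upper one for DR/DNR (the combination that yields positive effect sizes).
The boundary is the empirical quantile of per-trial extrema on a
calibration half of the catch trials such that FP = 0.25; the effect size
Ȳ = CD − FP is evaluated against the held-out half (the split is our
choice; it removes the optimistic bias of calibrating and evaluating on
the same trials). Bootstrap CIs (1000 trial resamples) accompany every
estimate. Standardized statistics μ̂(t), σ̂(t) are deviations of the trial
mean and trial SD from the catch baseline in units of the catch SD; the
printed definitions omit a square root under the stationary variance, which
we read as the standard deviation the surrounding text names — the single
intentional deviation from the printed formulae.

The simplified detection model treats the window as n = T_w/τ_corr
independent draws with non-crossing probability p₀ (FP = 1 − p₀ⁿ);
localized features perturb single draws, and effect sizes combine as
Ȳ₁₂ = p₀ⁿ(1 − p₁p₂/p₀²) ≈ Ȳ₁ + Ȳ₂ for small perturbations. τ_corr is
never assigned a number in the source material, so the model is exposed as
a standalone calculator, validated against a Bernoulli Monte-Carlo twin.

## Desk-scale presets and what the tests show

The published study used 10 000 trials per stimulus type (weeks on a
cluster) and a full-size DNR. The `desk_small` preset keeps the **full**
BCN — its size sets the connection probabilities and rates, i.e. the
physics — and reduces only estimator precision: a few hundred trials and a
scaled DNR (SB 1000; I 250, slightly above 1/10 so the published recurrent
fan-in of 200 remains feasible without replacement; Eq-7-style averaging
over fewer SB neurons mainly widens the trace noise). The test suite runs
60–100 trials per condition and averages single-cell statistics over
several realizations (the stimulated cell's own sampled τ_ref, τ_m, Δa
dominate the spread); with these sizes the suite resolves the spontaneous
rates, evoked counts and the SOM plateau quantitatively, but the effect
sizes only at CI-level, so the readout-ordering results (integrator grows
with duration, differentiators stay flat, DNR prefers irregular stimuli)
are asserted as CI-based orderings, not point values. The acceptance
script uses 5 realizations × 10 trials for step protocols, 200 irregular
trials and 100 stimulus + 100 catch trials for the plateau.

Synthetic-ensemble tests (Gaussian/AR traces for calibration, Bernoulli
draws for the simplified model) validate the detection machinery at
precisions the network batches cannot reach (e.g. FP = 0.25 ± 0.01); they
do not, of course, certify network behavior.

## Known limitations

* No layered or distance-dependent connectivity; the model is the local,
  statistically homogeneous surroundings of the stimulated cell.
* Subthreshold gap-junction coupling is omitted by design (set to zero).
* Readout weights are not learned; Tempotron-style decoders are out of
  scope.
* Threshold crossings are step-quantized; sub-grid interpolation is not
  attempted (absorbed by calibration, verified by the dt-halving test).
* The 800 ms stimuli of the original behavioral dataset are not part of
  any protocol here.
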