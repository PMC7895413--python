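# nanostim

A spiking-network model of how the stimulation of a **single cortical
neuron** can be detected downstream — and why detection barely depends on
the duration or intensity of a constant stimulus, yet improves markedly for
an irregular one.

Juxtacellular ("nano") stimulation experiments in the rat barrel cortex show
that driving one regular-spiking cell can elicit a behavioral response with
these counter-intuitive dependencies. `nanostim` implements a biologically
constrained model of this situation for computational neuroscientists who
want to simulate, extend, or re-analyze it:

* **Barrel-cortex network (BCN).** N = 2600 leaky integrate-and-fire
  neurons — 2000 regular-spiking (RS) excitatory cells, 400 fast-spiking
  (FS) and 200 somatostatin-positive low-threshold-spiking (SOM-LTS)
  interneurons — with heterogeneous cellular parameters, spike-frequency
  adaptation (RS, SOM), dense experimentally constrained connectivity,
  conduction delays, effective gap-junction coupling within FS and within
  SOM, and Poissonian shot-noise background input. Membrane dynamics
  τ_m dv/dt = −v + R_m I(t), with reset/clamp at v_R = 10 mV and threshold
  v_T ≈ 20 mV (14 mV for SOM).
* **Short-term synaptic plasticity.** Tsodyks–Markram depression on all
  chemical synapses except RS→SOM, which facilitate strongly and carry an
  activity-dependent transmission-failure rate (≈50% at rest, improving
  with use). Per-synapse dynamics reduce exactly to one *master variable*
  per presynaptic neuron, which the simulator exploits.
* **Three readouts.** An integrator (IR: the filtered, signed, summed
  activity of fixed readout subsets — one "grandmother" membrane potential),
  a differentiator (DR: A_ir(t) − A_ir(t−ΔT), smoothed), and a
  differentiator **network** (DNR): an explicit 10000+2000-neuron circuit in
  which delayed feed-forward inhibition implements the subtraction. The
  inhibitory weight that cancels static inputs follows from a
  linear-response calculation built on the exact firing rate of a
  shot-noise-driven LIF neuron.
* **Detection statistics.** Thresholds calibrated to a 25% false-positive
  rate on catch trials; the effect size Ȳ = hit rate − false-positive rate;
  standardized trace statistics μ̂(t), σ̂(t); and the simplified
  independent-draw detection model that explains how multiple trace
  features add or cancel.

## Worked example

```python
import nanostim as ns

net = ns.build_network(seed=1)                      # one frozen realization
recs = [ns.simulate_trial(net, trial_seed=s, t_end=3000.0) for s in (11, 12)]
print({k: round(v, 2)
       for k, v in ns.population_mean_rates(recs, window=(0.0, 3000.0)).items()})
```

prints (RS / FS / SOM population codes 0 / 1 / 2):

```
{0: 0.83, 1: 10.3, 2: 3.06}
```

i.e. the asynchronous-irregular spontaneous state with RS ≈ 0.8 Hz,
FS ≈ 10 Hz, SOM ≈ 3 Hz. Injecting a 400 ms, 1.25 nA step into one RS cell
(`examples/04_single_cell_stimulation.py`) evokes ≈ 20 spikes in the
targeted cell and raises the SOM population rate to a plateau ≈ 15–25%
above baseline — the disynaptic signature through the facilitating RS→SOM
synapses that ultimately suppresses the surrounding RS cells.

The `examples/` directory walks through each capability:

| script | shows |
|---|---|
| `01_spontaneous_activity.py` | spontaneous rates of the three populations |
| `02_short_term_plasticity.py` | depression/facilitation/failure dynamics along a 40 Hz train |
| `03_tune_differentiator_network.py` | the analytic inhibitory-weight tuning (→ ≈ 0.65 mV) |
| `04_single_cell_stimulation.py` | evoked spikes and the SOM/RS rate response |
| `05_detection_and_effect_size.py` | threshold calibration and effect sizes for IR/DR |

A thin CLI wraps the same functions for shell use, e.g.
`nanostim simulate --stimulus 400:0.25 --n-trials 20` or
`nanostim experiment duration --preset desk_small`; see `nanostim --help`.

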