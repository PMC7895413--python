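"""Stimulating one neuron: evoked spikes and the network's rate response.

Injects a 400 ms, 1.25 nA step (25% of the 5 nA maximum) into one randomly
chosen RS cell and shows (i) how many spikes the current evokes in the
targeted cell and (ii) the disynaptic signature in the population rates:
the facilitating synapses onto SOM-LTS interneurons raise the SOM rate to a
plateau ~20% above baseline, which in turn suppresses the RS population.
A handful of trials is enough for the evoked count; the population-rate
curves sharpen with more trials.
"""

import numpy as np

import nanostim as ns

net = ns.build_network(seed=1)
stim = ns.step_stimulus(400.0, 0.25)
print(f"stimulating RS cell #{net.stim_target} with "
      f"{stim.segments[0][1] * stim.I_max:.2f} nA for 400 ms")

n_trials = 30
recs = ns.simulate_batch(net, stim, n_trials, master_seed=7, t_end=430.0)
catch = ns.simulate_batch(net, ns.CATCH, n_trials, master_seed=8, t_end=430.0)

st = ns.evoked_spike_stats(recs)
print(f"\nevoked spikes in the stimulated cell: "
      f"{st.mean_count:.1f} +- {st.sd_count:.1f} "
      f"({st.mean_rate:.0f} Hz over the step)")

t, som_stim = ns.population_rate(recs, ns.SOM, filter_tau=15.0)
_, som_catch = ns.population_rate(catch, ns.SOM, filter_tau=15.0)
m = (t >= 250) & (t < 400)
print(f"SOM rate, late-stimulus plateau : {som_stim[m].mean():.2f} Hz")
print(f"SOM rate, catch trials          : {som_catch[m].mean():.2f} Hz")
print(f"plateau elevation               : "
      f"{100 * (som_stim[m].mean() / som_catch[m].mean() - 1):.0f} % "
      "above spontaneous")

_, rs_stim = ns.population_rate(recs, ns.RS, filter_tau=15.0,
                                exclude=(net.stim_target,))
_, rs_catch = ns.population_rate(catch, ns.RS, filter_tau=15.0)
print(f"RS rate (stimulated cell excluded) in the same window: "
      f"{rs_stim[m].mean():.2f} Hz vs {rs_catch[m].mean():.2f} Hz on catch "
      "(disynaptic inhibition)")
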