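"""One glutamate-release event: the EAAT impulse and the Na+ transient.

Drives the astrocyte with a single spike event (no neuron needed), then
integrates the recorded transporter currents to verify the per-spike load
and shows the resulting cradle Na+ transient.
"""

import pscradle as pc

geometry = pc.derive_geometry()
params, report = pc.calibrate_rest(pc.ModelParameters(), geometry)

cfg = pc.SimConfig(t_settle=0.5, t_stim=0.1, t_post=4.0,
                   stimulus=pc.StimulusSpec(mode="spike_train", rate=1.0,
                                            events=(0.0,)),
                   record_stride=10)
r = pc.run_simulation(params, geometry, cfg, calibration=report)

d = r.data
dt = float(d["time_s"].diff().median())
f = params.constants.F
na_up = -(d["i_na_eaat_A"] * dt).sum() / (f * geometry.vol_psecs)
k_rel = (d["i_k_eaat_A"] * dt).sum() / (f * geometry.vol_psecs)
print("per-spike EAAT Na+ uptake from the PsECS : %.3f mM" % (1e3 * na_up))
print("per-spike EAAT K+ release into the PsECS : %.3f mM" % (1e3 * k_rel))

na = d["na_psc_M"]
t = d["time_s"]
peak = na.idxmax()
print("cradle Na+ baseline %.3f mM -> peak %.3f mM at t = %.2f s (event at 0.5 s)"
      % (1e3 * params.na_psc_0, 1e3 * na[peak], t[peak]))
print("\nOne spike binds 1 mM glutamate; the transporter then moves 3 Na+ per")
print("glutamate (3 mM from the tiny PsECS) into the cradle and counter-")
print("transports 1 K+ (1 mM), decaying with tau = %.0f ms." % (1e3 * params.tau_eaat))
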