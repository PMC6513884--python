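"""Microdomain plateaus versus firing rate (10/20/30 Hz).

Runs the scaled protocol at three firing rates and prints the plateau
elevations of the three cradle microdomains.
"""

import pscradle as pc

geometry = pc.derive_geometry()
params, report = pc.calibrate_rest(pc.ModelParameters(), geometry)

print("rate    K+ plateau    Na+ plateau    Ca2+ plateau")
for rate in (10.0, 20.0, 30.0):
    amp = pc.calibrate_stimulus(rate, params, geometry)
    cfg = pc.SimConfig(t_settle=2.0, t_stim=10.0, t_post=2.0,
                       stimulus=pc.StimulusSpec(mode="pulse", rate=rate,
                                                amplitude=amp))
    r = pc.run_simulation(params, geometry, cfg, calibration=report)
    s = pc.plateau_summary(r, window=3.0)
    print("%2.0f Hz   %+7.2f mM    %+7.2f mM     %+7.0f nM" % (
        rate,
        1e3 * (s["k_psc_M"] - params.k_psc_0),
        1e3 * (s["na_psc_M"] - params.na_psc_0),
        1e9 * (s["ca_psc_M"] - report.ca_psc_rest)))

print("\nAll three plateaus grow with the firing rate: faster spiking stacks")
print("more EAAT impulses and neuronal K+ load, and the well-hopping process")
print("transport is too weak to drain the cradle, so microdomains deepen.")
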