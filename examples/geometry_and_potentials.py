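"""Derive the compartment geometry and the desk-scale potentials.

Recomputes the cradle/process/synapse areas and volumes from the primitive
lengths, then the Nernst potentials of the baseline gradients and the NCX
equilibrium potential that sets the exchanger's operating point.
"""

import pscradle as pc

g = pc.derive_geometry()
print("cradle membrane area        SA_PsC    = %.4e m^2" % g.sa_ps)
print("cradle volume               Vol_PsC   = %.4e L" % g.vol_ps)
print("perisynaptic ECS volume     Vol_PsECS = %.4e L" % g.vol_psecs)
print("process cross-section       CSA_P     = %.4e m^2" % g.csa_p)
print("process lateral area        SA_P      = %.4e m^2" % g.sa_p)

e_k = pc.nernst_potential(0.004, 0.1)
e_na = pc.nernst_potential(0.135, 0.015)
e_ca = pc.nernst_potential(1.5e-3, 80e-9, valence=2)
e_ncx = pc.ncx_equilibrium_potential(e_na, e_ca, n=3)
print("\nE_K  = %+.1f mV   E_Na = %+.1f mV   E_Ca = %+.1f mV"
      % (1e3 * e_k, 1e3 * e_na, 1e3 * e_ca))
print("E_NCX = 3 E_Na - 2 E_Ca = %+.1f mV" % (1e3 * e_ncx))
print("\nE_NCX sits in the astrocyte resting-potential range (-85..-90 mV):")
print("small shifts in cradle Na+ or membrane potential move the exchanger")
print("between forward (Ca2+ out) and reverse (Ca2+ in) operation.")
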