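"""Restricted cation transport along the thin astrocyte process.

Negatively charged membrane lipids line the thin (~100 nm) process with deep
potential wells; cations travelling between the cradle and the soma must hop
from well to well.  The resulting current follows Poole-Frenkel statistics:
an ohmic prefactor in the driving field times a Boltzmann factor whose
barrier is lowered by the square root of the field,

    I = K (dV/l) exp[-Q (phi_w - sqrt(Q |dV| / (l pi eps))) / (k_B T)] CSA_P

with dV = V_A - V_m - Vr.  The cradle is isopotential with the soma
(V_A = V_m), so in practice dV = -Vr, where Vr is the Nernst-like potential
of the soma/cradle concentration gradient.  The field term uses |dV| under
the square root; the sign of the current follows the sign of dV (positive =
out of the cradle toward the soma).

At the reference barrier height (0.267 eV at 310 K) the zero-field Boltzmann
factor is e^-10, which is what semi-isolates the cradle and lets
microdomains form: hopping currents run orders of magnitude below the
transmembrane currents at comparable driving force.
"""

import math
from dataclasses import dataclass, field

from numba import njit

from .constants import PhysicalConstants, CONSTANTS
from .errors import DomainError
from .geometry import Geometry
from .params import ModelParameters


@dataclass(frozen=True)
class ProcessParams:
    """Parameters of the well-hopping pathway (view over ModelParameters)."""

    phi_w: float = 0.267        # well activation energy, eV
    l: float = 25e-6            # process length, m
    k_k: float = 0.018          # per-ion channel constants, S/m
    k_na: float = 0.018
    k_ca: float = 0.0018
    k_soma: float = 0.1         # clamped soma concentrations, M
    na_soma: float = 0.015
    ca_soma: float = 100e-9
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    @classmethod
    def from_model(cls, params: ModelParameters, geometry: Geometry) -> "ProcessParams":
        return cls(phi_w=params.phi_w, l=geometry.l_p,
                   k_k=params.k_pf_k, k_na=params.k_pf_na, k_ca=params.k_pf_ca,
                   k_soma=params.k_soma, na_soma=params.na_soma,
                   ca_soma=params.ca_soma, constants=params.constants)


@njit(cache=True)
def _pf_density_factor(dv, l, phi_w_ev, q_hop, eps, k_b_t):
    """exp[-Q (phi_w - barrier lowering)/kT]; even in dv."""
    lowering = math.sqrt(q_hop * abs(dv) / (l * math.pi * eps))
    return math.exp(-q_hop * (phi_w_ev - lowering) / k_b_t)


@njit(cache=True)
def _pf_current(dv, k_ion, l, phi_w_ev, q_hop, eps, k_b_t, csa):
    """Poole-Frenkel hopping current (A); odd prefactor, even Boltzmann factor."""
    if dv == 0.0:
        return 0.0
    return k_ion * (dv / l) * _pf_density_factor(dv, l, phi_w_ev, q_hop, eps, k_b_t) * csa


def process_reversal_potential(ion: str, conc_soma: float, conc_psc: float,
                               T: float | None = None,
                               constants: PhysicalConstants = CONSTANTS) -> float:
    """Nernst-like soma/cradle reversal potential Vr = (RT/F) ln([i]AS/[i]PsC).

    Valence-free for every ion (including Ca2+), matching the published
    formulation.  Zero when soma and cradle concentrations are equal, which
    holds for all three ions at t = 0.
    """
    if conc_soma <= 0.0 or conc_psc <= 0.0:
        raise DomainError(
            f"non-positive concentration for {ion} reversal potential: "
            f"soma={conc_soma!r}, psc={conc_psc!r}"
        )
    temp = constants.T if T is None else T
    return constants.R * temp / constants.F * math.log(conc_soma / conc_psc)


def poole_frenkel_current(ion: str, vr: float, params: ModelParameters,
                          geometry: Geometry, v_a: float | None = None,
                          v_m: float | None = None) -> float:
    """Hopping current (A) along the process for 'k', 'na' or 'ca'.

    ``vr`` is the soma/cradle reversal potential; the driving term is
    dV = V_A - V_m - Vr, which reduces to -Vr under isopotentiality (the
    default: ``v_a`` and ``v_m`` both equal the astrocyte potential).
    """
    k_ion = {"k": params.k_pf_k, "na": params.k_pf_na, "ca": params.k_pf_ca}.get(ion)
    if k_ion is None:
        raise ValueError(f"unknown ion {ion!r}; expected 'k', 'na' or 'ca'")
    c = params.constants
    q_hop = c.Q
    if params.variants.pf_charge_valence and ion == "ca":
        q_hop = params.z_ca * c.Q
    va = params.v_a if v_a is None else v_a
    vm = params.v_a if v_m is None else v_m
    dv = va - vm - vr
    return _pf_current(dv, k_ion, geometry.l_p, params.phi_w, q_hop,
                       c.eps, c.kBT, geometry.csa_p)
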