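"""Transmembrane pathways on the perisynaptic cradle.

All pathways face the perisynaptic extracellular space (PsECS): the EAAT1/2
glutamate-transporter flux, the Na+/Ca2+ exchanger (NCX), the Na+/K+ pump
(NKA), the inwardly rectifying K+ channel (Kir), lumped background channels
for K+ and Na+, and the diffusive PsECS-to-global-ECS leak.

Sign convention: positive current = ion leaving the cradle for the PsECS
(for the leak: leaving the PsECS for the global ECS).

Scalar cores are numba-jitted and shared with the simulation kernel; the
public functions wrap them with state/parameter containers and input checks.
"""

import math
from dataclasses import dataclass

from numba import njit

from .errors import DomainError
from .geometry import Geometry
from .params import ModelParameters


@dataclass
class AstrocyteState:
    """Dynamic astrocyte state: five concentrations plus the EAAT flux.

    ``v_a`` is carried for convenience but held constant during a run
    (isopotentiality of the cradle with the astrocyte syncytium).
    """

    k_psc: float = 0.1
    na_psc: float = 0.015
    ca_psc: float = 100e-9
    k_psecs: float = 0.004
    na_psecs: float = 0.135
    j_eaat: float = 0.0          # EAAT Na+ flux state, M/s
    v_a: float = -0.0807


@dataclass(frozen=True)
class AstrocyteCurrents:
    """Named per-pathway currents (A), astrocyte side."""

    i_kir: float
    i_k_nka: float
    i_k_eaat: float
    i_k_bg: float
    i_na_bg: float
    i_na_nka: float
    i_na_eaat: float
    i_na_ncx: float
    i_ca_ncx: float
    i_k_ecsl: float
    i_na_ecsl: float
    i_k_pf: float = 0.0
    i_na_pf: float = 0.0
    i_ca_pf: float = 0.0


# ---------------------------------------------------------------------------
# numba scalar cores
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ncx_density(na_i, na_o, ca_i, ca_o, v, rtf, i_bar, gamma):
    """NCX Na+ current density (A/m^2); positive = Na+ efflux (reverse mode)."""
    return i_bar * ((na_i / na_o) ** 3 * math.exp(gamma * v / rtf)
                    - (ca_i / ca_o) * math.exp((gamma - 1.0) * v / rtf))


@njit(cache=True)
def _nka_rate(p_max, na_i, k_o, k_nai, k_ke):
    """Saturating NKA pump rate, mol/(m^2 s)."""
    occ_na = na_i / (na_i + k_nai)
    occ_k = k_o / (k_o + k_ke)
    return p_max * occ_na ** 3 * occ_k ** 2


@njit(cache=True)
def _kir_density(v_a, k_i, k_o, g_kir, rtf, sqrt_k_out, k_o_rest):
    """Kir current density; linear in driving force, optional sqrt([K]o) scaling."""
    e_k = rtf * math.log(k_o / k_i)
    g = g_kir
    if sqrt_k_out:
        g = g_kir * math.sqrt(k_o / k_o_rest)
    return g * (v_a - e_k)


@njit(cache=True)
def _background_density(v_m, c_i, c_o, g, rtf):
    """Passive electrochemical-gradient channel density g (V - E_i)."""
    e_i = rtf * math.log(c_o / c_i)
    return g * (v_m - e_i)


@njit(cache=True)
def _ecs_leak_density(c_psecs, c_gecs, g, rtf):
    """Diffusive PsECS->GECS leak density g * E; zero extracellular potential."""
    return g * rtf * math.log(c_psecs / c_gecs)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def eaat_update(j: float, dt: float, spike_now: bool,
                params: ModelParameters) -> float:
    """Advance the EAAT flux state one step.

    Between release events the flux decays exponentially, dJ/dt = -J/tau;
    a glutamate-release event (one presynaptic spike, 1 mM glutamate bound
    instantaneously) adds the full impulse J0 on top of whatever flux is
    still decaying, so closely spaced spikes stack.
    """
    if dt < 0.0:
        raise DomainError(f"dt must be >= 0, got {dt}")
    if j < 0.0:
        raise DomainError(f"EAAT flux must be >= 0, got {j}")
    j = j + dt * (-j / params.tau_eaat)
    if spike_now:
        j += params.j0_eaat
    return j


def eaat_currents(j: float, geometry: Geometry,
                  params: ModelParameters) -> tuple[float, float]:
    """EAAT Na+ and K+ currents (A) for flux state ``j``.

    ``j`` is the rate at which the transporter depletes PsECS Na+ (M/s), so
    the total Na+ current is ``-j * z_Na * F * Vol_PsECS`` (negative: influx
    into the cradle).  One K+ is counter-transported per 3 Na+:
    ``I_K = -I_Na / 3``.
    """
    if j < 0.0:
        raise DomainError(f"EAAT flux must be >= 0, got {j}")
    f = params.constants.F
    i_na = -j * params.z_na * f * geometry.vol_psecs
    return i_na, -i_na / 3.0


def ncx_currents(state: AstrocyteState, geometry: Geometry,
                 params: ModelParameters) -> tuple[float, float]:
    """NCX Na+ and Ca2+ currents (A).

    Positive I_NaNCX means the exchanger runs in reverse mode (3 Na+ leave
    the cradle, 1 Ca2+ enters); the Ca2+ component carries the opposite
    charge flow scaled by the 3:1 stoichiometry and the Ca2+ valence:
    I_CaNCX = -(2/3) I_NaNCX.
    """
    for name, val in (("na_psecs", state.na_psecs), ("ca_psecs", params.ca_psecs),
                      ("na_psc", state.na_psc), ("ca_psc", state.ca_psc)):
        if val <= 0.0 or not math.isfinite(val):
            raise DomainError(f"non-positive or non-finite concentration {name}={val!r}")
    d = _ncx_density(state.na_psc, state.na_psecs, state.ca_psc, params.ca_psecs,
                     state.v_a, params.constants.RTF, params.i_bar_ncx,
                     params.gamma_ncx)
    i_na = d * geometry.sa_ps
    return i_na, -2.0 * i_na / 3.0


def astro_nka_currents(state: AstrocyteState, geometry: Geometry,
                       params: ModelParameters) -> tuple[float, float]:
    """Astrocyte NKA Na+ and K+ currents (A); 3 Na+ out : 2 K+ in, exactly."""
    if state.na_psc <= 0.0 or state.k_psecs < 0.0:
        raise DomainError("invalid concentrations for NKA")
    f = params.constants.F
    p = _nka_rate(params.p_nka_max, state.na_psc, state.k_psecs,
                  params.k_nai, params.k_ke)
    i_na = 3.0 * f * p * geometry.sa_ps
    i_k = -2.0 * f * p * geometry.sa_ps
    return i_na, i_k


def kir_current(state: AstrocyteState, geometry: Geometry,
                params: ModelParameters) -> float:
    """Kir K+ current (A): g_Kir (V_A - E_K) SA, E_K across the cradle membrane.

    Positive (efflux) when the membrane sits above E_K; rising PsECS K+
    raises E_K above V_A and flips the channel to uptake.
    """
    if state.k_psc <= 0.0 or state.k_psecs <= 0.0:
        raise DomainError("non-positive K+ concentration for Kir")
    d = _kir_density(state.v_a, state.k_psc, state.k_psecs, params.g_kir,
                     params.constants.RTF, params.variants.kir_sqrt_k_out,
                     params.k_psecs_0)
    return d * geometry.sa_ps


def astro_background_current(ion: str, state: AstrocyteState,
                             geometry: Geometry,
                             params: ModelParameters) -> float:
    """Lumped background channel current (A) for 'k' or 'na'."""
    if ion == "k":
        c_i, c_o, g = state.k_psc, state.k_psecs, params.g_k_bg
    elif ion == "na":
        c_i, c_o, g = state.na_psc, state.na_psecs, params.g_na_bg
    else:
        raise ValueError(f"unknown ion {ion!r}; expected 'k' or 'na'")
    if c_i <= 0.0 or c_o <= 0.0:
        raise DomainError(f"non-positive {ion} concentration for background channel")
    d = _background_density(state.v_a, c_i, c_o, g, params.constants.RTF)
    return d * geometry.sa_ps


def ecs_leak_current(ion: str, state: AstrocyteState, geometry: Geometry,
                     params: ModelParameters) -> float:
    """PsECS -> global-ECS diffusive leak current (A) for 'k' or 'na'.

    Positive when the PsECS concentration exceeds the (clamped) global value.
    """
    if ion == "k":
        c_e, c_g = state.k_psecs, params.k_gecs
    elif ion == "na":
        c_e, c_g = state.na_psecs, params.na_gecs
    else:
        raise ValueError(f"unknown ion {ion!r}; expected 'k' or 'na'")
    if c_e <= 0.0 or c_g <= 0.0:
        raise DomainError(f"non-positive {ion} concentration for ECS leak")
    d = _ecs_leak_density(c_e, c_g, params.g_ecs_leak, params.constants.RTF)
    return d * geometry.sa_psecs_gecs
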