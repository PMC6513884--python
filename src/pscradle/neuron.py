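"""Hodgkin-Huxley presynaptic neuron.

The neuron converts an injected stimulus current into action potentials and
exchanges K+ and Na+ with the perisynaptic extracellular space through the
voltage-gated channels, passive background channels and the Na+/K+ pump.
Internal Na+ and K+ are clamped, so the terminal is a boundary condition for
the extracellular ODEs rather than a conserved compartment.

Voltages live in the classic rest-at-zero HH frame (depolarisation
positive); the gating rate functions are the original squid-axon forms with
removable singularities handled analytically.  Membrane reversal potentials
are taken from the reference table as printed.

Sign convention: positive current = ion leaving the terminal for the PsECS.
The voltage update is C_m dV/dt = -(sum of outward currents)/SA + stimulus
density, so an inward (negative) cation current depolarises.
"""

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import DomainError, IntegrationError
from .geometry import Geometry
from .params import ModelParameters


@dataclass
class NeuronState:
    """Membrane voltage (V, rest-at-zero frame) and HH gating variables."""

    v: float = 0.0
    m: float = 0.05
    h: float = 0.6
    n: float = 0.32


@dataclass(frozen=True)
class NeuronCurrents:
    """Named neuron membrane currents (A); NKA components obey 3:-2 exactly."""

    i_na_hh: float
    i_k_hh: float
    i_leak: float
    i_k_bg: float
    i_na_bg: float
    i_na_nka: float
    i_k_nka: float


@njit(cache=True)
def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the analytic limit y at x -> 0."""
    r = x / y
    if abs(r) < 1e-7:
        return y * (1.0 - r / 2.0)
    return x / (math.exp(r) - 1.0)


@njit(cache=True)
def _hh_rates(v_volts):
    """Classic HH gating rates (1/s) at voltage v (V, rest-at-zero frame)."""
    v = v_volts * 1e3  # formulas are in mV and 1/ms
    alpha_m = 0.1 * _vtrap(25.0 - v, 10.0)
    beta_m = 4.0 * math.exp(-v / 18.0)
    alpha_h = 0.07 * math.exp(-v / 20.0)
    beta_h = 1.0 / (math.exp((30.0 - v) / 10.0) + 1.0)
    alpha_n = 0.01 * _vtrap(10.0 - v, 10.0)
    beta_n = 0.125 * math.exp(-v / 80.0)
    return (alpha_m * 1e3, beta_m * 1e3, alpha_h * 1e3,
            beta_h * 1e3, alpha_n * 1e3, beta_n * 1e3)


@njit(cache=True)
def _nka_rate_neu(p_max, na_syn, k_psecs, k_nai, k_ke):
    occ_na = na_syn / (na_syn + k_nai)
    occ_k = k_psecs / (k_psecs + k_ke)
    return p_max * occ_na ** 3 * occ_k ** 2


def hh_rates(v: float) -> tuple[float, float, float, float, float, float]:
    """Gating rate constants (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n).

    Input voltage in volts (rest-at-zero frame); rates in 1/s.  The
    removable singularities of alpha_m (25 mV) and alpha_n (10 mV) evaluate
    to their analytic limits.
    """
    if not math.isfinite(v):
        raise DomainError(f"voltage must be finite, got {v!r}")
    return _hh_rates(v)


def gate_steady_state(v: float) -> tuple[float, float, float]:
    """Steady-state gating values (m_inf, h_inf, n_inf) at voltage v."""
    am, bm, ah, bh, an, bn = hh_rates(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def neuron_sodium_current(state: NeuronState, params: ModelParameters,
                          geometry: Geometry) -> float:
    """Voltage-gated Na+ current (A), positive = out of the neuron.

    I = g_Na m^3 h (V - E_Na) SA_Syn; during the upstroke V < E_Na so the
    current is negative (influx).  The inactivation gate h is included as in
    the standard HH model (drop it via ModelVariants.na_channel_h_gate for
    the strictly-as-printed m^3 form).
    """
    gate = state.m ** 3 * (state.h if params.variants.na_channel_h_gate else 1.0)
    return params.g_na_neu * gate * (state.v - params.e_na_neu) * geometry.sa_syn


def neuron_potassium_current(state: NeuronState, params: ModelParameters,
                             geometry: Geometry) -> float:
    """Voltage-gated (delayed rectifier) K+ current (A), positive = efflux."""
    return params.g_k_neu * state.n ** 4 * (state.v - params.e_k_neu) * geometry.sa_syn


def neuron_leak_current(state: NeuronState, params: ModelParameters,
                        geometry: Geometry) -> float:
    """Unspecific leak current (A); carries charge but no tracked ion."""
    return params.g_leak_neu * (state.v - params.e_leak_neu) * geometry.sa_syn


def neuron_background_current(ion: str, state: NeuronState,
                              k_psecs: float, na_psecs: float,
                              params: ModelParameters,
                              geometry: Geometry) -> float:
    """Passive background channel current (A): g (V - E_i) SA_Syn.

    E_i = (RT/F) ln([i]PsECS / [i]Syn) with the clamped internal
    concentration; at baseline the K+ channel effluxes and the Na+ channel
    influxes, as required for the terminal's dynamic equilibrium.
    """
    rtf = params.constants.RTF
    if ion == "k":
        if k_psecs <= 0.0:
            raise DomainError("non-positive PsECS K+ concentration")
        e = rtf * math.log(k_psecs / params.k_syn)
        g = params.g_k_bg_neu
    elif ion == "na":
        if na_psecs <= 0.0:
            raise DomainError("non-positive PsECS Na+ concentration")
        e = rtf * math.log(na_psecs / params.na_syn)
        g = params.g_na_bg_neu
    else:
        raise ValueError(f"unknown ion {ion!r}; expected 'k' or 'na'")
    return g * (state.v - e) * geometry.sa_syn


def neuron_nka_flux(k_psecs: float, params: ModelParameters,
                    geometry: Geometry) -> tuple[float, float, float]:
    """Neuron NKA pump rate and (Na+, K+) currents.

    Returns ``(P, I_Na, I_K)`` with P in mol/(m^2 s),
    I_Na = 3 F P SA (efflux into the PsECS) and I_K = -2 F P SA (uptake),
    i.e. I_Na : I_K = -3 : 2 at every state.  P saturates in the clamped
    internal Na+ and the PsECS K+; zero external K+ stalls the pump.
    """
    if k_psecs < 0.0:
        raise DomainError("negative PsECS K+ concentration")
    p = _nka_rate_neu(params.p_nka_max_neu, params.na_syn, k_psecs,
                      params.k_nai_neu, params.k_ke_neu)
    f = params.constants.F
    return p, 3.0 * f * p * geometry.sa_syn, -2.0 * f * p * geometry.sa_syn


def neuron_currents(state: NeuronState, k_psecs: float, na_psecs: float,
                    params: ModelParameters, geometry: Geometry) -> NeuronCurrents:
    """All neuron membrane currents at the given state."""
    _, i_na_nka, i_k_nka = neuron_nka_flux(k_psecs, params, geometry)
    return NeuronCurrents(
        i_na_hh=neuron_sodium_current(state, params, geometry),
        i_k_hh=neuron_potassium_current(state, params, geometry),
        i_leak=neuron_leak_current(state, params, geometry),
        i_k_bg=neuron_background_current("k", state, k_psecs, na_psecs, params, geometry),
        i_na_bg=neuron_background_current("na", state, k_psecs, na_psecs, params, geometry),
        i_na_nka=i_na_nka,
        i_k_nka=i_k_nka,
    )


def neuron_step(state: NeuronState, stimulus_density: float, dt: float,
                params: ModelParameters, geometry: Geometry,
                k_psecs: float | None = None,
                na_psecs: float | None = None,
                t: float = 0.0) -> NeuronState:
    """Advance the neuron one forward-Euler step.

    ``stimulus_density`` is the injected current density (A/m^2, positive
    depolarising).  PsECS concentrations default to baseline (stand-alone
    neuron).  Gating variables are clamped to [0, 1] after the update.

    Raises
    ------
    IntegrationError
        Naming the first non-finite state variable.
    """
    if dt < 0.0:
        raise DomainError(f"dt must be >= 0, got {dt}")
    if dt == 0.0:
        return NeuronState(state.v, state.m, state.h, state.n)
    ke = params.k_psecs_0 if k_psecs is None else k_psecs
    nae = params.na_psecs_0 if na_psecs is None else na_psecs
    cur = neuron_currents(state, ke, nae, params, geometry)
    i_out = (cur.i_k_hh + cur.i_na_hh + cur.i_leak + cur.i_k_bg
             + cur.i_na_bg + cur.i_na_nka + cur.i_k_nka)
    dv = (-i_out / geometry.sa_syn + stimulus_density) / params.c_m
    am, bm, ah, bh, an, bn = _hh_rates(state.v)
    v = state.v + dt * dv
    m = min(1.0, max(0.0, state.m + dt * (am * (1.0 - state.m) - bm * state.m)))
    h = min(1.0, max(0.0, state.h + dt * (ah * (1.0 - state.h) - bh * state.h)))
    n = min(1.0, max(0.0, state.n + dt * (an * (1.0 - state.n) - bn * state.n)))
    for name, val in (("v", v), ("m", m), ("h", h), ("n", n)):
        if not math.isfinite(val):
            raise IntegrationError(name, t)
    return NeuronState(v, m, h, n)


def detect_spikes(v_trace, dt: float, threshold: float,
                  refractory: float = 0.002) -> np.ndarray:
    """Times (s) of upward threshold crossings in a uniformly sampled trace.

    Crossings closer than ``refractory`` to the previous accepted event are
    discarded (a single action potential can graze the threshold more than
    once at coarse sampling).  An empty trace yields an empty array.
    """
    v = np.asarray(v_trace, dtype=float)
    if v.size < 2:
        return np.empty(0)
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    last = -math.inf
    for idx in crossings:
        t = idx * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)
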