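"""Compiled forward-Euler inner loop.

Parameters are packed into a flat float64 vector (indices below) so the
whole coupled neuron-astrocyte step can be jitted.  The right-hand side is
assembled once in :func:`_eval` and shared by the integrator and by the
Python-level single-step/diagnostic wrappers in :mod:`pscradle.engine`, so
there is a single source of truth for the model equations.

Column layout of the recorded array (after the time column):
10 state variables, then 21 named currents (see ``STATE_COLUMNS`` and
``CURRENT_COLUMNS`` in :mod:`pscradle.engine`).
"""

import math

import numpy as np
from numba import njit

from .membrane import (_background_density, _ecs_leak_density, _kir_density,
                       _ncx_density, _nka_rate)
from .neuron import _hh_rates
from .process import _pf_current

# --- parameter vector indices ---
(RTF, F, KBT, QE, EPS,
 SA_PS, SA_SYN, SA_ECSL, CSA_P, VOL_PS, VOL_PSECS, L_P,
 V_A, G_KIR, G_K_BG, G_NA_BG, P_NKA, K_NAI, K_KE,
 IBAR, GAMMA, J0, TAU, G_ECS,
 PHI_W, K_PF_K, K_PF_NA, K_PF_CA,
 K_SOMA, NA_SOMA, CA_SOMA, K_GECS, NA_GECS, CA_PSECS,
 CM, G_K_NEU, G_NA_NEU, G_L_NEU, G_KB_NEU, G_NAB_NEU,
 E_K_NEU, E_NA_NEU, E_L_NEU, P_NKA_NEU, K_NAI_NEU, K_KE_NEU,
 K_SYN, NA_SYN, V_REST, THRESH_OFF, REFRACT,
 K_PSECS0, FLOOR) = range(53)

NP = 53

# --- flag vector indices ---
(FLAG_H_GATE, FLAG_BG_K_IN_PSC, FLAG_KIR_SQRT, FLAG_PF_ZCA,
 FLAG_STIM_MODE) = range(5)

# stimulus modes
STIM_NONE = 0
STIM_CONSTANT = 1
STIM_PULSE = 2
STIM_SPIKE_TRAIN = 3

# state vector indices
(IV, IM, IH, IN, IJ, IKP, INAP, ICAP, IKE, INAE) = range(10)

N_STATE = 10
N_CURRENT = 21


def pack_params(params, geometry) -> tuple[np.ndarray, np.ndarray]:
    """Flatten ModelParameters + Geometry into kernel vectors."""
    c = params.constants
    p = np.zeros(NP)
    p[RTF] = c.RTF
    p[F] = c.F
    p[KBT] = c.kBT
    p[QE] = c.Q
    p[EPS] = c.eps
    p[SA_PS] = geometry.sa_ps
    p[SA_SYN] = geometry.sa_syn
    p[SA_ECSL] = geometry.sa_psecs_gecs
    p[CSA_P] = geometry.csa_p
    p[VOL_PS] = geometry.vol_ps
    p[VOL_PSECS] = geometry.vol_psecs
    p[L_P] = geometry.l_p
    p[V_A] = params.v_a
    p[G_KIR] = params.g_kir
    p[G_K_BG] = params.g_k_bg
    p[G_NA_BG] = params.g_na_bg
    p[P_NKA] = params.p_nka_max
    p[K_NAI] = params.k_nai
    p[K_KE] = params.k_ke
    p[IBAR] = params.i_bar_ncx
    p[GAMMA] = params.gamma_ncx
    p[J0] = params.j0_eaat
    p[TAU] = params.tau_eaat
    p[G_ECS] = params.g_ecs_leak
    p[PHI_W] = params.phi_w
    p[K_PF_K] = params.k_pf_k
    p[K_PF_NA] = params.k_pf_na
    p[K_PF_CA] = params.k_pf_ca
    p[K_SOMA] = params.k_soma
    p[NA_SOMA] = params.na_soma
    p[CA_SOMA] = params.ca_soma
    p[K_GECS] = params.k_gecs
    p[NA_GECS] = params.na_gecs
    p[CA_PSECS] = params.ca_psecs
    p[CM] = params.c_m
    p[G_K_NEU] = params.g_k_neu
    p[G_NA_NEU] = params.g_na_neu
    p[G_L_NEU] = params.g_leak_neu
    p[G_KB_NEU] = params.g_k_bg_neu
    p[G_NAB_NEU] = params.g_na_bg_neu
    p[E_K_NEU] = params.e_k_neu
    p[E_NA_NEU] = params.e_na_neu
    p[E_L_NEU] = params.e_leak_neu
    p[P_NKA_NEU] = params.p_nka_max_neu
    p[K_NAI_NEU] = params.k_nai_neu
    p[K_KE_NEU] = params.k_ke_neu
    p[K_SYN] = params.k_syn
    p[NA_SYN] = params.na_syn
    p[V_REST] = params.v_rest_neu
    p[THRESH_OFF] = params.spike_threshold_offset
    p[REFRACT] = params.spike_refractory
    p[K_PSECS0] = params.k_psecs_0
    p[FLOOR] = 1e-12

    v = params.variants
    flags = np.zeros(5, dtype=np.int64)
    flags[FLAG_H_GATE] = 1 if v.na_channel_h_gate else 0
    flags[FLAG_BG_K_IN_PSC] = 1 if v.background_k_in_psc else 0
    flags[FLAG_KIR_SQRT] = 1 if v.kir_sqrt_k_out else 0
    flags[FLAG_PF_ZCA] = 1 if v.pf_charge_valence else 0
    return p, flags


@njit(cache=True)
def _eval(y, p, flags):
    """Right-hand side and named currents at state ``y``.

    Returns (dy, currents); ``dy`` excludes the EAAT impulse (event term)
    and the stimulus contribution to dV, which the integrator adds.
    Currents use the global sign convention (positive = out of the source
    compartment into the PsECS; leak: out of the PsECS).
    """
    dy = np.zeros(N_STATE)
    cur = np.zeros(N_CURRENT)

    v, m, h, n = y[IV], y[IM], y[IH], y[IN]
    j = y[IJ]
    kp, nap, cap = y[IKP], y[INAP], y[ICAP]
    ke, nae = y[IKE], y[INAE]
    rtf = p[RTF]
    f = p[F]
    v_a = p[V_A]

    # --- astrocyte membrane ---
    i_kir = _kir_density(v_a, kp, ke, p[G_KIR], rtf,
                         flags[FLAG_KIR_SQRT] == 1, p[K_PSECS0]) * p[SA_PS]
    pump = _nka_rate(p[P_NKA], nap, ke, p[K_NAI], p[K_KE])
    i_na_nka = 3.0 * f * pump * p[SA_PS]
    i_k_nka = -2.0 * f * pump * p[SA_PS]
    i_na_eaat = -j * f * p[VOL_PSECS]
    i_k_eaat = -i_na_eaat / 3.0
    i_na_ncx = _ncx_density(nap, nae, cap, p[CA_PSECS], v_a, rtf,
                            p[IBAR], p[GAMMA]) * p[SA_PS]
    i_ca_ncx = -2.0 * i_na_ncx / 3.0
    i_k_bg = _background_density(v_a, kp, ke, p[G_K_BG], rtf) * p[SA_PS]
    i_na_bg = _background_density(v_a, nap, nae, p[G_NA_BG], rtf) * p[SA_PS]

    # --- process (Poole-Frenkel); dV = V_A - V_m - Vr = -Vr ---
    vr_k = rtf * math.log(p[K_SOMA] / kp)
    vr_na = rtf * math.log(p[NA_SOMA] / nap)
    vr_ca = rtf * math.log(p[CA_SOMA] / cap)
    q_ca = 2.0 * p[QE] if flags[FLAG_PF_ZCA] == 1 else p[QE]
    i_k_pf = _pf_current(-vr_k, p[K_PF_K], p[L_P], p[PHI_W], p[QE], p[EPS],
                         p[KBT], p[CSA_P])
    i_na_pf = _pf_current(-vr_na, p[K_PF_NA], p[L_P], p[PHI_W], p[QE], p[EPS],
                          p[KBT], p[CSA_P])
    i_ca_pf = _pf_current(-vr_ca, p[K_PF_CA], p[L_P], p[PHI_W], q_ca, p[EPS],
                          p[KBT], p[CSA_P])

    # --- PsECS <-> GECS leak ---
    i_k_ecsl = _ecs_leak_density(ke, p[K_GECS], p[G_ECS], rtf) * p[SA_ECSL]
    i_na_ecsl = _ecs_leak_density(nae, p[NA_GECS], p[G_ECS], rtf) * p[SA_ECSL]

    # --- neuron ---
    gate_na = m ** 3 * (h if flags[FLAG_H_GATE] == 1 else 1.0)
    i_na_hh = p[G_NA_NEU] * gate_na * (v - p[E_NA_NEU]) * p[SA_SYN]
    i_k_hh = p[G_K_NEU] * n ** 4 * (v - p[E_K_NEU]) * p[SA_SYN]
    i_leak = p[G_L_NEU] * (v - p[E_L_NEU]) * p[SA_SYN]
    e_k_bg = rtf * math.log(ke / p[K_SYN])
    e_na_bg = rtf * math.log(nae / p[NA_SYN])
    i_k_bg_n = p[G_KB_NEU] * (v - e_k_bg) * p[SA_SYN]
    i_na_bg_n = p[G_NAB_NEU] * (v - e_na_bg) * p[SA_SYN]
    pump_n = _nka_rate(p[P_NKA_NEU], p[NA_SYN], ke, p[K_NAI_NEU], p[K_KE_NEU])
    i_na_nka_n = 3.0 * f * pump_n * p[SA_SYN]
    i_k_nka_n = -2.0 * f * pump_n * p[SA_SYN]

    # --- neuron voltage and gates ---
    i_out = (i_k_hh + i_na_hh + i_leak + i_k_bg_n + i_na_bg_n
             + i_na_nka_n + i_k_nka_n)
    dy[IV] = -i_out / p[SA_SYN] / p[CM]
    am, bm, ah, bh, an, bn = _hh_rates(v)
    dy[IM] = am * (1.0 - m) - bm * m
    dy[IH] = ah * (1.0 - h) - bh * h
    dy[IN] = an * (1.0 - n) - bn * n
    dy[IJ] = -j / p[TAU]

    # --- five concentration ODEs ---
    i_k_m = i_kir + i_k_nka + i_k_eaat
    if flags[FLAG_BG_K_IN_PSC] == 1:
        i_k_m += i_k_bg
    i_na_m = i_na_bg + i_na_nka + i_na_eaat + i_na_ncx
    dy[IKP] = -(i_k_m + i_k_pf) / (f * p[VOL_PS])
    dy[INAP] = -(i_na_m + i_na_pf) / (f * p[VOL_PS])
    dy[ICAP] = -(i_ca_ncx + i_ca_pf) / (2.0 * f * p[VOL_PS])
    i_k_neu = i_k_hh + i_k_bg_n + i_k_nka_n
    i_na_neu = i_na_hh + i_na_bg_n + i_na_nka_n
    dy[IKE] = (i_k_m + i_k_neu - i_k_ecsl) / (f * p[VOL_PSECS])
    dy[INAE] = (i_na_m + i_na_neu - i_na_ecsl) / (f * p[VOL_PSECS])

    cur[0] = i_kir
    cur[1] = i_k_nka
    cur[2] = i_k_eaat
    cur[3] = i_k_bg
    cur[4] = i_k_pf
    cur[5] = i_k_ecsl
    cur[6] = i_na_bg
    cur[7] = i_na_nka
    cur[8] = i_na_eaat
    cur[9] = i_na_ncx
    cur[10] = i_na_pf
    cur[11] = i_na_ecsl
    cur[12] = i_ca_ncx
    cur[13] = i_ca_pf
    cur[14] = i_k_hh
    cur[15] = i_na_hh
    cur[16] = i_leak
    cur[17] = i_k_bg_n
    cur[18] = i_na_bg_n
    cur[19] = i_na_nka_n
    cur[20] = i_k_nka_n
    return dy, cur


@njit(cache=True)
def integrate(y0, p, flags, dt, n_steps, amp, rate, width, t_on, t_off,
              events, stride, max_spikes):
    """Forward-Euler integration with spike-triggered EAAT impulses.

    Returns
    -------
    rec : (n_rec, 1 + N_STATE + N_CURRENT) array
    n_rec : int
    spikes : (max_spikes,) array of event times, first n_spikes valid
    n_spikes : int
    floor_events : int
    err_var : int      index of the first non-finite state (-1 if clean)
    err_time : float
    y : final state
    """
    y = y0.copy()
    n_rec_cap = n_steps // stride + 2
    rec = np.zeros((n_rec_cap, 1 + N_STATE + N_CURRENT))
    spikes = np.zeros(max_spikes)
    n_spikes = 0
    last_spike = -1e30
    floor_events = 0
    stim_mode = flags[FLAG_STIM_MODE]
    threshold = p[V_REST] + p[THRESH_OFF]
    floor = p[FLOOR]
    i_rec = 0
    next_event = 0

    for i in range(n_steps):
        t = i * dt
        dy, cur = _eval(y, p, flags)

        if i % stride == 0:
            rec[i_rec, 0] = t
            for k in range(N_STATE):
                rec[i_rec, 1 + k] = y[k]
            for k in range(N_CURRENT):
                rec[i_rec, 1 + N_STATE + k] = cur[k]
            i_rec += 1

        stim = 0.0
        if stim_mode == STIM_CONSTANT:
            if t_on <= t < t_off:
                stim = amp
        elif stim_mode == STIM_PULSE:
            if t_on <= t < t_off:
                phase = (t - t_on) % (1.0 / rate)
                if phase < width:
                    stim = amp

        v_prev = y[IV]
        for k in range(N_STATE):
            y[k] = y[k] + dt * dy[k]
        y[IV] += dt * stim / p[CM]
        # clamp gates
        for k in (IM, IH, IN):
            if y[k] < 0.0:
                y[k] = 0.0
            elif y[k] > 1.0:
                y[k] = 1.0
        if y[IJ] < 0.0:
            y[IJ] = 0.0

        # spike detection / event handling -> EAAT impulse this step
        t_next = t + dt
        if stim_mode == STIM_SPIKE_TRAIN:
            while next_event < len(events) and events[next_event] <= t_next:
                y[IJ] += p[J0]
                if n_spikes < max_spikes:
                    spikes[n_spikes] = events[next_event]
                    n_spikes += 1
                next_event += 1
        else:
            if y[IV] >= threshold and v_prev < threshold and \
                    (t_next - last_spike) > p[REFRACT]:
                if n_spikes < max_spikes:
                    spikes[n_spikes] = t_next
                    n_spikes += 1
                last_spike = t_next
                y[IJ] += p[J0]

        # concentration floor
        for k in (IKP, INAP, ICAP, IKE, INAE):
            if y[k] < floor:
                y[k] = floor
                floor_events += 1

        # non-finite guard
        for k in range(N_STATE):
            if not np.isfinite(y[k]):
                return rec, i_rec, spikes, n_spikes, floor_events, k, t_next, y

    # final row
    dy, cur = _eval(y, p, flags)
    rec[i_rec, 0] = n_steps * dt
    for k in range(N_STATE):
        rec[i_rec, 1 + k] = y[k]
    for k in range(N_CURRENT):
        rec[i_rec, 1 + N_STATE + k] = cur[k]
    i_rec += 1
    return rec, i_rec, spikes, n_spikes, floor_events, -1, 0.0, y
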