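"""Numba-compiled reaction kernels for the Courtemanche atrial membrane model.

The 21 state variables are stored in a ``(21, n_nodes)`` float64 array; the
ordering is given by :data:`STATE_NAMES`.  All membrane currents are handled
per unit capacitance (pA/pF), so the voltage equation reads
``dV/dt = -I_total + I_stim`` with voltages in mV and time in ms.

The kernels implement plain forward (explicit) Euler for every state
variable; the reference integration step is dt = 0.01 ms.
"""

import math

import numpy as np
from numba import njit

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "nai", "ki", "cai", "caup", "carel",
)
N_STATE = len(STATE_NAMES)

CURRENT_NAMES = (
    "I_Na", "I_K1", "I_to", "I_Kur", "I_Kr", "I_Ks", "I_CaL",
    "I_NaK", "I_NaCa", "I_bNa", "I_bCa", "I_pCa", "I_KACh", "I_total",
)
N_CURRENT = len(CURRENT_NAMES)

# Parameter-vector layout (see courtemanche.IonicParameters.as_array).
P_GNA, P_GTO, P_GKUR_SCALE, P_GKR, P_GKS, P_GCAL, P_GK1, P_GBNA, P_GBCA, \
    P_INAK_MAX, P_INACA_MAX, P_IPCA_MAX, P_IUP_MAX, P_GKACH_DOSE, P_CM, \
    P_CLAMP_NAK = range(16)
N_PARAM = 16

# Physical constants (Courtemanche et al. 1998 values).
R_GAS = 8.3143          # J mol^-1 K^-1
TEMP = 310.0            # K
FARADAY = 96.4867       # C mmol^-1
RTF = R_GAS * TEMP / FARADAY   # mV

V_I = 13668.0           # intracellular volume, um^3
V_UP = 1109.52          # SR uptake compartment volume, um^3
V_REL = 96.48           # SR release compartment volume, um^3

KO = 5.4                # mM
NAO = 140.0             # mM
CAO = 1.8               # mM

K_Q10 = 3.0
KM_NAI = 10.0
KM_KO = 1.5
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA_NCX = 0.35
K_REL = 30.0            # ms^-1
K_UP = 0.00092          # mM
CA_UP_MAX = 15.0        # mM
CMDN_MAX = 0.05         # mM
TRPN_MAX = 0.07         # mM
CSQN_MAX = 10.0         # mM
KM_CMDN = 0.00238       # mM
KM_TRPN = 0.0005        # mM
KM_CSQN = 0.8           # mM
TAU_TR = 180.0          # ms
TAU_FCA = 2.0           # ms
TAU_U = 8.0             # ms

SIGMA_NAK = (math.exp(NAO / 67.3) - 1.0) / 7.0


@njit(cache=True, fastmath=True)
def step_nodes(S, dt, istim, P, cur, want_cur, peaks, want_peaks):
    """Advance all nodes one forward-Euler step in place.

    S : (21, M) state array, updated in place.
    istim : (M,) stimulus current, pA/pF, positive = depolarizing.
    P : parameter vector (length N_PARAM).
    cur : (14, M) output current record, written iff want_cur.
    peaks : (4, M) running peak magnitudes of I_Na, I_to, I_Kur, I_CaL,
            updated iff want_peaks.
    Returns -1 on success, else the index of the first node where the
    voltage left [-200, 200] mV or became non-finite.
    """
    M = S.shape[1]
    bad = -1
    cm = P[P_CM]
    for n in range(M):
        v = S[0, n]
        m = S[1, n]
        h = S[2, n]
        jj = S[3, n]
        oa = S[4, n]
        oi = S[5, n]
        ua = S[6, n]
        ui = S[7, n]
        xr = S[8, n]
        xs = S[9, n]
        d = S[10, n]
        f = S[11, n]
        fca = S[12, n]
        u = S[13, n]
        vv = S[14, n]
        w = S[15, n]
        nai = S[16, n]
        ki = S[17, n]
        cai = S[18, n]
        caup = S[19, n]
        carel = S[20, n]

        ena = RTF * math.log(NAO / nai)
        ek = RTF * math.log(KO / ki)
        eca = 0.5 * RTF * math.log(CAO / cai)

        # --- membrane currents (pA/pF) ---
        ina = P[P_GNA] * m * m * m * h * jj * (v - ena)
        ik1 = P[P_GK1] * (v - ek) / (1.0 + math.exp(0.07 * (v + 80.0)))
        ito = P[P_GTO] * oa * oa * oa * oi * (v - ek)
        gkur = P[P_GKUR_SCALE] * (0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0)))
        ikur = gkur * ua * ua * ua * ui * (v - ek)
        ikr = P[P_GKR] * xr * (v - ek) / (1.0 + math.exp((v + 15.0) / 22.4))
        iks = P[P_GKS] * xs * xs * (v - ek)
        ical = P[P_GCAL] * d * f * fca * (v - 65.0)

        fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / RTF)
                      + 0.0365 * SIGMA_NAK * math.exp(-v / RTF))
        inak = P[P_INAK_MAX] * fnak * (KO / (KO + KM_KO)) \
            / (1.0 + (KM_NAI / nai) ** 1.5)

        expg = math.exp(GAMMA_NCX * v / RTF)
        expg1 = math.exp((GAMMA_NCX - 1.0) * v / RTF)
        inaca = P[P_INACA_MAX] * (expg * nai ** 3 * CAO - expg1 * NAO ** 3 * cai) \
            / ((KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO) * (1.0 + K_SAT * expg1))

        ibna = P[P_GBNA] * (v - ena)
        ibca = P[P_GBCA] * (v - eca)
        ipca = P[P_IPCA_MAX] * cai / (0.0005 + cai)

        # Acetylcholine-activated K+ current (Kneller et al. formulation);
        # the dose-response factor is precomputed into P[P_GKACH_DOSE].
        ikach = P[P_GKACH_DOSE] * (0.0517 + 0.4516 / (1.0 + math.exp((v + 59.53) / 17.18))) * (v - ek)

        itot = (ina + ik1 + ito + ikur + ikr + iks + ical + inak + inaca
                + ibna + ibca + ipca + ikach)

        if want_cur:
            cur[0, n] = ina
            cur[1, n] = ik1
            cur[2, n] = ito
            cur[3, n] = ikur
            cur[4, n] = ikr
            cur[5, n] = iks
            cur[6, n] = ical
            cur[7, n] = inak
            cur[8, n] = inaca
            cur[9, n] = ibna
            cur[10, n] = ibca
            cur[11, n] = ipca
            cur[12, n] = ikach
            cur[13, n] = itot
        if want_peaks:
            if abs(ina) > peaks[0, n]:
                peaks[0, n] = abs(ina)
            if abs(ito) > peaks[1, n]:
                peaks[1, n] = abs(ito)
            if abs(ikur) > peaks[2, n]:
                peaks[2, n] = abs(ikur)
            if abs(ical) > peaks[3, n]:
                peaks[3, n] = abs(ical)

        # --- gating kinetics ---
        # fast Na+ gates
        if v == -47.13:
            am = 3.2
        else:
            am = 0.32 * (v + 47.13) / (1.0 - math.exp(-0.1 * (v + 47.13)))
        bm = 0.08 * math.exp(-v / 11.0)
        if v < -40.0:
            ah = 0.135 * math.exp(-(v + 80.0) / 6.8)
            bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
            aj = (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v)) \
                * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23)))
            bj = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
        else:
            ah = 0.0
            bh = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
            aj = 0.0
            bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))

        # transient outward gates
        a_oa = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
        b_oa = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
        tau_oa = 1.0 / ((a_oa + b_oa) * K_Q10)
        oa_inf = 1.0 / (1.0 + math.exp(-(v + 20.47) / 17.54))
        a_oi = 1.0 / (18.53 + math.exp((v + 113.7) / 10.95))
        b_oi = 1.0 / (35.56 + math.exp(-(v + 1.26) / 7.44))
        tau_oi = 1.0 / ((a_oi + b_oi) * K_Q10)
        oi_inf = 1.0 / (1.0 + math.exp((v + 43.1) / 5.3))

        # ultrarapid delayed-rectifier gates (same alpha/beta shape as oa)
        tau_ua = tau_oa
        ua_inf = 1.0 / (1.0 + math.exp(-(v + 30.3) / 9.6))
        a_ui = 1.0 / (21.0 + math.exp(-(v - 185.0) / 28.0))
        b_ui = math.exp((v - 158.0) / 16.0)
        tau_ui = 1.0 / ((a_ui + b_ui) * K_Q10)
        ui_inf = 1.0 / (1.0 + math.exp((v - 99.45) / 27.48))

        # rapid / slow delayed rectifiers
        if abs(v + 14.1) < 1e-10:
            a_xr = 0.0015
        else:
            a_xr = 0.0003 * (v + 14.1) / (1.0 - math.exp(-(v + 14.1) / 5.0))
        if abs(v - 3.3328) < 1e-10:
            b_xr = 3.7836118e-4
        else:
            b_xr = 7.3898e-5 * (v - 3.3328) / (math.exp((v - 3.3328) / 5.1237) - 1.0)
        tau_xr = 1.0 / (a_xr + b_xr)
        xr_inf = 1.0 / (1.0 + math.exp(-(v + 14.1) / 6.5))

        if abs(v - 19.9) < 1e-10:
            a_xs = 0.00068
            b_xs = 0.000315
        else:
            a_xs = 4e-5 * (v - 19.9) / (1.0 - math.exp(-(v - 19.9) / 17.0))
            b_xs = 3.5e-5 * (v - 19.9) / (math.exp((v - 19.9) / 9.0) - 1.0)
        tau_xs = 0.5 / (a_xs + b_xs)
        xs_inf = 1.0 / math.sqrt(1.0 + math.exp(-(v - 19.9) / 12.7))

        # L-type Ca2+ gates
        d_inf = 1.0 / (1.0 + math.exp(-(v + 10.0) / 8.0))
        e624 = math.exp(-(v + 10.0) / 6.24)
        if abs(v + 10.0) < 1e-10:
            tau_d = 4.579 / (1.0 + e624)
        else:
            tau_d = (1.0 - e624) / (0.035 * (v + 10.0) * (1.0 + e624))
        f_inf = 1.0 / (1.0 + math.exp((v + 28.0) / 6.9))
        tau_f = 9.0 / (0.0197 * math.exp(-(0.0337 * 0.0337) * (v + 10.0) * (v + 10.0)) + 0.02)
        fca_inf = 1.0 / (1.0 + cai / 0.00035)

        # SR Ca2+ handling
        irel = K_REL * u * u * vv * w * (carel - cai)         # mM/ms
        itr = (caup - carel) / TAU_TR                          # mM/ms
        iup = P[P_IUP_MAX] / (1.0 + K_UP / cai)                # mM/ms
        iupleak = P[P_IUP_MAX] * caup / CA_UP_MAX              # mM/ms

        fn = 1e3 * (1e-15 * V_REL * irel
                    - (1e-15 / (2.0 * FARADAY)) * (0.5 * ical * cm - 0.2 * inaca * cm))
        u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
        tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
        v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
        e79 = math.exp(-(v - 7.9) / 5.0)
        if abs(v - 7.9) < 1e-10:
            tau_w = 6.0 * 0.2 / 1.3
        else:
            tau_w = 6.0 * (1.0 - e79) / ((1.0 + 0.3 * e79) * (v - 7.9))
        w_inf = 1.0 - 1.0 / (1.0 + math.exp(-(v - 40.0) / 17.0))

        # --- concentration fluxes (currents in pA) ---
        ina_pa = ina * cm
        ibna_pa = ibna * cm
        inak_pa = inak * cm
        inaca_pa = inaca * cm
        ik_pa = (ik1 + ito + ikur + ikr + iks + ikach) * cm
        ical_pa = ical * cm
        ipca_pa = ipca * cm
        ibca_pa = ibca * cm

        if P[P_CLAMP_NAK] != 0.0:
            # long-simulation convention: intracellular Na+ and K+ held fixed
            dnai = 0.0
            dki = 0.0
        else:
            dnai = (-3.0 * inak_pa - (3.0 * inaca_pa + ibna_pa + ina_pa)) / (V_I * FARADAY)
            dki = (2.0 * inak_pa - ik_pa) / (V_I * FARADAY)
        b1 = (2.0 * inaca_pa - (ipca_pa + ical_pa + ibca_pa)) / (2.0 * V_I * FARADAY) \
            + (V_UP * (iupleak - iup) + irel * V_REL) / V_I
        b2 = 1.0 + TRPN_MAX * KM_TRPN / ((cai + KM_TRPN) * (cai + KM_TRPN)) \
            + CMDN_MAX * KM_CMDN / ((cai + KM_CMDN) * (cai + KM_CMDN))
        dcai = b1 / b2
        dcaup = iup - iupleak - itr * V_REL / V_UP
        dcarel = (itr - irel) / (1.0 + CSQN_MAX * KM_CSQN / ((carel + KM_CSQN) * (carel + KM_CSQN)))

        # --- time update: forward Euler for V and concentrations,
        # Rush-Larsen (exact exponential relaxation to the instantaneous
        # steady state) for the gates, which keeps the stiff Na+ gating
        # stable at hyperpolarized voltages where dt*(alpha+beta) > 2 ---
        vnew = v + dt * (-itot + istim[n])
        S[0, n] = vnew
        sm = am + bm
        sh = ah + bh
        sj = aj + bj
        S[1, n] = am / sm + (m - am / sm) * math.exp(-dt * sm)
        S[2, n] = ah / sh + (h - ah / sh) * math.exp(-dt * sh)
        S[3, n] = aj / sj + (jj - aj / sj) * math.exp(-dt * sj)
        S[4, n] = oa_inf + (oa - oa_inf) * math.exp(-dt / tau_oa)
        S[5, n] = oi_inf + (oi - oi_inf) * math.exp(-dt / tau_oi)
        S[6, n] = ua_inf + (ua - ua_inf) * math.exp(-dt / tau_ua)
        S[7, n] = ui_inf + (ui - ui_inf) * math.exp(-dt / tau_ui)
        S[8, n] = xr_inf + (xr - xr_inf) * math.exp(-dt / tau_xr)
        S[9, n] = xs_inf + (xs - xs_inf) * math.exp(-dt / tau_xs)
        S[10, n] = d_inf + (d - d_inf) * math.exp(-dt / tau_d)
        S[11, n] = f_inf + (f - f_inf) * math.exp(-dt / tau_f)
        S[12, n] = fca_inf + (fca - fca_inf) * math.exp(-dt / TAU_FCA)
        S[13, n] = u_inf + (u - u_inf) * math.exp(-dt / TAU_U)
        S[14, n] = v_inf + (vv - v_inf) * math.exp(-dt / tau_v)
        S[15, n] = w_inf + (w - w_inf) * math.exp(-dt / tau_w)
        S[16, n] = nai + dt * dnai
        S[17, n] = ki + dt * dki
        S[18, n] = cai + dt * dcai
        S[19, n] = caup + dt * dcaup
        S[20, n] = carel + dt * dcarel

        if bad < 0 and (not math.isfinite(vnew) or abs(vnew) > 200.0):
            bad = n
    return bad


@njit(cache=True, fastmath=True)
def pace_cell_kernel(S, P, dt, n_steps, period_steps, dur_steps, amp, sample_every, v_out):
    """Pace a single cell with a periodic rectangular pulse train.

    Stimuli of ``amp`` pA/pF start at steps k*period_steps and last
    dur_steps steps.  V is sampled into v_out every ``sample_every`` steps.
    Returns the step index of the first instability, or -1.
    """
    istim = np.zeros(1)
    cur = np.zeros((N_CURRENT, 1))
    peaks = np.zeros((4, 1))
    k = 0
    for step in range(n_steps):
        phase = step % period_steps
        istim[0] = amp if phase < dur_steps else 0.0
        bad = step_nodes(S, dt, istim, P, cur, False, peaks, False)
        if bad >= 0:
            return step
        if step % sample_every == 0:
            v_out[k] = S[0, 0]
            k += 1
    return -1
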