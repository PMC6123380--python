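"""Numba kernels for the ionic models.

Two membrane models share one calling convention: the detailed human atrial
model (Courtemanche–Ramirez–Nattel formulation, 21 state variables) used for
physiological runs, and a 3-variable Fenton–Karma model used where speed
matters more than ionic detail.  State is a ``(n_state, n_nodes)`` float64
array; kernels update it in place for one time step.  Gating variables use
the Rush–Larsen exponential update; voltage and concentrations use forward
Euler.

Conductance scaling factors enter as per-node arrays so that fibrotic and
non-fibrotic nodes can coexist in one tissue sheet.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Detailed human atrial model (CRN): state layout
# ---------------------------------------------------------------------------

CRN_STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w",
    "Nai", "Ki", "Cai", "Caup", "Carel",
)
CRN_NSTATE = len(CRN_STATE_NAMES)
CRN_GATES = slice(1, 16)
CRN_CONCS = slice(16, 21)

# order of per-node conductance scaling factors
CRN_SCAL_NAMES = ("gNa", "gK1", "gto", "gKur", "gCaL")
CRN_NSCAL = len(CRN_SCAL_NAMES)

# physical constants (units: mV, ms, mM, pA/pF, pF, µm³)
_R = 8.3143
_T = 310.0
_F = 96.4867
_CM = 100.0
_VI = 13668.0
_VUP = 1109.52
_VREL = 96.48
_KO = 5.4
_NAO = 140.0
_CAO = 1.8
_G_NA = 7.8
_G_K1 = 0.09
_G_TO = 0.1652
_G_KR = 0.029411765
_G_KS = 0.12941176
_G_CAL = 0.12375
_G_BCA = 0.001131
_G_BNA = 0.0006744375
_I_NAK_MAX = 0.59933874
_KM_NAI = 10.0
_KM_KO = 1.5
_I_NACA_MAX = 1600.0
_KM_NA = 87.5
_KM_CA = 1.38
_KSAT = 0.1
_GAMMA = 0.35
_I_PCA_MAX = 0.275
_I_UP_MAX = 0.005
_K_UP = 0.00092
_CA_UP_MAX = 15.0
_K_REL = 30.0
_CMDN_MAX = 0.05
_TRPN_MAX = 0.07
_CSQN_MAX = 10.0
_KM_CMDN = 0.00238
_KM_TRPN = 0.0005
_KM_CSQN = 0.8
_KQ10 = 3.0
_RTF = _R * _T / _F


def crn_initial_state(n: int) -> np.ndarray:
    """Resting state of the detailed model, tiled over ``n`` nodes."""
    y0 = np.array([
        -81.18,          # V
        2.908e-3,        # m
        9.649e-1,        # h
        9.775e-1,        # j
        3.043e-2,        # oa
        9.992e-1,        # oi
        4.966e-3,        # ua
        9.986e-1,        # ui
        3.296e-5,        # xr
        1.869e-2,        # xs
        1.367e-4,        # d
        9.996e-1,        # f
        7.755e-1,        # fca
        0.0,             # u
        1.0,             # v
        9.992e-1,        # w
        1.117e1,         # Nai
        1.390e2,         # Ki
        1.013e-4,        # Cai
        1.488,           # Caup
        1.488,           # Carel
    ])
    return np.repeat(y0[:, None], n, axis=1)


@njit(cache=True, fastmath=True)
def crn_step(S, i_stim, dt, scal):  # pragma: no cover - exercised via wrappers
    """Advance the detailed model one step of ``dt`` ms (in place).

    S : (21, n) state; i_stim : (n,) depolarizing stimulus in pA/pF
    (positive = depolarizing); scal : (5, n) conductance scalings in the
    order gNa, gK1, gto, gKur, gCaL.
    """
    n = S.shape[1]
    for k in range(n):
        V = S[0, k]
        m = S[1, k]
        h = S[2, k]
        j = S[3, k]
        oa = S[4, k]
        oi = S[5, k]
        ua = S[6, k]
        ui = S[7, k]
        xr = S[8, k]
        xs = S[9, k]
        d = S[10, k]
        f = S[11, k]
        fca = S[12, k]
        u = S[13, k]
        v = S[14, k]
        w = S[15, k]
        Nai = S[16, k]
        Ki = S[17, k]
        Cai = S[18, k]
        Caup = S[19, k]
        Carel = S[20, k]

        sNa = scal[0, k]
        sK1 = scal[1, k]
        sto = scal[2, k]
        sKur = scal[3, k]
        sCaL = scal[4, k]

        # reversal potentials
        ENa = _RTF * np.log(_NAO / Nai)
        EK = _RTF * np.log(_KO / Ki)
        ECa = 0.5 * _RTF * np.log(_CAO / Cai)

        # --- membrane currents (pA/pF) ---
        INa = sNa * _G_NA * m * m * m * h * j * (V - ENa)
        IK1 = sK1 * _G_K1 * (V - EK) / (1.0 + np.exp(0.07 * (V + 80.0)))
        Ito = sto * _G_TO * oa * oa * oa * oi * (V - EK)
        gkur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
        IKur = sKur * gkur * ua * ua * ua * ui * (V - EK)
        IKr = _G_KR * xr * (V - EK) / (1.0 + np.exp((V + 15.0) / 22.4))
        IKs = _G_KS * xs * xs * (V - EK)
        ICaL = sCaL * _G_CAL * d * f * fca * (V - 65.0)

        sigma_nak = (np.exp(_NAO / 67.3) - 1.0) / 7.0
        fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / _RTF)
                      + 0.0365 * sigma_nak * np.exp(-V / _RTF))
        INaK = (_I_NAK_MAX * fnak * _KO / (_KO + _KM_KO)
                / (1.0 + (_KM_NAI / Nai) ** 1.5))

        evf = np.exp(_GAMMA * V / _RTF)
        evf1 = np.exp((_GAMMA - 1.0) * V / _RTF)
        INaCa = (_I_NACA_MAX
                 * (evf * Nai ** 3 * _CAO - evf1 * _NAO ** 3 * Cai)
                 / ((_KM_NA ** 3 + _NAO ** 3) * (_KM_CA + _CAO)
                    * (1.0 + _KSAT * evf1)))

        IbNa = _G_BNA * (V - ENa)
        IbCa = _G_BCA * (V - ECa)
        IpCa = _I_PCA_MAX * Cai / (0.0005 + Cai)

        # --- SR fluxes (mM/ms) ---
        Irel = _K_REL * u * u * v * w * (Carel - Cai)
        Itr = (Caup - Carel) / 180.0
        Iup = _I_UP_MAX / (1.0 + _K_UP / Cai)
        Iupleak = _I_UP_MAX * Caup / _CA_UP_MAX

        # --- gate kinetics ---
        # INa gates
        dV = V + 47.13
        if np.abs(dV) < 1e-6:
            am = 3.2
        else:
            am = 0.32 * dV / (1.0 - np.exp(-0.1 * dV))
        bm = 0.08 * np.exp(-V / 11.0)
        if V >= -40.0:
            ah = 0.0
            bh = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
            aj = 0.0
            bj = (0.3 * np.exp(-2.535e-7 * V)
                  / (1.0 + np.exp(-0.1 * (V + 32.0))))
        else:
            ah = 0.135 * np.exp(-(V + 80.0) / 6.8)
            bh = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
            aj = ((-1.2714e5 * np.exp(0.2444 * V)
                   - 3.474e-5 * np.exp(-0.04391 * V)) * (V + 37.78)
                  / (1.0 + np.exp(0.311 * (V + 79.23))))
            bj = (0.1212 * np.exp(-0.01052 * V)
                  / (1.0 + np.exp(-0.1378 * (V + 40.14))))
        m = _rl(m, am / (am + bm), 1.0 / (am + bm), dt)
        h = _rl(h, ah / (ah + bh), 1.0 / (ah + bh), dt)
        j = _rl(j, aj / (aj + bj), 1.0 / (aj + bj), dt)

        # Ito gates
        aoa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
        boa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
        oa_inf = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
        oa = _rl(oa, oa_inf, 1.0 / ((aoa + boa) * _KQ10), dt)
        aoi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
        boi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
        oi_inf = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
        oi = _rl(oi, oi_inf, 1.0 / ((aoi + boi) * _KQ10), dt)

        # IKur gates
        aua = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
        bua = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
        ua_inf = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
        ua = _rl(ua, ua_inf, 1.0 / ((aua + bua) * _KQ10), dt)
        aui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
        bui = np.exp((V - 158.0) / 16.0)
        ui_inf = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
        ui = _rl(ui, ui_inf, 1.0 / ((aui + bui) * _KQ10), dt)

        # IKr gate
        dV = V + 14.1
        if np.abs(dV) < 1e-6:
            axr = 0.0015
        else:
            axr = 0.0003 * dV / (1.0 - np.exp(-dV / 5.0))
        dV = V - 3.3328
        if np.abs(dV) < 1e-6:
            bxr = 3.7836118e-4
        else:
            bxr = 7.3898e-5 * dV / (np.exp(dV / 5.1237) - 1.0)
        xr_inf = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
        xr = _rl(xr, xr_inf, 1.0 / (axr + bxr), dt)

        # IKs gate
        dV = V - 19.9
        if np.abs(dV) < 1e-6:
            axs = 6.8e-4
            bxs = 3.15e-4
        else:
            axs = 4e-5 * dV / (1.0 - np.exp(-dV / 17.0))
            bxs = 3.5e-5 * dV / (np.exp(dV / 9.0) - 1.0)
        xs_inf = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
        xs = _rl(xs, xs_inf, 0.5 / (axs + bxs), dt)

        # ICaL gates
        dV = V + 10.0
        d_inf = 1.0 / (1.0 + np.exp(-dV / 8.0))
        if np.abs(dV) < 1e-6:
            tau_d = 2.289538
        else:
            e = np.exp(-dV / 6.24)
            tau_d = (1.0 - e) / (0.035 * dV * (1.0 + e))
        d = _rl(d, d_inf, tau_d, dt)
        f_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
        tau_f = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * dV * dV) + 0.02)
        f = _rl(f, f_inf, tau_f, dt)
        fca_inf = 1.0 / (1.0 + Cai / 0.00035)
        fca = _rl(fca, fca_inf, 2.0, dt)

        # SR release gates (Fn in units of mM·µm³/ms scaled as published)
        Fn = (1e-12 * _VREL * Irel
              - 5e-13 / _F * (0.5 * ICaL - 0.2 * INaCa) * _CM)
        u_inf = 1.0 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
        u = _rl(u, u_inf, 8.0, dt)
        v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 13.67e-16))
        tau_v = 1.91 + 2.09 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
        v = _rl(v, v_inf, tau_v, dt)
        w_inf = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
        dV = V - 7.9
        if np.abs(dV) < 1e-6:
            tau_w = 0.923077
        else:
            e = np.exp(-dV / 5.0)
            tau_w = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * dV)
        w = _rl(w, w_inf, tau_w, dt)

        # --- concentrations (forward Euler) ---
        dNai = (-3.0 * INaK - 3.0 * INaCa - IbNa - INa) * _CM / (_F * _VI)
        dKi = ((2.0 * INaK - IK1 - Ito - IKur - IKr - IKs)
               * _CM / (_F * _VI))
        b1 = ((2.0 * INaCa - IpCa - ICaL - IbCa) * _CM / (2.0 * _F * _VI)
              + (_VUP * (Iupleak - Iup) + Irel * _VREL) / _VI)
        b2 = (1.0
              + _TRPN_MAX * _KM_TRPN / ((Cai + _KM_TRPN) ** 2)
              + _CMDN_MAX * _KM_CMDN / ((Cai + _KM_CMDN) ** 2))
        dCai = b1 / b2
        dCaup = Iup - Iupleak - Itr * _VREL / _VUP
        dCarel = ((Itr - Irel)
                  / (1.0 + _CSQN_MAX * _KM_CSQN / ((Carel + _KM_CSQN) ** 2)))

        Iion = (INa + IK1 + Ito + IKur + IKr + IKs + ICaL + IpCa
                + INaK + INaCa + IbNa + IbCa)
        V = V + dt * (-Iion + i_stim[k])

        S[0, k] = V
        S[1, k] = m
        S[2, k] = h
        S[3, k] = j
        S[4, k] = oa
        S[5, k] = oi
        S[6, k] = ua
        S[7, k] = ui
        S[8, k] = xr
        S[9, k] = xs
        S[10, k] = d
        S[11, k] = f
        S[12, k] = fca
        S[13, k] = u
        S[14, k] = v
        S[15, k] = w
        S[16, k] = Nai + dt * dNai
        S[17, k] = Ki + dt * dKi
        S[18, k] = Cai + dt * dCai
        S[19, k] = Caup + dt * dCaup
        S[20, k] = Carel + dt * dCarel


@njit(cache=True, fastmath=True, inline="always")
def _rl(g, g_inf, tau, dt):
    """Rush–Larsen exponential update of a gate toward its steady state."""
    return g_inf + (g - g_inf) * np.exp(-dt / tau)


# ---------------------------------------------------------------------------
# Fenton–Karma 3-variable reduced model
# ---------------------------------------------------------------------------

FK_STATE_NAMES = ("V", "v", "w")
FK_NSTATE = 3
#: exc scales excitability (1/tau_d); rep scales the repolarizing current
#: (rep < 1 lengthens the action potential, as in fibrosis-affected cells)
FK_SCAL_NAMES = ("exc", "rep")
FK_NSCAL = 2

# resting/plateau mapping u∈[0,1] -> mV
FK_V_REST = -85.0
FK_V_AMP = 100.0

# parameter set supporting a stable spiral (modified BR-like kinetics with
# shortened repolarization so the rotor tip can re-enter its own tail)
_FK_TAU_VP = 3.33
_FK_TAU_V1M = 1250.0
_FK_TAU_V2M = 19.6
_FK_TAU_WP = 870.0
_FK_TAU_WM = 41.0
_FK_TAU_D = 0.25
_FK_TAU_0 = 12.5
_FK_TAU_R = 25.0
_FK_TAU_SI = 29.0
_FK_K = 10.0
_FK_UCSI = 0.85
_FK_UC = 0.13
_FK_UV = 0.04


def fk_initial_state(n: int) -> np.ndarray:
    y0 = np.array([FK_V_REST, 1.0, 1.0])
    return np.repeat(y0[:, None], n, axis=1)


@njit(cache=True, fastmath=True)
def fk_step(S, i_stim, dt, scal):  # pragma: no cover - exercised via wrappers
    """One forward-Euler step of the reduced model (in place).

    Stimulus is interpreted in pA/pF-equivalent units and converted to the
    dimensionless activation variable via the voltage mapping.
    """
    n = S.shape[1]
    for k in range(n):
        u = (S[0, k] - FK_V_REST) / FK_V_AMP
        v = S[1, k]
        w = S[2, k]
        exc = scal[0, k]
        rep = scal[1, k]

        p = 1.0 if u >= _FK_UC else 0.0
        q = 1.0 if u >= _FK_UV else 0.0

        jfi = -v * p * (1.0 - u) * (u - _FK_UC) * exc / _FK_TAU_D
        jso = u * (1.0 - p) / _FK_TAU_0 + p * rep / _FK_TAU_R
        jsi = -w * (1.0 + np.tanh(_FK_K * (u - _FK_UCSI))) / (2.0 * _FK_TAU_SI)

        tau_vm = q * _FK_TAU_V1M + (1.0 - q) * _FK_TAU_V2M
        dv = (1.0 - p) * (1.0 - v) / tau_vm - p * v / _FK_TAU_VP
        dw = (1.0 - p) * (1.0 - w) / _FK_TAU_WM - p * w / _FK_TAU_WP

        du = -(jfi + jso + jsi) + i_stim[k] / FK_V_AMP
        S[0, k] = FK_V_REST + FK_V_AMP * (u + dt * du)
        S[1, k] = min(max(v + dt * dv, 0.0), 1.0)
        S[2, k] = min(max(w + dt * dw, 0.0), 1.0)
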