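"""Courtemanche–Ramirez–Nattel (1998) human atrial myocyte model.

Twenty-one state variables: potential, fifteen gates (including the
Ca-release gates u, v, w and the Ca-dependent inactivation gate f_Ca),
and five concentration pools (Na_i, K_i, Ca_i, Ca_up, Ca_rel).

Potentials in mV, time in ms, concentrations in mM, membrane currents in
pA/pF (the cell capacitance Cm = 100 pF enters the concentration balances).
The three calcium-release gates u, v, w relax toward steady states driven
by the flux variable Fn, and f_Ca by Ca_i, so they are integrated by the
exponential rule together with the voltage gates.
"""

from __future__ import annotations

import numpy as np

from .base import IonicModel, register_model

__all__ = ["Courtemanche"]

R_GAS = 8.3143      # J/(mol K)
TEMP = 310.0
FARADAY = 96.4867   # C/mmol
RTF = R_GAS * TEMP / FARADAY  # mV

KO, NAO, CAO = 5.4, 140.0, 1.8
CM = 100.0          # pF
VI, VUP, VRELV = 13668.0, 1109.52, 96.48  # um^3

GNA = 7.8
GK1 = 0.09
GTO = 0.1652
GKR = 0.029411765
GKS = 0.12941176
GCAL = 0.12375
GBCA = 0.00113
GBNA = 0.0006744375
INAK_MAX = 0.59933874
KM_NAI, KM_KO = 10.0, 1.5
INACA_MAX, KM_NA, KM_CA, KSAT, GAMMA = 1600.0, 87.5, 1.38, 0.1, 0.35
IPCA_MAX = 0.275
KREL = 30.0
IUP_MAX, K_UP, CA_UP_MAX = 0.005, 0.00092, 15.0
TRPN_MAX, KM_TRPN = 0.07, 0.0005
CMDN_MAX, KM_CMDN = 0.05, 0.00238
CSQN_MAX, KM_CSQN = 10.0, 0.8
TAU_TR, TAU_U, TAU_FCA = 180.0, 8.0, 2.0
KQ10 = 3.0

_STATE_NAMES = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f",
                "fca", "u", "vg", "w", "na_i", "k_i", "ca_i", "ca_up",
                "ca_rel")
_GATES = tuple(range(15))

# Quiescent equilibrium: published initial conditions relaxed to steady
# state on this module's rhs (stiff integration, rtol 1e-10); residual
# |d/dt| < 1e-7 per ms.
_REST = dict(
    v=-81.18669125,
    s=(2.905590486e-03, 9.649735342e-01, 9.775230143e-01, 3.042441698e-02,
       9.992435884e-01, 4.963358144e-03, 9.986048928e-01, 3.293210954e-05,
       1.868628169e-02, 1.365973497e-04, 9.995510797e-01, 7.762111123e-01,
       0.0, 1.0, 9.991988244e-01, 1.112991289e+01, 1.390412423e+02,
       1.009082572e-04, 1.482629562e+00, 1.482630161e+00),
)


@register_model
class Courtemanche(IonicModel):
    name = "courtemanche"
    aliases = ("atrial", "crn98")
    state_names = _STATE_NAMES
    gate_idx = _GATES
    dt_default = 0.02
    activation_threshold = -40.0  # mV, upstroke detection level
    Cm = 0.01
    chi = 140.0

    rest_v = _REST["v"]
    rest_s = _REST["s"]

    def __init__(self):
        self.params = {}

    def rates(self, v, s, I_stim=0.0):
        (m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, vg, w,
         nai, ki, cai, caup, carel) = s
        exp = np.exp
        vfrt = v / RTF

        ena = RTF * np.log(NAO / nai)
        ek = RTF * np.log(KO / ki)
        eca = 0.5 * RTF * np.log(CAO / cai)

        ina = GNA * m ** 3 * h * j * (v - ena)
        ik1 = GK1 * (v - ek) / (1.0 + exp(0.07 * (v + 80.0)))
        ito = GTO * oa ** 3 * oi * (v - ek)
        gkur = 0.005 + 0.05 / (1.0 + exp(-(v - 15.0) / 13.0))
        ikur = gkur * ua ** 3 * ui * (v - ek)
        ikr = GKR * xr * (v - ek) / (1.0 + exp((v + 15.0) / 22.4))
        iks = GKS * xs ** 2 * (v - ek)
        ical = GCAL * d * f * fca * (v - 65.0)
        ipca = IPCA_MAX * cai / (0.0005 + cai)

        sigma = (exp(NAO / 67.3) - 1.0) / 7.0
        fnak = 1.0 / (1.0 + 0.1245 * exp(-0.1 * vfrt)
                      + 0.0365 * sigma * exp(-vfrt))
        inak = (INAK_MAX * fnak / (1.0 + (KM_NAI / nai) ** 1.5)
                * KO / (KO + KM_KO))
        e1 = exp(GAMMA * vfrt)
        e2 = exp((GAMMA - 1.0) * vfrt)
        inaca = (INACA_MAX * (e1 * nai ** 3 * CAO - e2 * NAO ** 3 * cai)
                 / ((KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO)
                    * (1.0 + KSAT * e2)))
        ibna = GBNA * (v - ena)
        ibca = GBCA * (v - eca)

        itot = (ina + ik1 + ito + ikur + ikr + iks + ical + ipca + inak
                + inaca + ibna + ibca)
        dv = -itot + I_stim

        # --- SR calcium fluxes --------------------------------------------
        irel = KREL * u ** 2 * vg * w * (carel - cai)
        itr = (caup - carel) / TAU_TR
        iup = IUP_MAX / (1.0 + K_UP / cai)
        iupleak = IUP_MAX * caup / CA_UP_MAX

        # --- gate kinetics -------------------------------------------------
        num = v + 47.13
        am = np.where(np.abs(num) < 1e-10, 3.2,
                      0.32 * num / (1.0 - exp(-0.1 * num)))
        bm = 0.08 * exp(-v / 11.0)
        m_inf, tau_m = am / (am + bm), 1.0 / (am + bm)

        lo = v < -40.0
        ah = np.where(lo, 0.135 * exp(-(v + 80.0) / 6.8), 0.0)
        bh = np.where(lo, 3.56 * exp(0.079 * v) + 3.1e5 * exp(0.35 * v),
                      1.0 / (0.13 * (1.0 + exp(-(v + 10.66) / 11.1))))
        h_inf, tau_h = ah / (ah + bh), 1.0 / (ah + bh)
        with np.errstate(over="ignore"):
            aj = np.where(lo,
                          (-1.2714e5 * exp(0.2444 * v)
                           - 3.474e-5 * exp(-0.04391 * v)) * (v + 37.78)
                          / (1.0 + exp(0.311 * (v + 79.23))), 0.0)
            bj = np.where(lo,
                          0.1212 * exp(-0.01052 * v)
                          / (1.0 + exp(-0.1378 * (v + 40.14))),
                          0.3 * exp(-2.535e-7 * v)
                          / (1.0 + exp(-0.1 * (v + 32.0))))
        j_inf, tau_j = aj / (aj + bj), 1.0 / (aj + bj)

        aoa = 0.65 / (exp(-(v + 10.0) / 8.5) + exp(-(v - 30.0) / 59.0))
        boa = 0.65 / (2.5 + exp((v + 82.0) / 17.0))
        tau_oa = 1.0 / ((aoa + boa) * KQ10)
        oa_inf = 1.0 / (1.0 + exp(-(v + 20.47) / 17.54))
        aoi = 1.0 / (18.53 + exp((v + 113.7) / 10.95))
        boi = 1.0 / (35.56 + exp(-(v + 1.26) / 7.44))
        tau_oi = 1.0 / ((aoi + boi) * KQ10)
        oi_inf = 1.0 / (1.0 + exp((v + 43.1) / 5.3))

        tau_ua = tau_oa
        ua_inf = 1.0 / (1.0 + exp(-(v + 30.3) / 9.6))
        aui = 1.0 / (21.0 + exp(-(v - 185.0) / 28.0))
        bui = exp((v - 158.0) / 16.0)
        tau_ui = 1.0 / ((aui + bui) * KQ10)
        ui_inf = 1.0 / (1.0 + exp((v - 99.45) / 27.48))

        n1 = v + 14.1
        axr = np.where(np.abs(n1) < 1e-10, 0.0015,
                       0.0003 * n1 / (1.0 - exp(-n1 / 5.0)))
        n2 = v - 3.3328
        bxr = np.where(np.abs(n2) < 1e-10, 3.7836118e-4,
                       7.3898e-5 * n2 / (exp(n2 / 5.1237) - 1.0))
        tau_xr = 1.0 / (axr + bxr)
        xr_inf = 1.0 / (1.0 + exp(-n1 / 6.5))

        n3 = v - 19.9
        axs = np.where(np.abs(n3) < 1e-10, 0.00068,
                       4e-5 * n3 / (1.0 - exp(-n3 / 17.0)))
        bxs = np.where(np.abs(n3) < 1e-10, 0.000315,
                       3.5e-5 * n3 / (exp(n3 / 9.0) - 1.0))
        tau_xs = 0.5 / (axs + bxs)
        xs_inf = 1.0 / np.sqrt(1.0 + exp(-n3 / 12.7))

        n4 = v + 10.0
        tau_d = np.where(np.abs(n4) < 1e-10, 4.579 / 1.4,
                         (1.0 - exp(-n4 / 6.24))
                         / (0.035 * n4 * (1.0 + exp(-n4 / 6.24))))
        d_inf = 1.0 / (1.0 + exp(-n4 / 8.0))
        tau_f = 9.0 / (0.0197 * exp(-(0.0337 ** 2) * n4 ** 2) + 0.02)
        f_inf = 1.0 / (1.0 + exp((v + 28.0) / 6.9))

        fca_inf = 1.0 / (1.0 + cai / 0.00035)
        tau_fca = np.full_like(np.asarray(v, dtype=float), TAU_FCA)

        # Ca-release activation flux (currents in pA: multiply by CM)
        fn = (1e-12 * VRELV * irel
              - (5e-13 / FARADAY) * (0.5 * ical - 0.2 * inaca) * CM)
        u_inf = 1.0 / (1.0 + exp(-(fn - 3.4175e-13) / 13.67e-16))
        tau_u = np.full_like(np.asarray(v, dtype=float), TAU_U)
        v_inf = 1.0 - 1.0 / (1.0 + exp(-(fn - 6.835e-14) / 13.67e-16))
        tau_v = 1.91 + 2.09 / (1.0 + exp(-(fn - 3.4175e-13) / 13.67e-16))
        n5 = v - 7.9
        tau_w = np.where(np.abs(n5) < 1e-10, 6.0 * 0.2 / 1.3,
                         6.0 * (1.0 - exp(-n5 / 5.0))
                         / ((1.0 + 0.3 * exp(-n5 / 5.0)) * n5))
        w_inf = 1.0 - 1.0 / (1.0 + exp(-(v - 40.0) / 17.0))

        gate_inf = np.asarray([m_inf, h_inf, j_inf, oa_inf, oi_inf, ua_inf,
                               ui_inf, xr_inf, xs_inf, d_inf, f_inf, fca_inf,
                               u_inf, v_inf, w_inf])
        gate_tau = np.asarray([tau_m, tau_h, tau_j, tau_oa, tau_oi, tau_ua,
                               tau_ui, tau_xr, tau_xs, tau_d, tau_f, tau_fca,
                               tau_u, tau_v, tau_w])

        # --- concentration balances ---------------------------------------
        dnai = (-3.0 * inak - 3.0 * inaca - ibna - ina) * CM / (FARADAY * VI)
        dki = (2.0 * inak - ik1 - ito - ikur - ikr - iks) * CM / (FARADAY * VI)
        b1 = ((2.0 * inaca - ipca - ical - ibca) * CM / (2.0 * FARADAY * VI)
              + (VUP * (iupleak - iup) + irel * VRELV) / VI)
        b2 = (1.0 + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2
              + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2)
        dcai = b1 / b2
        dcaup = iup - iupleak - itr * VRELV / VUP
        dcarel = (itr - irel) / (1.0 + CSQN_MAX * KM_CSQN
                                 / (carel + KM_CSQN) ** 2)

        ds = np.asarray([
            (m_inf - m) / tau_m, (h_inf - h) / tau_h, (j_inf - j) / tau_j,
            (oa_inf - oa) / tau_oa, (oi_inf - oi) / tau_oi,
            (ua_inf - ua) / tau_ua, (ui_inf - ui) / tau_ui,
            (xr_inf - xr) / tau_xr, (xs_inf - xs) / tau_xs,
            (d_inf - d) / tau_d, (f_inf - f) / tau_f,
            (fca_inf - fca) / tau_fca, (u_inf - u) / tau_u,
            (v_inf - vg) / tau_v, (w_inf - w) / tau_w,
            dnai, dki, dcai, dcaup, dcarel,
        ])
        return dv, ds, gate_inf, gate_tau
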