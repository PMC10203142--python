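"""Stewart et al. (2009) human Purkinje-fibre myocyte model.

A modification of the ten Tusscher–Panfilov ventricular model with a
hyperpolarization-activated "funny" current I_f (gate y), a sustained
outward current I_sus, a weakened time-independent rectifier I_K1 and
re-tuned transient-outward kinetics.  Twenty states.

Purkinje cells are auto-rhythmic: the model has no stable resting state
and depolarizes spontaneously (cycle length on the order of a second).
The registered ``rest_state`` is the quiescent *equilibrium* of the
right-hand side (Newton-polished); it is a genuine fixed point but an
unstable one, so trajectories started nearby eventually fire — that is
the physiology, not an integration artefact.
"""

from __future__ import annotations

import numpy as np

from .base import IonicModel, register_model
from .tentusscher import (BUFC, BUFSR, BUFSS, CAO, CAPACITANCE, EC, FARADAY,
                          GBCA, GBNA, GPCA, GPK, K1P, K2P, K3, K4, KBUFC,
                          KBUFSR, KBUFSS, KMCA, KMK, KMNA, KMNAI, KNACA,
                          KNAK, KO, KPCA, KSAT, KUP, MAXSR, MINSR, NAO,
                          NGAMMA, PKNA, RTONF, VC, VLEAK, VMAXUP, VREL, VSR,
                          VSS, VXFER)

__all__ = ["StewartPurkinje"]

GNA = 130.5744
GK1 = 0.065
GKR = 0.0918
GKS = 0.2352
GTO = 0.08184
GSUS = 0.0227
GFNA = 0.0145654
GFK = 0.0234346
GCAL = 3.980e-5

_STATE_NAMES = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f",
                "f2", "fcass", "y", "rr", "ca_i", "ca_sr", "ca_ss",
                "na_i", "k_i")
_GATES = tuple(range(13))  # m..y

# Quiescent equilibrium of the rhs (Newton-polished to residual < 1e-12
# per ms; an *unstable* fixed point, see module docstring).  The ionic
# pools at this mathematical equilibrium sit away from the paced
# physiological diastole — pacemaking cells never rest there.
_EQUILIBRIUM = dict(
    v=-69.10069153,
    s=(4.200988953e-02, 1.749962174e-01, 1.749962174e-01, 2.113610842e-03,
       3.127119125e-01, 1.016466789e-02, 1.054219997e-03, 9.622582055e-01,
       2.895888206e-04, 9.991019483e-01, 9.949057223e-01, 9.999465817e-01,
       1.556345490e-01, 9.901218580e-01, 4.265018523e-05, 5.008274733e-01,
       4.718010149e-04, 7.134947580e+00, 1.684954283e+02),
)

#: published paced initial conditions (mid-diastole of the spontaneous
#: cycle) — the natural starting point for beating-cell simulations
PACED_DIASTOLE = dict(
    v=-69.1370441635924,
    s=(0.0417391656294997, 0.190678733735145, 0.238219836154029,
       0.00550281999719088, 0.313213286437995, 0.00953708522974789,
       0.00103618091196912, 0.963861017995438, 0.000287906256206415,
       0.989328560287987, 0.995474890442185, 0.999955429598213,
       0.0457562667986602, 0.991580051907845, 0.000101878186157052,
       3.10836886659417, 0.000446818714055411, 8.80420286531673,
       136.781894160227),
)


@register_model
class StewartPurkinje(IonicModel):
    name = "stewart"
    aliases = ("purkinje",)
    state_names = _STATE_NAMES
    gate_idx = _GATES
    dt_default = 0.02
    activation_threshold = -40.0  # mV, upstroke detection level
    Cm = 0.01
    chi = 140.0

    rest_v = _EQUILIBRIUM["v"]
    rest_s = _EQUILIBRIUM["s"]
    #: the model self-depolarizes; no stable rest state exists
    auto_rhythmic = True

    def __init__(self):
        self.params = {}

    def rates(self, v, s, I_stim=0.0):
        (m, h, j, xr1, xr2, xs, r, sg, d, f, f2, fcass, y,
         rr, cai, casr, cass, nai, ki) = s
        exp = np.exp
        vfrt = v / RTONF

        ek = RTONF * np.log(KO / ki)
        ena = RTONF * np.log(NAO / nai)
        eks = RTONF * np.log((KO + PKNA * NAO) / (ki + PKNA * nai))
        eca = 0.5 * RTONF * np.log(CAO / cai)

        # Purkinje-specific currents
        xk1_inf = 1.0 / (1.0 + exp(0.1 * (v + 75.44)))
        ik1 = GK1 * xk1_inf * (v - 8.0 - ek)
        a_sus = 1.0 / (1.0 + exp((5.0 - v) / 17.0))
        isus = GSUS * a_sus * (v - ek)
        ifna = GFNA * y * (v - ena)
        ifk = GFK * y * (v - ek)

        ito = GTO * r * sg * (v - ek)
        ikr = GKR * np.sqrt(KO / 5.4) * xr1 * xr2 * (v - ek)
        iks = GKS * xs * xs * (v - eks)
        ina = GNA * m ** 3 * h * j * (v - ena)
        ibna = GBNA * (v - ena)
        e2 = exp(2.0 * (v - 15.0) / RTONF)
        ical = (GCAL * d * f * f2 * fcass * 4.0 * (v - 15.0)
                * (FARADAY / RTONF) * (0.25 * cass * e2 - CAO) / (e2 - 1.0))
        ibca = GBCA * (v - eca)
        en1 = exp(NGAMMA * vfrt)
        en2 = exp((NGAMMA - 1.0) * vfrt)
        inaca = (KNACA / ((KMNAI ** 3 + NAO ** 3) * (KMCA + CAO))
                 / (1.0 + KSAT * en2)
                 * (en1 * nai ** 3 * CAO - en2 * NAO ** 3 * cai * 2.5))
        inak = (KNAK * KO / (KO + KMK) * nai / (nai + KMNA)
                / (1.0 + 0.1245 * exp(-0.1 * vfrt) + 0.0353 * exp(-vfrt)))
        ipca = GPCA * cai / (KPCA + cai)
        ipk = GPK * (v - ek) / (1.0 + exp((25.0 - v) / 5.98))

        itot = (ik1 + ito + isus + ifna + ifk + ikr + iks + ical + inak
                + ina + ibna + inaca + ibca + ipk + ipca)
        dv = -itot + I_stim

        # --- gates: TP06 kinetics except r, s, y ---------------------------
        m_inf = 1.0 / (1.0 + exp((-56.86 - v) / 9.03)) ** 2
        tau_m = (1.0 / (1.0 + exp((-60.0 - v) / 5.0))
                 * (0.1 / (1.0 + exp((v + 35.0) / 5.0))
                    + 0.10 / (1.0 + exp((v - 50.0) / 200.0))))
        h_inf = 1.0 / (1.0 + exp((v + 71.55) / 7.43)) ** 2
        lo = v < -40.0
        ah = np.where(lo, 0.057 * exp(-(v + 80.0) / 6.8), 0.0)
        bh = np.where(lo,
                      2.7 * exp(0.079 * v) + 3.1e5 * exp(0.3485 * v),
                      0.77 / (0.13 * (1.0 + exp(-(v + 10.66) / 11.1))))
        tau_h = 1.0 / (ah + bh)
        j_inf = h_inf
        with np.errstate(over="ignore"):
            aj = np.where(lo,
                          (-2.5428e4 * exp(0.2444 * v)
                           - 6.948e-6 * exp(-0.04391 * v)) * (v + 37.78)
                          / (1.0 + exp(0.311 * (v + 79.23))), 0.0)
            bj = np.where(lo,
                          0.02424 * exp(-0.01052 * v)
                          / (1.0 + exp(-0.1378 * (v + 40.14))),
                          0.6 * exp(0.057 * v)
                          / (1.0 + exp(-0.1 * (v + 32.0))))
        tau_j = 1.0 / (aj + bj)

        xr1_inf = 1.0 / (1.0 + exp((-26.0 - v) / 7.0))
        tau_xr1 = (450.0 / (1.0 + exp((-45.0 - v) / 10.0))
                   * 6.0 / (1.0 + exp((v + 30.0) / 11.5)))
        xr2_inf = 1.0 / (1.0 + exp((v + 88.0) / 24.0))
        tau_xr2 = (3.0 / (1.0 + exp((-60.0 - v) / 20.0))
                   * 1.12 / (1.0 + exp((v - 60.0) / 20.0)))
        xs_inf = 1.0 / (1.0 + exp((-5.0 - v) / 14.0))
        tau_xs = (1400.0 / np.sqrt(1.0 + exp((5.0 - v) / 6.0))
                  / (1.0 + exp((v - 35.0) / 15.0))) + 80.0

        # Purkinje transient-outward kinetics
        r_inf = 1.0 / (1.0 + exp((20.0 - v) / 13.0))
        tau_r = 10.45 * exp(-(v + 40.0) ** 2 / 1800.0) + 7.3
        s_inf = 1.0 / (1.0 + exp((v + 27.0) / 13.0))
        tau_s = (85.0 * exp(-(v + 25.0) ** 2 / 320.0)
                 + 5.0 / (1.0 + exp((v - 40.0) / 5.0)) + 42.0)

        d_inf = 1.0 / (1.0 + exp((-8.0 - v) / 7.5))
        tau_d = ((1.4 / (1.0 + exp((-35.0 - v) / 13.0)) + 0.25)
                 * 1.4 / (1.0 + exp((v + 5.0) / 5.0))
                 + 1.0 / (1.0 + exp((50.0 - v) / 20.0)))
        f_inf = 1.0 / (1.0 + exp((v + 20.0) / 7.0))
        tau_f = (1102.5 * exp(-(v + 27.0) ** 2 / 225.0)
                 + 200.0 / (1.0 + exp((13.0 - v) / 10.0))
                 + 180.0 / (1.0 + exp((v + 30.0) / 10.0)) + 20.0)
        f2_inf = 0.67 / (1.0 + exp((v + 35.0) / 7.0)) + 0.33
        tau_f2 = (562.0 * exp(-(v + 27.0) ** 2 / 240.0)
                  + 31.0 / (1.0 + exp((25.0 - v) / 10.0))
                  + 80.0 / (1.0 + exp((v + 30.0) / 10.0)))
        fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
        tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

        # funny-current activation
        y_inf = 1.0 / (1.0 + exp((v + 80.6) / 6.8))
        ay = exp(-2.9 - 0.04 * v)
        by = exp(3.6 + 0.11 * v)
        tau_y = 4000.0 / (ay + by)

        gate_inf = np.asarray([m_inf, h_inf, j_inf, xr1_inf, xr2_inf, xs_inf,
                               r_inf, s_inf, d_inf, f_inf, f2_inf, fcass_inf,
                               y_inf])
        gate_tau = np.asarray([tau_m, tau_h, tau_j, tau_xr1, tau_xr2, tau_xs,
                               tau_r, tau_s, tau_d, tau_f, tau_f2, tau_fcass,
                               tau_y])

        # --- calcium dynamics (as TP06) ------------------------------------
        kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / casr) ** 2)
        k1 = K1P / kcasr
        k2 = K2P * kcasr
        drr = K4 * (1.0 - rr) - k2 * cass * rr
        o_rel = k1 * cass ** 2 * rr / (K3 + k1 * cass ** 2)
        irel = VREL * o_rel * (casr - cass)
        ileak = VLEAK * (casr - cai)
        iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
        ixfer = VXFER * (cass - cai)

        csqn = 1.0 / (1.0 + BUFSR * KBUFSR / (casr + KBUFSR) ** 2)
        dcasr = csqn * (iup - irel - ileak)
        bss = 1.0 / (1.0 + BUFSS * KBUFSS / (cass + KBUFSS) ** 2)
        dcass = bss * (-ixfer * (VC / VSS) + irel * (VSR / VSS)
                       + (-ical * CAPACITANCE / (2.0 * VSS * FARADAY)))
        bcai = 1.0 / (1.0 + BUFC * KBUFC / (cai + KBUFC) ** 2)
        dcai = bcai * ((-(ibca + ipca - 2.0 * inaca)
                        * CAPACITANCE / (2.0 * VC * FARADAY))
                       - (iup - ileak) * (VSR / VC) + ixfer)
        dnai = -(ina + ibna + ifna + 3.0 * inak + 3.0 * inaca) \
            * CAPACITANCE / (VC * FARADAY)
        dki = -(ik1 + ito + isus + ifk + ikr + iks - 2.0 * inak + ipk) \
            * CAPACITANCE / (VC * FARADAY)

        ds = np.asarray([
            (m_inf - m) / tau_m, (h_inf - h) / tau_h, (j_inf - j) / tau_j,
            (xr1_inf - xr1) / tau_xr1, (xr2_inf - xr2) / tau_xr2,
            (xs_inf - xs) / tau_xs, (r_inf - r) / tau_r,
            (s_inf - sg) / tau_s, (d_inf - d) / tau_d,
            (f_inf - f) / tau_f, (f2_inf - f2) / tau_f2,
            (fcass_inf - fcass) / tau_fcass, (y_inf - y) / tau_y,
            drr, dcai, dcasr, dcass, dnai, dki,
        ])
        return dv, ds, gate_inf, gate_tau
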