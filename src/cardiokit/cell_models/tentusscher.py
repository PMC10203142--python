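"""ten Tusscher–Panfilov (2006) human ventricular myocyte model.

Nineteen state variables: transmembrane potential, twelve Hodgkin–Huxley
gates, the calcium-release recovery variable R', and five concentrations
(Ca_i, Ca_SR, Ca_ss, Na_i, K_i).  The epicardial parameter set is the
default; ``celltype`` selects ``"epi"``, ``"endo"`` or ``"mcell"`` which
differ in the transient-outward (G_to) and slow-delayed-rectifier (G_Ks)
conductances and in the kinetics of the s gate.

Potentials in mV, time in ms, concentrations in mM, currents in pA/pF.
The published initial conditions are near — but not exactly at — the
quiescent equilibrium; the registered rest state has been Newton-polished
on the model's own right-hand side so that it is a fixed point to high
accuracy (see ``rest_s`` below).
"""

from __future__ import annotations

import numpy as np

from .base import IonicModel, register_model

__all__ = ["TenTusscherPanfilov"]

# physical constants (mJ/(mol K), K, C/mol)
R_GAS = 8314.472
TEMP = 310.0
FARADAY = 96485.3415
RTONF = R_GAS * TEMP / FARADAY

# extracellular concentrations, mM
KO, CAO, NAO = 5.4, 2.0, 140.0
# volumes (uL) and capacitance (uF) of the model cell
VC, VSR, VSS = 0.016404, 0.001094, 0.00005468
CAPACITANCE = 0.185
# buffering
BUFC, KBUFC = 0.2, 0.001
BUFSR, KBUFSR = 10.0, 0.3
BUFSS, KBUFSS = 0.4, 0.00025
# SR fluxes
VMAXUP, KUP = 0.006375, 0.00025
VREL, VLEAK, VXFER = 0.102, 0.00036, 0.0038
K1P, K2P, K3, K4 = 0.15, 0.045, 0.060, 0.005
EC, MAXSR, MINSR = 1.5, 2.5, 1.0
# fixed conductances / permeabilities
PKNA = 0.03
GK1 = 5.405
GKR = 0.153
GNA = 14.838
GBNA = 0.00029
KMK, KMNA, KNAK = 1.0, 40.0, 2.724
GCAL = 3.980e-5
GBCA = 0.000592
KNACA, KMNAI, KMCA, KSAT, NGAMMA = 1000.0, 87.5, 1.38, 0.1, 0.35
GPCA, KPCA = 0.1238, 0.0005
GPK = 0.0146

_CELLTYPE = {
    # Gks, Gto
    "epi": (0.392, 0.294),
    "endo": (0.392, 0.073),
    "mcell": (0.098, 0.294),
}

_STATE_NAMES = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f",
                "f2", "fcass", "rr", "ca_i", "ca_sr", "ca_ss", "na_i", "k_i")
_GATES = tuple(range(12))  # m..fcass are Rush-Larsen gates

# Quiescent equilibrium (epi): the published initial conditions relaxed to
# steady state on this module's own rhs (stiff integration, rtol 1e-9);
# residual |d/dt| < 1e-7 per ms.  The unpaced equilibrium sits slightly
# below the published paced diastolic state and carries a depleted SR.
_REST_EPI = dict(
    v=-86.90025600,
    s=(1.20172600e-03, 7.87749810e-01, 7.87749808e-01, 1.66551975e-04,
       4.88546338e-01, 2.87157681e-03, 1.82936952e-08, 9.99998454e-01,
       2.69895412e-05, 9.99929313e-01, 9.99596527e-01, 9.99998664e-01,
       9.98339732e-01, 2.59672754e-05, 1.89048693e-01, 7.46123554e-05,
       3.41884519e+00, 1.43287707e+02),
)


@register_model
class TenTusscherPanfilov(IonicModel):
    name = "tentusscher_panfilov"
    aliases = ("tp06", "ventricular")
    state_names = _STATE_NAMES
    gate_idx = _GATES
    dt_default = 0.02
    activation_threshold = -40.0  # mV, upstroke detection level
    Cm = 0.01    # uF/mm^2 (1 uF/cm^2, conventional)
    chi = 140.0  # 1/mm

    rest_v = _REST_EPI["v"]
    rest_s = _REST_EPI["s"]

    def __init__(self, celltype: str = "epi", **overrides):
        if celltype not in _CELLTYPE:
            raise ValueError(f"celltype must be one of {sorted(_CELLTYPE)}")
        self.celltype = celltype
        self.Gks, self.Gto = _CELLTYPE[celltype]
        self.params = dict(celltype=celltype, Gks=self.Gks, Gto=self.Gto)
        for k, val in overrides.items():
            if not hasattr(self, k):
                raise KeyError(f"unknown parameter {k!r}")
            setattr(self, k, float(val))
            self.params[k] = float(val)
        if celltype != "epi":
            # published initial conditions; polished only for epi
            self.rest_v = -86.2
            self.rest_s = (0.0, 0.75, 0.75, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0,
                           1.0, 1.0, 1.0, 1.0, 0.00007, 1.3, 0.00007, 7.67,
                           138.3)

    # ------------------------------------------------------------------
    def rates(self, v, s, I_stim=0.0):
        (m, h, j, xr1, xr2, xs, r, sg, d, f, f2, fcass,
         rr, cai, casr, cass, nai, ki) = s

        exp = np.exp
        vfrt = v / RTONF

        ek = RTONF * np.log(KO / ki)
        ena = RTONF * np.log(NAO / nai)
        eks = RTONF * np.log((KO + PKNA * NAO) / (ki + PKNA * nai))
        eca = 0.5 * RTONF * np.log(CAO / cai)

        # inward rectifier
        ak1 = 0.1 / (1.0 + exp(0.06 * (v - ek - 200.0)))
        bk1 = (3.0 * exp(0.0002 * (v - ek + 100.0))
               + exp(0.1 * (v - ek - 10.0))) / (1.0 + exp(-0.5 * (v - ek)))
        ik1 = GK1 * np.sqrt(KO / 5.4) * ak1 / (ak1 + bk1) * (v - ek)

        ito = self.Gto * r * sg * (v - ek)
        ikr = GKR * np.sqrt(KO / 5.4) * xr1 * xr2 * (v - ek)
        iks = self.Gks * xs * xs * (v - eks)
        ina = GNA * m ** 3 * h * j * (v - ena)
        ibna = GBNA * (v - ena)

        # L-type calcium (GHK-like driving term, centred at +15 mV)
        e2 = exp(2.0 * (v - 15.0) / RTONF)
        ical = (GCAL * d * f * f2 * fcass * 4.0 * (v - 15.0)
                * (FARADAY / RTONF) * (0.25 * cass * e2 - CAO) / (e2 - 1.0))

        ibca = GBCA * (v - eca)
        # Na/Ca exchanger
        en1 = exp(NGAMMA * vfrt)
        en2 = exp((NGAMMA - 1.0) * vfrt)
        inaca = (KNACA / ((KMNAI ** 3 + NAO ** 3) * (KMCA + CAO))
                 / (1.0 + KSAT * en2)
                 * (en1 * nai ** 3 * CAO - en2 * NAO ** 3 * cai * 2.5))
        # Na/K pump
        inak = (KNAK * KO / (KO + KMK) * nai / (nai + KMNA)
                / (1.0 + 0.1245 * exp(-0.1 * vfrt) + 0.0353 * exp(-vfrt)))
        ipca = GPCA * cai / (KPCA + cai)
        ipk = GPK * (v - ek) / (1.0 + exp((25.0 - v) / 5.98))

        itot = ik1 + ito + ikr + iks + ical + inak + ina + ibna + inaca \
            + ibca + ipk + ipca
        dv = -itot + I_stim

        # --- gate kinetics -------------------------------------------------
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

        r_inf = 1.0 / (1.0 + exp((20.0 - v) / 6.0))
        tau_r = 9.5 * exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
        if self.celltype == "endo":
            s_inf = 1.0 / (1.0 + exp((v + 28.0) / 5.0))
            tau_s = (1000.0 * exp(-(v + 67.0) ** 2 / 1000.0) + 8.0)
        else:
            s_inf = 1.0 / (1.0 + exp((v + 20.0) / 5.0))
            tau_s = (85.0 * exp(-(v + 45.0) ** 2 / 320.0)
                     + 5.0 / (1.0 + exp((v - 20.0) / 5.0)) + 3.0)

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

        gate_inf = np.asarray([m_inf, h_inf, j_inf, xr1_inf, xr2_inf, xs_inf,
                               r_inf, s_inf, d_inf, f_inf, f2_inf, fcass_inf])
        gate_tau = np.asarray([tau_m, tau_h, tau_j, tau_xr1, tau_xr2, tau_xs,
                               tau_r, tau_s, tau_d, tau_f, tau_f2, tau_fcass])

        # --- calcium dynamics ---------------------------------------------
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
        dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) \
            * CAPACITANCE / (VC * FARADAY)
        dki = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk) \
            * CAPACITANCE / (VC * FARADAY)

        ds = np.asarray([
            (m_inf - m) / tau_m, (h_inf - h) / tau_h, (j_inf - j) / tau_j,
            (xr1_inf - xr1) / tau_xr1, (xr2_inf - xr2) / tau_xr2,
            (xs_inf - xs) / tau_xs, (r_inf - r) / tau_r,
            (s_inf - sg) / tau_s, (d_inf - d) / tau_d,
            (f_inf - f) / tau_f, (f2_inf - f2) / tau_f2,
            (fcass_inf - fcass) / tau_fcass,
            drr, dcai, dcasr, dcass, dnai, dki,
        ])
        return dv, ds, gate_inf, gate_tau
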