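"""Adult human ventricular myocyte model (O'Hara--Rudy 2011 lineage).

Full dynamic model: fast and late Na current with CaMK-phosphorylated
fractions, transient outward K current, L-type Ca current with Ca-dependent
inactivation and subspace Ca handling, IKr/IKs/IK1, Na/Ca exchange in bulk
and subspace compartments, Na/K pump, background and pump Ca currents, SR
release/uptake/translocation, and intracellular Na/K/Ca accumulation with
buffering.  The engineered BacNav channel is added as two extra gating
states carrying an ohmic Na-selective current (see
:mod:`bacnavsim.channel`); its Na flux is included in the intracellular Na
balance.

State is stored column-wise, shape ``(N_STATE, n_nodes)``, so the same
kernel serves single cells (n=1), 1D cables, and 2D tissue.  Hodgkin--Huxley
gates advance by exact exponential (Rush--Larsen) relaxation; concentrations
and the membrane potential by forward Euler.

Parameters are absolute maximal conductances/permeabilities per node; the
defaults reproduce the published endocardial cell.  ``celltype`` selects
endo (0), epi (1) or mid (2) scalings.
"""

import math

import numpy as np
from numba import njit

from ._kernels import bac_hinf, bac_minf, bac_tauh, bac_taum, eg

NAME = "human"

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
    "m_bac", "h_bac",
)
N_STATE = len(STATE_NAMES)

CURRENT_NAMES = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "INab", "IKb", "IpCa", "ICab", "IBacNav",
)
N_CURRENT = len(CURRENT_NAMES)

# parameter vector layout (absolute values; scale via build_cell modifiers)
PARAM_NAMES = (
    "g_Na", "g_NaL", "g_to", "P_Ca", "g_Kr", "g_Ks", "g_K1",
    "g_ncx", "P_nak", "h_speed", "bacnav_g", "bacnav_erev", "celltype",
)
N_PARAM = len(PARAM_NAMES)

#: Published endocardial maxima.  bacnav_erev = nan means "use the Na
#: Nernst potential computed from the instantaneous nai".
DEFAULT_PARAMS = np.array(
    [75.0, 0.0075, 0.02, 0.0001, 0.046, 0.0034, 0.1908,
     0.0008, 30.0, 1.0, 0.0, np.nan, 0.0]
)

DEFAULT_RATE_HZ = 1.0
DEFAULT_STIM = (80.0, 1.0)  # amplitude (uA/uF, depolarizing), duration (ms)

# extracellular milieu (mM) and physical constants
NAO, CAO, KO = 140.0, 1.8, 5.4
R_GAS, TEMP, FARADAY = 8314.0, 310.0, 96485.0

# cell geometry (cm); capacitive area doubles the geometric area
_L, _RAD = 0.01, 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL


def initial_state(n=1):
    """Published resting initial conditions tiled over ``n`` nodes."""
    s = np.zeros((N_STATE, n))
    init = {
        "v": -87.0, "nai": 7.0, "nass": 7.0, "ki": 145.0, "kss": 145.0,
        "cai": 1.0e-4, "cass": 1.0e-4, "cansr": 1.2, "cajsr": 1.2,
        "m": 0.0, "hf": 1.0, "hs": 1.0, "j": 1.0, "hsp": 1.0, "jp": 1.0,
        "mL": 0.0, "hL": 1.0, "hLp": 1.0,
        "a": 0.0, "iF": 1.0, "iS": 1.0, "ap": 0.0, "iFp": 1.0, "iSp": 1.0,
        "d": 0.0, "ff": 1.0, "fs": 1.0, "fcaf": 1.0, "fcas": 1.0,
        "jca": 1.0, "nca": 0.0, "ffp": 1.0, "fcafp": 1.0,
        "xrf": 0.0, "xrs": 0.0, "xs1": 0.0, "xs2": 0.0, "xk1": 1.0,
        "Jrelnp": 0.0, "Jrelp": 0.0, "CaMKt": 0.0,
    }
    for name, val in init.items():
        s[STATE_NAMES.index(name)] = val
    v0 = init["v"]
    s[STATE_NAMES.index("m_bac")] = 1.0 / (1.0 + math.exp((-22.5 - v0) / 2.704))
    s[STATE_NAMES.index("h_bac")] = 1.0 / (1.0 + math.exp((v0 + 77.05) / 10.64))
    return s


@njit(cache=True)
def step(S, P, dt, istim, clamped, IOUT):
    """Advance all nodes by one time step of ``dt`` ms.

    ``S``: (N_STATE, n) state; ``P``: (N_PARAM, n) parameters;
    ``istim``: (n,) depolarizing stimulus (uA/uF); ``clamped``: (n,) bool,
    nodes whose Vm is externally prescribed (voltage clamp / obstacle);
    ``IOUT``: (N_CURRENT, n) output array of the instantaneous currents.
    Returns the (n,) total ionic current (uA/uF, outward positive).
    With ``dt == 0`` the state is untouched and only currents are written.
    """
    n = S.shape[1]
    itot_out = np.empty(n)
    rtf = R_GAS * TEMP / FARADAY
    frt = 1.0 / rtf

    for i in range(n):
        v = S[0, i]
        nai = S[1, i]; nass = S[2, i]; ki = S[3, i]; kss = S[4, i]
        cai = S[5, i]; cass = S[6, i]; cansr = S[7, i]; cajsr = S[8, i]
        m = S[9, i]; hf = S[10, i]; hs = S[11, i]; j = S[12, i]
        hsp = S[13, i]; jp = S[14, i]
        mL = S[15, i]; hL = S[16, i]; hLp = S[17, i]
        a = S[18, i]; iF = S[19, i]; iS = S[20, i]
        ap = S[21, i]; iFp = S[22, i]; iSp = S[23, i]
        d = S[24, i]; ff = S[25, i]; fs = S[26, i]
        fcaf = S[27, i]; fcas = S[28, i]; jca = S[29, i]; nca = S[30, i]
        ffp = S[31, i]; fcafp = S[32, i]
        xrf = S[33, i]; xrs = S[34, i]; xs1 = S[35, i]; xs2 = S[36, i]
        xk1 = S[37, i]; Jrelnp = S[38, i]; Jrelp = S[39, i]; CaMKt = S[40, i]
        mb = S[41, i]; hb = S[42, i]

        gna = P[0, i]; gnal = P[1, i]; gto = P[2, i]; pca = P[3, i]
        gkr = P[4, i]; gks = P[5, i]; gk1 = P[6, i]
        gncx = P[7, i]; pnak = P[8, i]; hspeed = P[9, i]
        gbac = P[10, i]; erev_bac = P[11, i]
        celltype = int(P[12, i])

        if celltype == 1:  # epi
            gnal *= 0.6; gto *= 4.0; pca *= 1.2; gkr *= 1.3; gks *= 1.4
            gk1 *= 1.2; gncx *= 1.1; pnak *= 0.9
        elif celltype == 2:  # mid
            gto *= 4.0; pca *= 2.5; gkr *= 0.8; gk1 *= 1.3
            gncx *= 1.4; pnak *= 0.7

        ena = rtf * math.log(NAO / nai)
        ek = rtf * math.log(KO / ki)
        eks = rtf * math.log((KO + 0.01833 * NAO) / (ki + 0.01833 * nai))

        # CaMK
        KmCaMK = 0.15
        CaMKb = 0.05 * (1.0 - CaMKt) / (1.0 + 0.0015 / cass)
        CaMKa = CaMKb + CaMKt
        fp = 1.0 / (1.0 + KmCaMK / CaMKa)  # phosphorylated fraction

        # --- INa (fast) ---
        mss = 1.0 / (1.0 + eg(-(v + 39.57) / 9.871))
        tm = 1.0 / (6.765 * eg((v + 11.64) / 34.77)
                    + 8.552 * eg(-(v + 77.42) / 5.955))
        hss = 1.0 / (1.0 + eg((v + 82.90) / 6.086))
        thf = 1.0 / (1.432e-5 * eg(-(v + 1.196) / 6.285)
                     + 6.149 * eg((v + 0.5096) / 20.27))
        ths = 1.0 / (0.009794 * eg(-(v + 17.95) / 28.05)
                     + 0.3343 * eg((v + 5.730) / 56.66))
        thf /= hspeed
        ths /= hspeed
        jss = hss
        tj = 2.038 + 1.0 / (0.02136 * eg(-(v + 100.6) / 8.281)
                            + 0.3052 * eg((v + 0.9941) / 38.45))
        hssp = 1.0 / (1.0 + eg((v + 89.1) / 6.086))
        thsp = 3.0 * ths
        tjp = 1.46 * tj
        h_ = 0.99 * hf + 0.01 * hs
        hp_ = 0.99 * hf + 0.01 * hsp
        INa = gna * (v - ena) * m * m * m * (
            (1.0 - fp) * h_ * j + fp * hp_ * jp)

        # --- INaL ---
        mLss = 1.0 / (1.0 + eg(-(v + 42.85) / 5.264))
        tmL = tm
        hLss = 1.0 / (1.0 + eg((v + 87.61) / 7.488))
        thL = 200.0
        hLssp = 1.0 / (1.0 + eg((v + 93.81) / 7.488))
        thLp = 3.0 * thL
        INaL = gnal * (v - ena) * mL * ((1.0 - fp) * hL + fp * hLp)

        # --- Ito ---
        ass = 1.0 / (1.0 + eg(-(v - 14.34) / 14.82))
        ta = 1.0515 / (1.0 / (1.2089 * (1.0 + eg(-(v - 18.4099) / 29.3814)))
                       + 3.5 / (1.0 + eg((v + 100.0) / 29.3814)))
        iss = 1.0 / (1.0 + eg((v + 43.94) / 5.711))
        if celltype == 1:
            delta_epi = 1.0 - 0.95 / (1.0 + eg((v + 70.0) / 5.0))
        else:
            delta_epi = 1.0
        tiF = 4.562 + 1.0 / (0.3933 * eg(-(v + 100.0) / 100.0)
                             + 0.08004 * eg((v + 50.0) / 16.59))
        tiS = 23.62 + 1.0 / (0.001416 * eg(-(v + 96.52) / 59.05)
                             + 1.780e-8 * eg((v + 114.1) / 8.079))
        tiF *= delta_epi
        tiS *= delta_epi
        AiF = 1.0 / (1.0 + eg((v - 213.6) / 151.2))
        AiS = 1.0 - AiF
        i_ = AiF * iF + AiS * iS
        assp = 1.0 / (1.0 + eg(-(v - 24.34) / 14.82))
        dti_dev = 1.354 + 1.0e-4 / (eg((v - 167.4) / 15.89)
                                    + eg(-(v - 12.23) / 0.2154))
        dti_rec = 1.0 - 0.5 / (1.0 + eg((v + 70.0) / 20.0))
        tiFp = dti_dev * dti_rec * tiF
        tiSp = dti_dev * dti_rec * tiS
        ip_ = AiF * iFp + AiS * iSp
        Ito = gto * (v - ek) * ((1.0 - fp) * a * i_ + fp * ap * ip_)

        # --- ICaL / ICaNa / ICaK ---
        vv = v if abs(v) > 1.0e-7 else 1.0e-7
        vfrt = vv * frt
        vffrt = vv * FARADAY * frt
        dss = 1.0 / (1.0 + eg(-(v + 3.940) / 4.230))
        td = 0.6 + 1.0 / (eg(-0.05 * (v + 6.0)) + eg(0.09 * (v + 14.0)))
        fss = 1.0 / (1.0 + eg((v + 19.58) / 3.696))
        tff = 7.0 + 1.0 / (0.0045 * eg(-(v + 20.0) / 10.0)
                           + 0.0045 * eg((v + 20.0) / 10.0))
        tfs = 1000.0 + 1.0 / (0.000035 * eg(-(v + 5.0) / 4.0)
                              + 0.000035 * eg((v + 5.0) / 6.0))
        f_ = 0.6 * ff + 0.4 * fs
        fcass = fss
        tfcaf = 7.0 + 1.0 / (0.04 * eg(-(v - 4.0) / 7.0)
                             + 0.04 * eg((v - 4.0) / 7.0))
        tfcas = 100.0 + 1.0 / (0.00012 * eg(-v / 3.0) + 0.00012 * eg(v / 7.0))
        Afcaf = 0.3 + 0.6 / (1.0 + eg((v - 10.0) / 10.0))
        Afcas = 1.0 - Afcaf
        fca_ = Afcaf * fcaf + Afcas * fcas
        tjca = 75.0
        tffp = 2.5 * tff
        fp_ = 0.6 * ffp + 0.4 * fs
        tfcafp = 2.5 * tfcaf
        fcap_ = Afcaf * fcafp + Afcas * fcas
        km2n = jca * 1.0
        anca = 1.0 / (1000.0 / km2n + (1.0 + 0.002 / cass) ** 4)
        e2v = eg(2.0 * vfrt)
        e1v = eg(vfrt)
        PhiCaL = 4.0 * vffrt * (cass * e2v - 0.341 * CAO) / (e2v - 1.0)
        PhiCaNa = vffrt * (0.75 * nass * e1v - 0.75 * NAO) / (e1v - 1.0)
        PhiCaK = vffrt * (0.75 * kss * e1v - 0.75 * KO) / (e1v - 1.0)
        pcap = 1.1 * pca
        pcana = 0.00125 * pca
        pcak = 3.574e-4 * pca
        pcanap = 0.00125 * pcap
        pcakp = 3.574e-4 * pcap
        g_np = d * (f_ * (1.0 - nca) + jca * fca_ * nca)
        g_p = d * (fp_ * (1.0 - nca) + jca * fcap_ * nca)
        ICaL = (1.0 - fp) * pca * PhiCaL * g_np + fp * pcap * PhiCaL * g_p
        ICaNa = (1.0 - fp) * pcana * PhiCaNa * g_np + fp * pcanap * PhiCaNa * g_p
        ICaK = (1.0 - fp) * pcak * PhiCaK * g_np + fp * pcakp * PhiCaK * g_p

        # --- IKr ---
        xrss = 1.0 / (1.0 + eg(-(v + 8.337) / 6.789))
        txrf = 12.98 + 1.0 / (0.3652 * eg((v - 31.66) / 3.869)
                              + 4.123e-5 * eg(-(v - 47.78) / 20.38))
        txrs = 1.865 + 1.0 / (0.06629 * eg((v - 34.70) / 7.355)
                              + 1.128e-5 * eg(-(v - 29.74) / 25.94))
        Axrf = 1.0 / (1.0 + eg((v + 54.81) / 38.21))
        Axrs = 1.0 - Axrf
        xr = Axrf * xrf + Axrs * xrs
        rkr = 1.0 / (1.0 + eg((v + 55.0) / 75.0)) \
            * 1.0 / (1.0 + eg((v - 10.0) / 30.0))
        IKr = gkr * math.sqrt(KO / 5.4) * xr * rkr * (v - ek)

        # --- IKs ---
        xs1ss = 1.0 / (1.0 + eg(-(v + 11.60) / 8.932))
        txs1 = 817.3 + 1.0 / (2.326e-4 * eg((v + 48.28) / 17.80)
                              + 0.001292 * eg(-(v + 210.0) / 230.0))
        xs2ss = xs1ss
        txs2 = 1.0 / (0.01 * eg((v - 50.0) / 20.0)
                      + 0.0193 * eg(-(v + 66.54) / 31.0))
        KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
        IKs = gks * KsCa * xs1 * xs2 * (v - eks)

        # --- IK1 ---
        xk1ss = 1.0 / (1.0 + eg(-(v + 2.5538 * KO + 144.59)
                                / (1.5692 * KO + 3.8115)))
        txk1 = 122.2 / (eg(-(v + 127.2) / 20.36) + eg((v + 236.8) / 69.33))
        rk1 = 1.0 / (1.0 + eg((v + 105.8 - 2.6 * KO) / 9.493))
        IK1 = gk1 * math.sqrt(KO) * rk1 * xk1 * (v - ek)

        # --- INaCa (bulk and subspace) ---
        kna1 = 15.0; kna2 = 5.0; kna3 = 88.12; kasymm = 12.5
        wna = 6.0e4; wca = 6.0e4; wnaca = 5.0e3
        kcaon = 1.5e6; kcaoff = 5.0e3
        hca = eg(0.167 * v * frt)
        hna = eg(0.5224 * v * frt)
        # bulk
        h1 = 1.0 + nai / kna3 * (1.0 + hna)
        h2 = (nai * hna) / (kna3 * h1)
        h3 = 1.0 / h1
        h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
        h5 = nai * nai / (h4 * kna1 * kna2)
        h6 = 1.0 / h4
        h7 = 1.0 + NAO / kna3 * (1.0 + 1.0 / hna)
        h8 = NAO / (kna3 * hna * h7)
        h9 = 1.0 / h7
        h10 = kasymm + 1.0 + NAO / kna1 * (1.0 + NAO / kna2)
        h11 = NAO * NAO / (h10 * kna1 * kna2)
        h12 = 1.0 / h10
        k1 = h12 * CAO * kcaon
        k2 = kcaoff
        k3p = h9 * wca
        k3pp = h8 * wnaca
        k3 = k3p + k3pp
        k4p = h3 * wca / hca
        k4pp = h2 * wnaca
        k4 = k4p + k4pp
        k5 = kcaoff
        k6 = h6 * cai * kcaon
        k7 = h5 * h2 * wna
        k8 = h8 * h11 * wna
        x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
        x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
        x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
        x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
        sx = x1 + x2 + x3 + x4
        E1 = x1 / sx; E2 = x2 / sx; E3 = x3 / sx; E4 = x4 / sx
        allo = 1.0 / (1.0 + (150.0e-6 / cai) ** 2)
        JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
        JncxCa = E2 * k2 - E1 * k1
        INaCa_i = 0.8 * gncx * allo * (JncxNa + 2.0 * JncxCa)
        # subspace
        h1 = 1.0 + nass / kna3 * (1.0 + hna)
        h2 = (nass * hna) / (kna3 * h1)
        h3 = 1.0 / h1
        h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
        h5 = nass * nass / (h4 * kna1 * kna2)
        h6 = 1.0 / h4
        k4p = h3 * wca / hca
        k4pp = h2 * wnaca
        k4 = k4p + k4pp
        k6 = h6 * cass * kcaon
        k7 = h5 * h2 * wna
        x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
        x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
        x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
        x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
        sx = x1 + x2 + x3 + x4
        E1 = x1 / sx; E2 = x2 / sx; E3 = x3 / sx; E4 = x4 / sx
        allo_ss = 1.0 / (1.0 + (150.0e-6 / cass) ** 2)
        JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
        JncxCa = E2 * k2 - E1 * k1
        INaCa_ss = 0.2 * gncx * allo_ss * (JncxNa + 2.0 * JncxCa)

        # --- INaK ---
        k1p = 949.5; k1m = 182.4; k2p = 687.2; k2m = 39.4
        k3pk = 1899.0; k3m = 79300.0; k4pk = 639.0; k4m = 40.0
        Knai0 = 9.073; Knao0 = 27.78; delta = -0.1550
        Kki = 0.5; Kko = 0.3582
        MgADP = 0.05; MgATP = 9.8; Kmgatp = 1.698e-7
        H = 1.0e-7; eP = 4.2; Khp = 1.698e-7; Knap = 224.0; Kxkur = 292.0
        Knai = Knai0 * eg(delta * v * frt / 3.0)
        Knao = Knao0 * eg((1.0 - delta) * v * frt / 3.0)
        Pfrac = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
        a1 = (k1p * (nai / Knai) ** 3) / (
            (1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
        b1 = k1m * MgADP
        a2 = k2p
        b2 = (k2m * (NAO / Knao) ** 3) / (
            (1.0 + NAO / Knao) ** 3 + (1.0 + KO / Kko) ** 2 - 1.0)
        a3 = (k3pk * (KO / Kko) ** 2) / (
            (1.0 + NAO / Knao) ** 3 + (1.0 + KO / Kko) ** 2 - 1.0)
        b3 = (k3m * Pfrac * H) / (1.0 + MgATP / Kmgatp)
        a4 = (k4pk * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
        b4 = (k4m * (ki / Kki) ** 2) / (
            (1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
        x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
        x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
        x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
        x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
        sx = x1 + x2 + x3 + x4
        E1 = x1 / sx; E2 = x2 / sx; E3 = x3 / sx; E4 = x4 / sx
        JnakNa = 3.0 * (E1 * a3 - E2 * b3)
        JnakK = 2.0 * (E4 * b1 - E3 * a1)
        INaK = pnak * (JnakNa + JnakK)

        # --- minor currents ---
        xkb = 1.0 / (1.0 + eg(-(v - 14.48) / 18.34))
        IKb = 0.003 * xkb * (v - ek)
        INab = 3.75e-10 * vffrt * (nai * e1v - NAO) / (e1v - 1.0)
        ICab = 2.5e-8 * 4.0 * vffrt * (cai * e2v - 0.341 * CAO) / (e2v - 1.0)
        IpCa = 0.0005 * cai / (0.0005 + cai)

        # --- BacNav ---
        if math.isnan(erev_bac):
            ebac = ena
        else:
            ebac = erev_bac
        IBac = gbac * mb * hb * hb * (v - ebac)

        itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
                + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + IBac)

        IOUT[0, i] = INa; IOUT[1, i] = INaL; IOUT[2, i] = Ito
        IOUT[3, i] = ICaL; IOUT[4, i] = ICaNa; IOUT[5, i] = ICaK
        IOUT[6, i] = IKr; IOUT[7, i] = IKs; IOUT[8, i] = IK1
        IOUT[9, i] = INaCa_i; IOUT[10, i] = INaCa_ss; IOUT[11, i] = INaK
        IOUT[12, i] = INab; IOUT[13, i] = IKb; IOUT[14, i] = IpCa
        IOUT[15, i] = ICab; IOUT[16, i] = IBac
        itot_out[i] = itot

        if dt == 0.0:
            continue

        # --- SR fluxes (use the currents just computed) ---
        bt = 4.75
        a_rel = 0.5 * bt
        Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
        if celltype == 2:
            Jrel_inf *= 1.7
        tau_rel = bt / (1.0 + 0.0123 / cajsr)
        if tau_rel < 0.001:
            tau_rel = 0.001
        btp = 1.25 * bt
        a_relp = 0.5 * btp
        Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
        if celltype == 2:
            Jrel_infp *= 1.7
        tau_relp = btp / (1.0 + 0.0123 / cajsr)
        if tau_relp < 0.001:
            tau_relp = 0.001
        Jrel = (1.0 - fp) * Jrelnp + fp * Jrelp

        Jupnp = 0.004375 * cai / (cai + 0.00092)
        Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
        if celltype == 1:
            Jupnp *= 1.3
            Jupp *= 1.3
        Jleak = 0.0039375 * cansr / 15.0
        Jup = (1.0 - fp) * Jupnp + fp * Jupp - Jleak
        Jtr = (cansr - cajsr) / 100.0

        JdiffNa = (nass - nai) / 2.0
        JdiffK = (kss - ki) / 2.0
        Jdiff = (cass - cai) / 0.2

        # --- gate updates (exact relaxation) ---
        S[9, i] = mss + (m - mss) * eg(-dt / tm)
        S[10, i] = hss + (hf - hss) * eg(-dt / thf)
        S[11, i] = hss + (hs - hss) * eg(-dt / ths)
        S[12, i] = jss + (j - jss) * eg(-dt / tj)
        S[13, i] = hssp + (hsp - hssp) * eg(-dt / thsp)
        S[14, i] = jss + (jp - jss) * eg(-dt / tjp)
        S[15, i] = mLss + (mL - mLss) * eg(-dt / tmL)
        S[16, i] = hLss + (hL - hLss) * eg(-dt / thL)
        S[17, i] = hLssp + (hLp - hLssp) * eg(-dt / thLp)
        S[18, i] = ass + (a - ass) * eg(-dt / ta)
        S[19, i] = iss + (iF - iss) * eg(-dt / tiF)
        S[20, i] = iss + (iS - iss) * eg(-dt / tiS)
        S[21, i] = assp + (ap - assp) * eg(-dt / ta)
        S[22, i] = iss + (iFp - iss) * eg(-dt / tiFp)
        S[23, i] = iss + (iSp - iss) * eg(-dt / tiSp)
        S[24, i] = dss + (d - dss) * eg(-dt / td)
        S[25, i] = fss + (ff - fss) * eg(-dt / tff)
        S[26, i] = fss + (fs - fss) * eg(-dt / tfs)
        S[27, i] = fcass + (fcaf - fcass) * eg(-dt / tfcaf)
        S[28, i] = fcass + (fcas - fcass) * eg(-dt / tfcas)
        S[29, i] = fcass + (jca - fcass) * eg(-dt / tjca)
        nca_inf = anca * 1000.0 / km2n
        S[30, i] = nca_inf - (nca_inf - nca) * eg(-km2n * dt)
        S[31, i] = fss + (ffp - fss) * eg(-dt / tffp)
        S[32, i] = fcass + (fcafp - fcass) * eg(-dt / tfcafp)
        S[33, i] = xrss + (xrf - xrss) * eg(-dt / txrf)
        S[34, i] = xrss + (xrs - xrss) * eg(-dt / txrs)
        S[35, i] = xs1ss + (xs1 - xs1ss) * eg(-dt / txs1)
        S[36, i] = xs2ss + (xs2 - xs2ss) * eg(-dt / txs2)
        S[37, i] = xk1ss + (xk1 - xk1ss) * eg(-dt / txk1)
        S[38, i] = Jrel_inf + (Jrelnp - Jrel_inf) * eg(-dt / tau_rel)
        S[39, i] = Jrel_infp + (Jrelp - Jrel_infp) * eg(-dt / tau_relp)
        mbi = bac_minf(v)
        hbi = bac_hinf(v)
        S[41, i] = mbi + (mb - mbi) * eg(-dt / bac_taum(v))
        S[42, i] = hbi + (hb - hbi) * eg(-dt / bac_tauh(v))

        # --- concentration and CaMK updates (forward Euler) ---
        dCaMKt = 0.05 * CaMKb * (CaMKb + CaMKt) - 0.00068 * CaMKt
        S[40, i] = CaMKt + dt * dCaMKt

        acap_f = _ACAP / FARADAY
        dnai = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab + IBac) \
            * acap_f / _VMYO + JdiffNa * _VSS / _VMYO
        dnass = -(ICaNa + 3.0 * INaCa_ss) * acap_f / _VSS - JdiffNa
        dki = -(Ito + IKr + IKs + IK1 + IKb - istim[i] - 2.0 * INaK) \
            * acap_f / _VMYO + JdiffK * _VSS / _VMYO
        dkss = -ICaK * acap_f / _VSS - JdiffK
        Bcai = 1.0 / (1.0 + 0.05 * (1.3 if celltype == 1 else 1.0) * 0.00238
                      / (0.00238 + cai) ** 2
                      + 0.07 * 0.0005 / (0.0005 + cai) ** 2)
        dcai = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * acap_f / (2.0 * _VMYO)
                       - Jup * _VNSR / _VMYO + Jdiff * _VSS / _VMYO)
        Bcass = 1.0 / (1.0 + 0.047 * 0.00087 / (0.00087 + cass) ** 2
                       + 1.124 * 0.0087 / (0.0087 + cass) ** 2)
        dcass = Bcass * (-(ICaL - 2.0 * INaCa_ss) * acap_f / (2.0 * _VSS)
                         + Jrel * _VJSR / _VSS - Jdiff)
        dcansr = Jup - Jtr * _VJSR / _VNSR
        Bcajsr = 1.0 / (1.0 + 10.0 * 0.8 / (0.8 + cajsr) ** 2)
        dcajsr = Bcajsr * (Jtr - Jrel)

        S[1, i] = nai + dt * dnai
        S[2, i] = nass + dt * dnass
        S[3, i] = ki + dt * dki
        S[4, i] = kss + dt * dkss
        S[5, i] = cai + dt * dcai
        S[6, i] = cass + dt * dcass
        S[7, i] = cansr + dt * dcansr
        S[8, i] = cajsr + dt * dcajsr

        if not clamped[i]:
            S[0, i] = v + dt * (-itot + istim[i])

    return itot_out
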