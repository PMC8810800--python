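"""Guinea-pig ventricular myocyte model (Luo--Rudy lineage).

Core membrane kinetics follow the Luo--Rudy formulation of the guinea-pig
ventricular AP: fast Na current with ``m^3 h j`` gating, slow inward
Ca current with dynamic intracellular Ca, and inward-rectifier/plateau/
background K currents.  The single delayed rectifier is split into its
rapid (IKr) and slow (IKs) components following the Rudy-lab extension of
the model, because the transmural Brugada cable differentiates wall layers
by their IKs:IKr balance.  A 4-AP-sensitive transient outward current
(Ito, activation ``r`` and inactivation ``s``, standard epicardial
kinetics) is included with zero conductance by default; the transmural
layers and Brugada severities set it per cell.

The Brugada substrate accelerates fast Na inactivation: the ``h_speed``
parameter divides the fast inactivation (h-gate) time constant, leaving
the steady state unchanged.

BacNav is added exactly as in the human model.  Intracellular Na/K are
fixed (classic Luo--Rudy assumption), so the BacNav reversal defaults to
the constant Na Nernst potential (~54 mV).

Units: mV, ms, uA/uF, mS/uF; concentrations mM.
"""

import math

import numpy as np
from numba import njit

from ._kernels import bac_hinf, bac_minf, bac_tauh, bac_taum, eg

NAME = "guineapig"

STATE_NAMES = (
    "v", "m", "h", "j", "d", "f", "cai",
    "xr", "xs1", "xs2", "r_to", "s_to", "m_bac", "h_bac",
)
N_STATE = len(STATE_NAMES)

CURRENT_NAMES = ("INa", "Isi", "IKr", "IKs", "IK1", "IKp", "Ib", "Ito",
                 "IBacNav")
N_CURRENT = len(CURRENT_NAMES)

PARAM_NAMES = (
    "g_Na", "g_si", "g_to", "g_Kr", "g_Ks", "g_K1", "g_Kp", "g_b",
    "h_speed", "bacnav_g", "bacnav_erev", "ito_vhalf", "ito_slope",
    "ito_taur_scale", "ito_taus_gauss",
)
N_PARAM = len(PARAM_NAMES)

DEFAULT_PARAMS = np.array(
    [23.0, 0.09, 0.0, 0.02614, 0.433, 0.6047, 0.0183, 0.03921,
     1.0, 0.0, np.nan, -5.0, 9.0, 1.0, 85.0]
)

DEFAULT_RATE_HZ = 3.33   # guinea-pig sinus rate
DEFAULT_STIM = (80.0, 1.0)

# fixed ionic milieu (mM)
NAO, NAI = 140.0, 18.0
KO, KI = 5.4, 145.0
R_GAS, TEMP, FARADAY = 8314.0, 310.0, 96485.0
RTF = R_GAS * TEMP / FARADAY
ENA = RTF * math.log(NAO / NAI)        # ~54.4 mV
EK = RTF * math.log(KO / KI)
EKS = RTF * math.log((KO + 0.01833 * NAO) / (KI + 0.01833 * NAI))
PRNAK_EK1 = EK                          # IK1/IKp reversal


def initial_state(n=1):
    """Resting state; gates at their steady state for v0 = -84 mV."""
    v0 = -84.0
    s = np.zeros((N_STATE, n))
    vals = _gate_inf(v0)
    for k, name in enumerate(("m", "h", "j", "d", "f", "xr", "xs1", "xs2",
                              "r_to", "s_to")):
        s[STATE_NAMES.index(name)] = vals[k]
    s[0] = v0
    s[6] = 1.0e-4
    s[STATE_NAMES.index("m_bac")] = 1.0 / (1.0 + math.exp((-22.5 - v0) / 2.704))
    s[STATE_NAMES.index("h_bac")] = 1.0 / (1.0 + math.exp((v0 + 77.05) / 10.64))
    return s


@njit(cache=True, inline="always")
def _lr_rates(v):
    """Luo--Rudy alpha/beta rates for m, h, j, d, f (1/ms)."""
    dv = v + 47.13
    if abs(dv) < 1.0e-6:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - eg(-0.1 * dv))
    bm = 0.08 * eg(-v / 11.0)
    if v < -40.0:
        ah = 0.135 * eg(-(80.0 + v) / 6.8)
        bh = 3.56 * eg(0.079 * v) + 3.1e5 * eg(0.35 * v)
        aj = (-1.2714e5 * eg(0.2444 * v) - 3.474e-5 * eg(-0.04391 * v)) \
            * (v + 37.78) / (1.0 + eg(0.311 * (v + 79.23)))
        bj = 0.1212 * eg(-0.01052 * v) / (1.0 + eg(-0.1378 * (v + 40.14)))
    else:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + eg(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * eg(-2.535e-7 * v) / (1.0 + eg(-0.1 * (v + 32.0)))
    ad = 0.095 * eg(-0.01 * (v - 5.0)) / (1.0 + eg(-0.072 * (v - 5.0)))
    bd = 0.07 * eg(-0.017 * (v + 44.0)) / (1.0 + eg(0.05 * (v + 44.0)))
    af = 0.012 * eg(-0.008 * (v + 28.0)) / (1.0 + eg(0.15 * (v + 28.0)))
    bf = 0.0065 * eg(-0.02 * (v + 30.0)) / (1.0 + eg(-0.2 * (v + 30.0)))
    return am, bm, ah, bh, aj, bj, ad, bd, af, bf


@njit(cache=True, inline="always")
def _xr_kinetics(v):
    xinf = 1.0 / (1.0 + eg(-(v + 21.5) / 7.5))
    d1 = v + 14.2
    if abs(d1) < 1.0e-6:
        t1 = 0.00138 / 0.123
    else:
        t1 = 0.00138 * d1 / (1.0 - eg(-0.123 * d1))
    d2 = v + 38.9
    if abs(d2) < 1.0e-6:
        t2 = 0.00061 / 0.145
    else:
        t2 = 0.00061 * d2 / (eg(0.145 * d2) - 1.0)
    return xinf, 1.0 / (t1 + t2)


@njit(cache=True, inline="always")
def _xs_kinetics(v):
    xinf = 1.0 / (1.0 + eg(-(v - 1.5) / 16.7))
    d = v + 30.0
    if abs(d) < 1.0e-6:
        t1 = 7.19e-5 / 0.148
        t2 = 1.31e-4 / 0.0687
    else:
        t1 = 7.19e-5 * d / (1.0 - eg(-0.148 * d))
        t2 = 1.31e-4 * d / (eg(0.0687 * d) - 1.0)
    return xinf, 1.0 / (t1 + t2)


@njit(cache=True, inline="always")
def _ito_kinetics(v, vhalf, slope, taur_scale, taus_gauss):
    # activation must reach into the phase-1 voltage range so the notch
    # current persists while the potential falls -- the substrate of
    # regenerative, all-or-none dome loss; midpoint/slope/time-constant
    # scales are model parameters with documented defaults
    rinf = 1.0 / (1.0 + eg(-(v - vhalf) / slope))
    taur = taur_scale * (9.5 * eg(-(v + 40.0) ** 2 / 1800.0) + 0.8)
    sinf = 1.0 / (1.0 + eg((v + 20.0) / 5.0))
    taus = taus_gauss * eg(-(v + 45.0) ** 2 / 320.0) \
        + 5.0 / (1.0 + eg((v - 20.0) / 5.0)) + 3.0
    return rinf, taur, sinf, taus


@njit(cache=True)
def _gate_inf(v):
    am, bm, ah, bh, aj, bj, ad, bd, af, bf = _lr_rates(v)
    xrinf, _ = _xr_kinetics(v)
    xsinf, _ = _xs_kinetics(v)
    rinf, _, sinf, _ = _ito_kinetics(v, DEFAULT_PARAMS[11], DEFAULT_PARAMS[12],
                                     DEFAULT_PARAMS[13], DEFAULT_PARAMS[14])
    return (am / (am + bm), ah / (ah + bh), aj / (aj + bj),
            ad / (ad + bd), af / (af + bf), xrinf, xsinf, xsinf, rinf, sinf)


@njit(cache=True)
def step(S, P, dt, istim, clamped, IOUT):
    """One time step; same contract as :func:`bacnavsim.models.human.step`."""
    n = S.shape[1]
    itot_out = np.empty(n)
    for i in range(n):
        v = S[0, i]
        m = S[1, i]; h = S[2, i]; j = S[3, i]
        d = S[4, i]; f = S[5, i]; cai = S[6, i]
        xr = S[7, i]; xs1 = S[8, i]; xs2 = S[9, i]
        rto = S[10, i]; sto = S[11, i]
        mb = S[12, i]; hb = S[13, i]

        gna = P[0, i]; gsi = P[1, i]; gto = P[2, i]
        gkr = P[3, i]; gks = P[4, i]; gk1 = P[5, i]
        gkp = P[6, i]; gb = P[7, i]; hspeed = P[8, i]
        gbac = P[9, i]; erev_bac = P[10, i]
        ito_vhalf = P[11, i]; ito_slope = P[12, i]
        ito_trs = P[13, i]; ito_tsg = P[14, i]

        INa = gna * m * m * m * h * j * (v - ENA)

        esi = 7.7 - 13.0287 * math.log(cai)
        Isi = gsi * d * f * (v - esi)

        rkr = 1.0 / (1.0 + eg((v + 9.0) / 22.4))
        IKr = gkr * math.sqrt(KO / 5.4) * xr * rkr * (v - EK)

        gks_eff = gks * (1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4))
        IKs = gks_eff * xs1 * xs2 * (v - EKS)

        dvk1 = v - PRNAK_EK1
        ak1 = 1.02 / (1.0 + eg(0.2385 * (dvk1 - 59.215)))
        bk1 = (0.49124 * eg(0.08032 * (dvk1 + 5.476))
               + eg(0.06175 * (dvk1 - 594.31))) \
            / (1.0 + eg(-0.5143 * (dvk1 + 4.753)))
        IK1 = gk1 * math.sqrt(KO / 5.4) * ak1 / (ak1 + bk1) * dvk1

        kp = 1.0 / (1.0 + eg((7.488 - v) / 5.98))
        IKp = gkp * kp * dvk1

        Ib = gb * (v + 59.87)

        Ito = gto * rto * rto * rto * sto * (v - EK)

        if math.isnan(erev_bac):
            ebac = ENA
        else:
            ebac = erev_bac
        IBac = gbac * mb * hb * hb * (v - ebac)

        itot = INa + Isi + IKr + IKs + IK1 + IKp + Ib + Ito + IBac

        IOUT[0, i] = INa; IOUT[1, i] = Isi; IOUT[2, i] = IKr
        IOUT[3, i] = IKs; IOUT[4, i] = IK1; IOUT[5, i] = IKp
        IOUT[6, i] = Ib; IOUT[7, i] = Ito; IOUT[8, i] = IBac
        itot_out[i] = itot

        if dt == 0.0:
            continue

        am, bm, ah, bh, aj, bj, ad, bd, af, bf = _lr_rates(v)
        # h_speed divides the fast-inactivation time constant only
        ah *= hspeed
        bh *= hspeed
        minf = am / (am + bm)
        hinf = ah / (ah + bh) if (ah + bh) > 0.0 else 0.0
        jinf = aj / (aj + bj) if (aj + bj) > 0.0 else 0.0
        dinf = ad / (ad + bd)
        finf = af / (af + bf)
        S[1, i] = minf + (m - minf) * eg(-dt * (am + bm))
        S[2, i] = hinf + (h - hinf) * eg(-dt * (ah + bh))
        S[3, i] = jinf + (j - jinf) * eg(-dt * (aj + bj))
        S[4, i] = dinf + (d - dinf) * eg(-dt * (ad + bd))
        S[5, i] = finf + (f - finf) * eg(-dt * (af + bf))

        xrinf, txr = _xr_kinetics(v)
        S[7, i] = xrinf + (xr - xrinf) * eg(-dt / txr)
        xsinf, txs1 = _xs_kinetics(v)
        S[8, i] = xsinf + (xs1 - xsinf) * eg(-dt / txs1)
        S[9, i] = xsinf + (xs2 - xsinf) * eg(-dt / (4.0 * txs1))
        rinf, taur, sinf, taus = _ito_kinetics(v, ito_vhalf, ito_slope,
                                               ito_trs, ito_tsg)
        S[10, i] = rinf + (rto - rinf) * eg(-dt / taur)
        S[11, i] = sinf + (sto - sinf) * eg(-dt / taus)

        mbi = bac_minf(v)
        hbi = bac_hinf(v)
        S[12, i] = mbi + (mb - mbi) * eg(-dt / bac_taum(v))
        S[13, i] = hbi + (hb - hbi) * eg(-dt / bac_tauh(v))

        S[6, i] = cai + dt * (-1.0e-4 * Isi + 0.07 * (1.0e-4 - cai))

        if not clamped[i]:
            S[0, i] = v + dt * (-itot + istim[i])

    return itot_out
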