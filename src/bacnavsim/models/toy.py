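"""Two-variable excitable toy cell (Aliev--Panfilov form).

Fast fixture for solver verification: a cubic excitation variable ``u``
and one recovery variable ``w``,

    du/dt = k u (u - a)(1 - u) - u w + I
    dw/dt = (eps0 + mu1 w / (mu2 + u)) (-w - k u (u - a - 1))

mapped onto the membrane-potential scale as ``Vm = 100 u - 80`` so it
plugs into the same integration/diffusion machinery as the ionic models.
``u`` stays in a bounded interval near [0, 1] for the documented stable
parameter region (0 < a < 0.5, k > 0, eps0 > 0).  Model time is treated
as milliseconds.  No BacNav and no ionic bookkeeping.
"""

import numpy as np
from numba import njit

NAME = "toy"

STATE_NAMES = ("v", "w")
N_STATE = 2
CURRENT_NAMES = ("Iion",)
N_CURRENT = 1
PARAM_NAMES = ("k", "a", "eps0", "mu1", "mu2")
N_PARAM = 5
DEFAULT_PARAMS = np.array([8.0, 0.15, 0.002, 0.2, 0.3])

DEFAULT_RATE_HZ = 10.0
DEFAULT_STIM = (30.0, 1.0)

V_REST = -80.0
V_SCALE = 100.0


def initial_state(n=1):
    s = np.zeros((N_STATE, n))
    s[0] = V_REST
    return s


@njit(cache=True)
def step(S, P, dt, istim, clamped, IOUT):
    n = S.shape[1]
    itot_out = np.empty(n)
    for i in range(n):
        u = (S[0, i] - V_REST) / V_SCALE
        w = S[1, i]
        k = P[0, i]; a = P[1, i]
        eps0 = P[2, i]; mu1 = P[3, i]; mu2 = P[4, i]
        du = k * u * (u - a) * (1.0 - u) - u * w
        iion = -V_SCALE * du  # uA/uF-equivalent so that dV = -iion + istim
        IOUT[0, i] = iion
        itot_out[i] = iion
        if dt == 0.0:
            continue
        dw = (eps0 + mu1 * w / (mu2 + u)) * (-w - k * u * (u - a - 1.0))
        S[1, i] = w + dt * dw
        if not clamped[i]:
            S[0, i] = S[0, i] + dt * (-iion + istim[i])
    return itot_out
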