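"""Shared scalar numba helpers for the ionic-model kernels."""

import math

from numba import njit

__all__ = ["eg", "bac_minf", "bac_hinf", "bac_taum", "bac_tauh"]


@njit(cache=True, inline="always")
def eg(x):
    """Overflow-guarded exponential; exact for asymptotic denominators."""
    if x > 700.0:
        x = 700.0
    elif x < -700.0:
        x = -700.0
    return math.exp(x)


# BacNav gating functions (scalar twins of bacnavsim.channel; the vector
# versions in channel.py are the reference, cross-checked in the tests).

@njit(cache=True, inline="always")
def bac_minf(v):
    return 1.0 / (1.0 + eg((-22.5 - v) / 2.704))


@njit(cache=True, inline="always")
def bac_hinf(v):
    return 1.0 / (1.0 + eg((v + 77.05) / 10.64))


@njit(cache=True, inline="always")
def bac_taum(v):
    return 34.65 / (eg((v + 43.47) / 14.36) + eg(-(v + 15.75) / 0.2351)) + 1.66


@njit(cache=True, inline="always")
def bac_tauh(v):
    return 107.8 / (eg((v + 27.15) / 0.1281) + eg(-(v + 25.63) / 25.19)) + 9.593
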