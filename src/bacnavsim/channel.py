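"""Kinetic model of the engineered bacterial sodium channel (h2SheP).

The channel is described by a single activation gate ``m`` and a single
inactivation gate ``h``, each obeying first-order Hodgkin--Huxley kinetics

.. math::

    \\frac{dg}{dt} = \\frac{g_\\infty(V_m) - g}{\\tau_g(V_m)},

with fitted voltage-dependent time constants and steady-state curves.
The macroscopic current is ohmic with one activation and two identical
inactivation gates,

.. math::

    I_{BacNav} = X \\, \\bar g_{1X} \\, m \\, h^2 \\, (V_m - E_{rev}),

where ``X`` is the expression multiplier (0.5X, 1X, 2X ...) and
``gbar_1x`` is the maximal conductance at the 1X expression level, defined
by calibration against the endogenous Na_v1.5 peak current (see
:mod:`bacnavsim.calibration`).  The channel is Na-selective, so the default
reversal potential is the sodium Nernst potential of the host cell model.

The squared inactivation gate is the package's resolution of an
under-determined current law: the fitted steady-state curves leave a
small m_inf * h_inf overlap ("window") near -15 mV, and with a single h
gate the calibrated channel conducts a sustained inward current there
that is incompatible with the channel's functional phenotype -- the
current switches off completely within tens of milliseconds and stays
off during late repolarization, and expression does not prolong the
ventricular AP.  Two identical inactivation gates keep every fitted
kinetic curve while suppressing the window open-probability by more than
two orders of magnitude.

Units: mV, ms, mS/uF, uA/uF.

The time-constant denominators contain very steep exponentials (slope
factors 0.2351 and 0.1281 mV); evaluated naively these overflow doubles at
ordinary membrane potentials, so all exponent arguments are clamped to
+/-700 before exponentiation.  Because the overflowing exponential sits in
a denominator, the clamp reproduces the exact asymptotic value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "ChannelGates",
    "BacNavParams",
    "tau_m",
    "tau_h",
    "m_inf",
    "h_inf",
    "step_gates",
    "bacnav_current",
]

#: Clamp for exponent arguments: exp(709.8) is the largest finite double.
EXP_CLIP = 700.0


def _exp(x):
    """Overflow-guarded exponential (vectorised)."""
    return np.exp(np.clip(x, -EXP_CLIP, EXP_CLIP))


def _check_vm(vm):
    vm = np.asarray(vm, dtype=float)
    if not np.all(np.isfinite(vm)):
        raise InvalidInputError("membrane potential must be finite")
    return vm


def tau_m(vm):
    """Activation time constant (ms) of the BacNav ``m`` gate.

    Approaches 1.66 ms at strongly depolarized potentials where both
    denominator exponentials diverge.
    """
    vm = _check_vm(vm)
    den = _exp((vm + 43.47) / 14.36) + _exp(-(vm + 15.75) / 0.2351)
    return 34.65 / den + 1.66


def tau_h(vm):
    """Inactivation time constant (ms) of the BacNav ``h`` gate.

    Approaches 9.593 ms at strongly depolarized potentials.
    """
    vm = _check_vm(vm)
    den = _exp((vm + 27.15) / 0.1281) + _exp(-(vm + 25.63) / 25.19)
    return 107.8 / den + 9.593


def m_inf(vm):
    """Steady-state activation; sigmoid with half-activation at -22.5 mV."""
    vm = _check_vm(vm)
    return 1.0 / (1.0 + _exp((-22.5 - vm) / 2.704))


def h_inf(vm):
    """Steady-state inactivation; sigmoid with half-inactivation at -77.05 mV."""
    vm = _check_vm(vm)
    return 1.0 / (1.0 + _exp((vm + 77.05) / 10.64))


@dataclass
class ChannelGates:
    """Pair of BacNav gating variables, each a fraction in [0, 1]."""

    m: float
    h: float

    @classmethod
    def at_rest(cls, v0: float) -> "ChannelGates":
        """Gates equilibrated at a holding potential ``v0``."""
        return cls(m=float(m_inf(v0)), h=float(h_inf(v0)))

    def __post_init__(self):
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.h <= 1.0):
            raise InvalidInputError(
                f"gates must lie in [0, 1], got m={self.m}, h={self.h}"
            )


@dataclass
class BacNavParams:
    """BacNav conductance parameters.

    Attributes
    ----------
    gbar_1x:
        Maximal conductance at the 1X expression level (mS/uF), > 0.
    x_level:
        Dimensionless expression multiplier, >= 0.  0 removes the channel.
    e_rev:
        Reversal potential (mV).  By convention set to the sodium Nernst
        potential of the host model.
    """

    gbar_1x: float
    x_level: float = 1.0
    e_rev: float = 70.0

    def __post_init__(self):
        if not self.gbar_1x > 0:
            raise InvalidInputError(f"gbar_1x must be > 0, got {self.gbar_1x}")
        if self.x_level < 0:
            raise InvalidInputError(f"x_level must be >= 0, got {self.x_level}")


def step_gates(gates: ChannelGates, vm: float, dt: float) -> ChannelGates:
    """Advance both gates over ``dt`` ms at fixed ``vm``.

    Uses the exact-relaxation (Rush--Larsen) update
    ``g' = g_inf + (g - g_inf) * exp(-dt / tau)``, which is the exact
    solution of the linear gate ODE for constant voltage and therefore
    unconditionally keeps gates inside [0, 1].
    """
    if dt < 0:
        raise InvalidInputError(f"dt must be >= 0, got {dt}")
    minf, hinf = float(m_inf(vm)), float(h_inf(vm))
    m = minf + (gates.m - minf) * float(np.exp(-dt / tau_m(vm)))
    h = hinf + (gates.h - hinf) * float(np.exp(-dt / tau_h(vm)))
    return ChannelGates(m=m, h=h)


def bacnav_current(vm, gates: ChannelGates, params: BacNavParams):
    """Macroscopic BacNav current density (uA/uF), ``X g m h^2 (Vm - E)``.

    Linear in the expression multiplier; zero at ``x_level = 0`` and at
    ``vm = e_rev`` (zero driving force).
    """
    return params.x_level * params.gbar_1x * gates.m * gates.h ** 2 * (
        np.asarray(vm, dtype=float) - params.e_rev
    )
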