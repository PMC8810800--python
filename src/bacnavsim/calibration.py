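"""Calibration of the 1X BacNav expression level.

1X is *defined* as the BacNav maximal conductance whose simulated peak
voltage-clamp current magnitude equals that of the endogenous Na_v1.5
current in the same host model, under the standard step protocol
(holding -80 mV, 500 ms steps from -50 to +50 mV in 10 mV increments).
Calibration is per species: each host model has its own endogenous Na
density and therefore its own gbar_1x.

The search is a deterministic bisection on gbar; since the clamp-gate
trajectories do not depend on gbar, peak |I_BacNav| is exactly linear in
gbar and the bisection converges to machine-level consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import CellModel, build_cell, voltage_clamp
from .errors import CalibrationError, InvalidInputError

__all__ = ["ClampProtocol", "CalibrationReport", "calibrate_1x", "peak_iv"]


@dataclass(frozen=True)
class ClampProtocol:
    """Voltage-step protocol mirroring the experimental patch recipe."""

    holding_mv: float = -80.0
    steps_mv: tuple = tuple(range(-50, 51, 10))
    step_duration_ms: float = 500.0
    settle_ms: float = 500.0


@dataclass
class CalibrationReport:
    """Result of matching peak BacNav to peak endogenous Na current."""

    species: str
    gbar_1x: float               # mS/uF
    peak_ina_ref: float          # uA/uF (signed extremum)
    peak_ibacnav: float          # uA/uF at gbar_1x
    mismatch_pct: float
    protocol: ClampProtocol = field(default_factory=ClampProtocol)

    def to_dict(self):
        return {
            "species": self.species,
            "gbar_1x_mS_per_uF": self.gbar_1x,
            "peak_INa_uA_per_uF": self.peak_ina_ref,
            "peak_IBacNav_uA_per_uF": self.peak_ibacnav,
            "mismatch_pct": self.mismatch_pct,
            "protocol": {
                "holding_mV": self.protocol.holding_mv,
                "steps_mV": list(self.protocol.steps_mv),
                "step_duration_ms": self.protocol.step_duration_ms,
            },
        }


def peak_iv(cell: CellModel, current: str,
            protocol: ClampProtocol = ClampProtocol()):
    """Peak (signed, max-|.|) current at each test potential."""
    steps, peaks, _ = voltage_clamp(
        cell, protocol.holding_mv, protocol.steps_mv,
        step_duration_ms=protocol.step_duration_ms, current=current,
        settle_ms=protocol.settle_ms)
    return steps, peaks


def calibrate_1x(
    cell: CellModel,
    protocol: ClampProtocol = ClampProtocol(),
    tol_pct: float = 0.1,
    bracket_hi_factor: float = 10.0,
) -> CalibrationReport:
    """Find gbar_1x such that peak |I_BacNav| matches peak |I_Na|.

    ``cell`` is the host model at its endogenous Na density (any
    ``gNa_scale`` already applied defines the reference).  Raises
    :class:`CalibrationError` when the endogenous Na conductance is zero
    or the bracket does not contain the match.
    """
    gna = cell.conductance("g_Na")
    if gna <= 0:
        raise CalibrationError(
            "calibration undefined: endogenous g_Na is zero")
    if tol_pct <= 0:
        raise InvalidInputError("tol_pct must be > 0")

    _, peaks_na = peak_iv(cell, "INa", protocol)
    ref = float(peaks_na[np.argmax(np.abs(peaks_na))])
    ref_mag = abs(ref)
    if ref_mag == 0:
        raise CalibrationError("reference peak I_Na is zero under protocol")

    def peak_bac(gbar):
        probe = cell.copy()
        probe.set_conductance("bacnav_g", gbar)
        _, peaks = peak_iv(probe, "IBacNav", protocol)
        return float(peaks[np.argmax(np.abs(peaks))])

    lo, hi = 1.0e-4, bracket_hi_factor * gna
    m_lo, m_hi = abs(peak_bac(lo)), abs(peak_bac(hi))
    if not (m_lo < m_hi):
        raise CalibrationError("peak |I_BacNav| not increasing over bracket")
    if not (m_lo <= ref_mag <= m_hi):
        raise CalibrationError(
            f"bracket [{lo}, {hi}] does not contain the match "
            f"(|peaks| {m_lo:.3g}..{m_hi:.3g}, ref {ref_mag:.3g})")

    gbar = 0.5 * (lo + hi)
    for _ in range(200):
        gbar = 0.5 * (lo + hi)
        m_mid = abs(peak_bac(gbar))
        if abs(m_mid - ref_mag) / ref_mag * 100.0 < tol_pct:
            break
        if m_mid < ref_mag:
            lo = gbar
        else:
            hi = gbar
    achieved = peak_bac(gbar)
    mismatch = (abs(achieved) - ref_mag) / ref_mag * 100.0
    return CalibrationReport(
        species=cell.species,
        gbar_1x=gbar,
        peak_ina_ref=ref,
        peak_ibacnav=achieved,
        mismatch_pct=mismatch,
        protocol=protocol,
    )


_CAL_CACHE: dict = {}


def calibrated_gbar_1x(species: str, gNa_scale: float = 1.0) -> float:
    """Memoised per-species calibration at the *unscaled* Na reference.

    The 1X definition references the healthy endogenous peak current, so
    reduced-excitability runs (``gNa_scale < 1``) still use the gbar_1x
    calibrated against the full-density Na_v1.5 peak.
    """
    key = species
    if key not in _CAL_CACHE:
        cell = build_cell(species)
        # bisection needs a nonzero starting bacnav conductance slot
        cell.set_conductance("bacnav_g", 0.0)
        _CAL_CACHE[key] = calibrate_1x(cell)
    return _CAL_CACHE[key].gbar_1x
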