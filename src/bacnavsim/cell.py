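"""Single-cell simulation engine.

Builds host myocyte models, optionally with BacNav attached and endogenous
conductances rescaled, paces them to (approximate) equilibrium, records
AP and current traces, and runs voltage-clamp protocols.

Integration: Hodgkin--Huxley gates by exact exponential relaxation,
concentrations and Vm by forward Euler, default dt = 0.01 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    IntegrationFailureError,
    InvalidInputError,
    NoCaptureError,
)
from .models import ModelDef, get_model

__all__ = [
    "CellModel",
    "PacingResult",
    "TraceResult",
    "build_cell",
    "pace_to_equilibrium",
    "simulate_ap",
    "voltage_clamp",
    "replay_clamp",
    "find_threshold",
]

#: default equilibrium criterion: max per-beat state change, percent
EQ_CRITERION_PCT = 0.001
EQ_MAX_BEATS = 200

V_BLOWUP = 500.0  # |Vm| beyond this is a numerical failure


@dataclass
class CellModel:
    """One myocyte: model handle, state vector and parameter vector."""

    species: str
    model: ModelDef
    state: np.ndarray            # (n_state,)
    params: np.ndarray           # (n_param,)
    pacing_hz: float
    stim_amplitude: float        # uA/uF, depolarizing positive
    stim_duration: float         # ms
    dt: float = 0.01

    @property
    def vm(self) -> float:
        return float(self.state[0])

    @property
    def cycle_length_ms(self) -> float:
        return 1000.0 / self.pacing_hz

    def conductance(self, name: str) -> float:
        return float(self.params[self.model.param_names.index(name)])

    def set_conductance(self, name: str, value: float) -> None:
        if value < 0:
            raise InvalidInputError(f"conductance {name} must be >= 0")
        self.params[self.model.param_names.index(name)] = value

    def copy(self) -> "CellModel":
        return replace(self, state=self.state.copy(), params=self.params.copy())

    # -- low-level integration -------------------------------------------

    def _columns(self):
        """State/params as (n, 1) columns for the kernel."""
        return self.state.reshape(-1, 1), self.params.reshape(-1, 1)

    def run_beat(self, record_dt: float | None = None):
        """Advance one pacing cycle; optionally record traces.

        Returns ``None`` or ``(t, vm, currents)`` where ``currents`` has
        shape ``(n_current, n_samples)``.
        """
        S, P = self._columns()
        dt = self.dt
        n_steps = int(round(self.cycle_length_ms / dt))
        stim_steps = max(1, int(round(self.stim_duration / dt)))
        istim_on = np.array([self.stim_amplitude])
        istim_off = np.zeros(1)
        clamped = np.zeros(1, dtype=np.bool_)
        iout = np.empty((self.model.n_current, 1))
        step = self.model.step

        rec = None
        if record_dt is not None:
            every = max(1, int(round(record_dt / dt)))
            n_rec = n_steps // every + 1
            rec_t = np.empty(n_rec)
            rec_v = np.empty(n_rec)
            rec_i = np.empty((self.model.n_current, n_rec))
            k_rec = 0

        vmax = S[0, 0]
        for k in range(n_steps):
            if record_dt is not None and k % every == 0:
                step(S, P, 0.0, istim_off, clamped, iout)
                rec_t[k_rec] = k * dt
                rec_v[k_rec] = S[0, 0]
                rec_i[:, k_rec] = iout[:, 0]
                k_rec += 1
            istim = istim_on if k < stim_steps else istim_off
            step(S, P, dt, istim, clamped, iout)
            if S[0, 0] > vmax:
                vmax = S[0, 0]
            if k % 500 == 0:
                _check_finite(S, self.model, k * dt)
        _check_finite(S, self.model, n_steps * dt)
        self.state = S[:, 0].copy()
        self.last_beat_peak_vm = float(vmax)
        if record_dt is not None:
            return rec_t[:k_rec], rec_v[:k_rec], rec_i[:, :k_rec]
        return None


def _check_finite(S, model, t_ms):
    bad = ~np.isfinite(S) | (np.abs(S[0:1]) > V_BLOWUP)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise IntegrationFailureError(
            f"integration failure: state {model.state_names[idx[0]]!r} at "
            f"node {idx[1]}, t = {t_ms:.3f} ms",
            variable=model.state_names[idx[0]], node=int(idx[1]), time_ms=t_ms,
        )


def build_cell(
    species: str,
    *,
    x_level: float = 0.0,
    gbar_1x: float | None = None,
    e_rev: float | None = None,
    gNa_scale: float = 1.0,
    conductance_scales: dict | None = None,
    pacing_hz: float | None = None,
    stim_amplitude: float | None = None,
    stim_duration: float | None = None,
    dt: float = 0.01,
    celltype: str = "endo",
) -> CellModel:
    """Construct a host myocyte, optionally with BacNav.

    ``x_level``/``gbar_1x`` set the BacNav conductance to
    ``x_level * gbar_1x`` (mS/uF); ``e_rev=None`` keeps the Na Nernst
    default.  ``gNa_scale`` scales the endogenous fast Na conductance
    (reduced-excitability experiments use 0.5).  ``conductance_scales``
    maps registered conductance names to multiplicative factors.
    """
    model = get_model(species)
    params = model.default_params
    names = model.param_names
    if gNa_scale != 1.0:
        params[names.index("g_Na")] *= gNa_scale
    for key, factor in (conductance_scales or {}).items():
        if key not in names:
            raise InvalidInputError(
                f"unknown conductance {key!r} for species {species!r}")
        params[names.index(key)] *= factor
    if x_level:
        if "bacnav_g" not in names:
            raise InvalidInputError(f"model {species!r} has no BacNav hook")
        if gbar_1x is None or gbar_1x <= 0:
            raise InvalidInputError(
                "x_level > 0 requires a calibrated gbar_1x > 0")
        params[names.index("bacnav_g")] = x_level * gbar_1x
        if e_rev is not None:
            params[names.index("bacnav_erev")] = e_rev
    if "celltype" in names:
        params[names.index("celltype")] = {"endo": 0, "epi": 1, "mid": 2}[
            celltype]
    amp, dur = model.default_stim
    return CellModel(
        species=species,
        model=model,
        state=model.initial_state(1)[:, 0],
        params=params,
        pacing_hz=pacing_hz if pacing_hz is not None else model.default_rate_hz,
        stim_amplitude=stim_amplitude if stim_amplitude is not None else amp,
        stim_duration=stim_duration if stim_duration is not None else dur,
        dt=dt,
    )


@dataclass
class PacingResult:
    """Outcome of pacing to equilibrium."""

    state: np.ndarray
    beats: int
    converged: bool
    max_rel_change_pct: float


def pace_to_equilibrium(
    cell,
    rate_hz: float | None = None,
    criterion_pct: float = EQ_CRITERION_PCT,
    max_beats: int = EQ_MAX_BEATS,
) -> PacingResult:
    """Pace until every state variable changes < ``criterion_pct`` %/beat.

    The cell is modified in place; the honest convergence flag is
    returned even when the beat budget is exhausted.  ``cell`` only needs
    ``run_beat()`` and ``state`` (duck-typed so analytic relaxation
    fixtures can exercise the convergence logic).
    """
    if rate_hz is not None:
        if rate_hz <= 0:
            raise InvalidInputError("pacing rate must be > 0")
        cell.pacing_hz = rate_hz
    if criterion_pct <= 0:
        raise InvalidInputError("criterion must be > 0")
    prev = np.array(cell.state, dtype=float, copy=True)
    v_rest = float(prev[0])
    max_change = math.inf
    beats = 0
    for beats in range(1, max_beats + 1):
        cell.run_beat()
        cur = np.asarray(cell.state, dtype=float)
        if beats == 1:
            peak = getattr(cell, "last_beat_peak_vm", None)
            if peak is not None and peak - v_rest < 10.0:
                raise NoCaptureError(
                    f"stimulus did not elicit an AP (peak {peak:.1f} mV "
                    f"from {v_rest:.1f} mV rest)")
        denom = np.maximum(np.abs(prev), 1e-12)
        max_change = float(np.max(np.abs(cur - prev) / denom) * 100.0)
        prev = cur.copy()
        if max_change < criterion_pct:
            break
    return PacingResult(
        state=np.array(cell.state, copy=True),
        beats=beats,
        converged=max_change < criterion_pct,
        max_rel_change_pct=max_change,
    )


@dataclass
class TraceResult:
    """Recorded final-beat traces."""

    t: np.ndarray                 # ms, from beat onset (stimulus at t=0)
    vm: np.ndarray                # mV
    currents: dict                # name -> uA/uF array
    stim_time: float = 0.0

    @property
    def peak_vm(self) -> float:
        return float(self.vm.max())


def simulate_ap(cell: CellModel, n_beats: int = 1,
                record_dt: float = 0.05) -> TraceResult:
    """Run ``n_beats`` pacing cycles, recording the final one.

    Raises :class:`NoCaptureError` if the recorded beat shows no AP
    (peak depolarization < 10 mV above the pre-stimulus potential).
    """
    if n_beats < 1:
        raise InvalidInputError("n_beats must be >= 1")
    for _ in range(n_beats - 1):
        cell.run_beat()
    v_pre = cell.vm
    t, vm, cur = cell.run_beat(record_dt=record_dt)
    if vm.max() - v_pre < 10.0:
        raise NoCaptureError(
            f"stimulus did not elicit an AP (peak {vm.max():.1f} mV from "
            f"{v_pre:.1f} mV)")
    currents = {name: cur[k] for k, name in enumerate(cell.model.current_names)}
    return TraceResult(t=t, vm=vm, currents=currents)


def replay_clamp(cell: CellModel, t_ms, v_command, current: str,
                 settle_ms: float = 500.0):
    """Replay an arbitrary command waveform in voltage clamp (AP clamp).

    ``v_command(t)`` is given as samples on ``t_ms`` (linear interpolation
    between them).  The cell settles at the first command value, then Vm
    is prescribed along the waveform while the selected channel current
    is recorded at every integration step.  Returns ``(t, i_trace)``.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    v_command = np.asarray(v_command, dtype=float)
    if t_ms.ndim != 1 or t_ms.size != v_command.size or t_ms.size < 2:
        raise InvalidInputError("need matching 1D t/v with >= 2 samples")
    model = cell.model
    dt = cell.dt
    S = model.initial_state(1)
    P = cell.params.reshape(-1, 1).copy()
    clamped = np.ones(1, dtype=np.bool_)
    istim = np.zeros(1)
    iout = np.empty((model.n_current, 1))
    cidx = model.current_names.index(current)

    S[0, 0] = v_command[0]
    for _ in range(int(round(settle_ms / dt))):
        model.step(S, P, dt, istim, clamped, iout)
        S[0, 0] = v_command[0]

    n_steps = int(round((t_ms[-1] - t_ms[0]) / dt))
    tt = t_ms[0] + np.arange(n_steps) * dt
    vv = np.interp(tt, t_ms, v_command)
    trace = np.empty(n_steps)
    for k in range(n_steps):
        S[0, 0] = vv[k]
        model.step(S, P, dt, istim, clamped, iout)
        trace[k] = iout[cidx, 0]
    return tt, trace


def find_threshold(cell: CellModel, duration_ms: float = 1.0,
                   lo: float = 1.0, hi: float = 400.0,
                   tol: float = 1.0) -> float:
    """Diastolic stimulus threshold (uA/uF) by bisection.

    Capture = Vm exceeds 0 mV within 50 ms of stimulus onset.
    """
    def captures(amp):
        c = cell.copy()
        c.stim_amplitude = amp
        c.stim_duration = duration_ms
        S, P = c._columns()
        clamped = np.zeros(1, dtype=np.bool_)
        iout = np.empty((c.model.n_current, 1))
        stim_steps = max(1, int(round(duration_ms / c.dt)))
        n_steps = int(round(50.0 / c.dt))
        ion = np.array([amp])
        ioff = np.zeros(1)
        for k in range(n_steps):
            c.model.step(S, P, c.dt, ion if k < stim_steps else ioff,
                         clamped, iout)
            if S[0, 0] > 0.0:
                return True
        return False

    if not captures(hi):
        raise NoCaptureError(
            f"no capture even at {hi} uA/uF for {duration_ms} ms")
    if captures(lo):
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return hi


def voltage_clamp(
    cell: CellModel,
    holding_mv: float,
    steps_mv,
    step_duration_ms: float = 500.0,
    current: str = "INa",
    settle_ms: float = 500.0,
    record_dt: float = 0.05,
):
    """Step-clamp protocol; returns (steps, peak current per step, traces).

    All test potentials run in parallel as columns of one state array.
    The cell's Vm is prescribed; the signed extremum (largest magnitude)
    of the selected current during the step window is reported.
    """
    steps_mv = np.asarray(list(steps_mv), dtype=float)
    if steps_mv.size == 0:
        raise InvalidInputError("steps must be non-empty")
    model = cell.model
    n = steps_mv.size
    S = np.repeat(cell.model.initial_state(1), n, axis=1)
    P = np.repeat(cell.params.reshape(-1, 1), n, axis=1)
    S[0, :] = holding_mv
    clamped = np.ones(n, dtype=np.bool_)
    istim = np.zeros(n)
    iout = np.empty((model.n_current, n))
    dt = cell.dt
    cidx = model.current_names.index(current)

    for _ in range(int(round(settle_ms / dt))):
        model.step(S, P, dt, istim, clamped, iout)
        S[0, :] = holding_mv

    every = max(1, int(round(record_dt / dt)))
    n_steps = int(round(step_duration_ms / dt))
    n_rec = n_steps // every
    traces = np.empty((n, n_rec))
    tvec = np.empty(n_rec)
    peaks = np.zeros(n)
    S[0, :] = steps_mv
    k_rec = 0
    for k in range(n_steps):
        model.step(S, P, dt, istim, clamped, iout)
        S[0, :] = steps_mv
        if k % every == 0 and k_rec < n_rec:
            traces[:, k_rec] = iout[cidx]
            tvec[k_rec] = (k + 1) * dt
            k_rec += 1
        sel = np.abs(iout[cidx]) > np.abs(peaks)
        peaks[sel] = iout[cidx][sel]
    return steps_mv, peaks, (tvec[:k_rec], traces[:, :k_rec])
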