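"""1D monodomain cable simulation of AP propagation.

The cable is the standard continuous monodomain reduction of a fiber of
coupled myocytes: ``dVm/dt = -Iion + Istim + D d2Vm/dx2`` with no-flux
ends, where the effective diffusion coefficient follows from the fiber
radius ``a``, intracellular resistivity ``Ri`` and membrane capacitance
``Cm`` as ``D = a / (2 Ri Cm)``.

Default geometry: 100 cells of 100 um length (1 cm total), radius 10 um,
Ri = 0.4 kOhm.cm, one node per cell (dx = 100 um).  Conduction velocity
is the least-squares slope of position on activation time over a central
window; activation time is the instant of maximum dVm/dt per node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import build_cell, pace_to_equilibrium, _check_finite
from .errors import (
    ConductionBlockError,
    EstimatorDegenerateError,
    InvalidInputError,
)
from .models import get_model

__all__ = [
    "CableConfig",
    "CableResult",
    "diffusion_coefficient",
    "run_cable",
    "integrate_fiber",
    "measure_cv",
    "detect_block",
]


def diffusion_coefficient(radius_um: float, ri_kohm_cm: float,
                          cm_uf_cm2: float = 1.0) -> float:
    """Monodomain D in cm^2/ms from fiber radius and axial resistivity."""
    a_cm = radius_um * 1e-4
    ri_ohm_cm = ri_kohm_cm * 1e3
    cm_f_cm2 = cm_uf_cm2 * 1e-6
    d_cm2_s = a_cm / (2.0 * ri_ohm_cm * cm_f_cm2)
    return d_cm2_s * 1e-3


@dataclass
class CableConfig:
    """Geometry, membrane modifiers and pacing for one cable run."""

    species: str = "human"
    n_cells: int = 100
    cell_length_um: float = 100.0
    cell_radius_um: float = 10.0
    ri_kohm_cm: float = 0.4
    cm_uf_cm2: float = 1.0
    nodes_per_cell: int = 1      # >1 refines dx for convergence checks
    dt: float = 0.01
    x_level: float = 0.0
    gbar_1x: float | None = None
    gNa_scale: float = 1.0
    conductance_scales: dict = field(default_factory=dict)
    pacing_hz: float | None = None
    n_beats: int = 2             # conditioning beats + 1 measured beat
    stim_cells: int = 3
    stim_amplitude: float = 100.0
    stim_duration_ms: float = 1.0
    record_dt: float = 1.0
    activation_threshold: float = -20.0
    prepace_beats: int = 30
    prepace_criterion_pct: float = 0.01

    def __post_init__(self):
        if self.n_cells < 10:
            raise InvalidInputError("n_cells must be >= 10")
        for name in ("cell_length_um", "cell_radius_um", "ri_kohm_cm",
                     "cm_uf_cm2", "dt"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")

    @property
    def dx_cm(self) -> float:
        return self.cell_length_um * 1e-4 / self.nodes_per_cell

    @property
    def n_nodes(self) -> int:
        return self.n_cells * self.nodes_per_cell

    @property
    def diffusion_cm2_ms(self) -> float:
        return diffusion_coefficient(self.cell_radius_um, self.ri_kohm_cm,
                                     self.cm_uf_cm2)


@dataclass
class CableResult:
    """Traces and activation analysis of the final (measured) beat."""

    config: CableConfig
    positions_cm: np.ndarray
    t_rec: np.ndarray
    vm: np.ndarray               # (n_nodes, n_samples)
    activation_time: np.ndarray  # ms, nan where unactivated
    activated: np.ndarray        # bool
    blocked: bool
    last_activated_cm: float
    cv_cm_s: float | None


def integrate_fiber(
    model,
    S,
    P,
    *,
    d_cm2_ms: float,
    dx_cm: float,
    dt: float,
    duration_ms: float,
    stim_mask,
    stim_amplitude: float,
    stim_duration_ms: float,
    activation_threshold: float = -20.0,
    record_dt: float | None = None,
    track_activation: bool = True,
):
    """Integrate a fiber for ``duration_ms``; state updated in place.

    Operator-split explicit scheme: the ionic kernel advances membrane and
    gating states, then the diffusion term ``D * lap(V)`` is added.
    Returns ``(t_rec, vm_rec, act_time, activated, dvdt_max)``; recording
    entries are None when ``record_dt`` is None.
    """
    n = S.shape[1]
    n_steps = int(round(duration_ms / dt))
    stim_steps = max(1, int(round(stim_duration_ms / dt)))
    istim_on = np.where(stim_mask, stim_amplitude, 0.0)
    istim_off = np.zeros(n)
    clamped = np.zeros(n, dtype=np.bool_)
    iout = np.empty((len(model.CURRENT_NAMES) if hasattr(model, "CURRENT_NAMES")
                     else model.n_current, n))
    step = model.step
    alpha = d_cm2_ms / dx_cm ** 2

    act_time = np.full(n, np.nan)
    activated = np.zeros(n, dtype=bool)
    dvdt_best = np.zeros(n)

    rec_t = rec_v = None
    if record_dt is not None:
        every = max(1, int(round(record_dt / dt)))
        n_rec = n_steps // every + 1
        rec_t = np.empty(n_rec)
        rec_v = np.empty((n, n_rec))
        k_rec = 0

    v_prev = S[0].copy()
    for k in range(n_steps):
        t = k * dt
        if record_dt is not None and k % every == 0:
            rec_t[k_rec] = t
            rec_v[:, k_rec] = S[0]
            k_rec += 1
        istim = istim_on if k < stim_steps else istim_off
        step(S, P, dt, istim, clamped, iout)
        v = S[0]
        lap = np.empty(n)
        lap[1:-1] = v[:-2] - 2.0 * v[1:-1] + v[2:]
        lap[0] = v[1] - v[0]
        lap[-1] = v[-2] - v[-1]
        v += dt * alpha * lap
        if track_activation:
            dvdt = (v - v_prev) / dt
            better = dvdt > dvdt_best
            dvdt_best[better] = dvdt[better]
            act_time[better] = t + dt
            activated |= v >= activation_threshold
        v_prev[:] = v
        if k % 1000 == 0:
            _check_finite(S, model if hasattr(model, "state_names")
                          else _ModelShim(model), t)
    act_time[~activated] = np.nan
    if record_dt is not None:
        rec_t = rec_t[:k_rec]
        rec_v = rec_v[:, :k_rec]
    return rec_t, rec_v, act_time, activated, dvdt_best


class _ModelShim:
    def __init__(self, module):
        self.state_names = module.STATE_NAMES


def run_cable(config: CableConfig, initial_state=None) -> CableResult:
    """Run the paced cable experiment described by ``config``.

    The single-cell equilibrium (pre-paced with the configured beat
    budget) is tiled along the cable, ``n_beats - 1`` conditioning beats
    are propagated, and activation/CV analysis is performed on the final
    beat.
    """
    model = get_model(config.species)
    cell = build_cell(
        config.species,
        x_level=config.x_level,
        gbar_1x=config.gbar_1x,
        gNa_scale=config.gNa_scale,
        conductance_scales=config.conductance_scales,
        pacing_hz=config.pacing_hz,
        dt=config.dt,
    )
    if initial_state is None:
        pace_to_equilibrium(cell, criterion_pct=config.prepace_criterion_pct,
                            max_beats=config.prepace_beats)
        initial_state = cell.state
    n = config.n_nodes
    S = np.repeat(np.asarray(initial_state).reshape(-1, 1), n, axis=1)
    P = np.repeat(cell.params.reshape(-1, 1), n, axis=1)

    stim_mask = np.zeros(n, dtype=bool)
    stim_mask[: config.stim_cells * config.nodes_per_cell] = True
    cl = 1000.0 / cell.pacing_hz

    kwargs = dict(
        d_cm2_ms=config.diffusion_cm2_ms,
        dx_cm=config.dx_cm,
        dt=config.dt,
        stim_mask=stim_mask,
        stim_amplitude=config.stim_amplitude,
        stim_duration_ms=config.stim_duration_ms,
        activation_threshold=config.activation_threshold,
    )
    for _ in range(max(0, config.n_beats - 1)):
        integrate_fiber(model.module, S, P, duration_ms=cl,
                        track_activation=False, **kwargs)
    t_rec, vm, act_time, activated, _ = integrate_fiber(
        model.module, S, P, duration_ms=cl, record_dt=config.record_dt,
        **kwargs)

    positions = (np.arange(n) + 0.5) * config.dx_cm
    blocked, last_cm = detect_block(activated, positions, stim_mask)
    cv = None
    if not blocked:
        try:
            cv = measure_cv(act_time, positions,
                            fit_window=_central_window(config))
        except (ConductionBlockError, EstimatorDegenerateError):
            cv = None
    return CableResult(
        config=config,
        positions_cm=positions,
        t_rec=t_rec,
        vm=vm,
        activation_time=act_time,
        activated=activated,
        blocked=blocked,
        last_activated_cm=last_cm,
        cv_cm_s=cv,
    )


def _central_window(config: CableConfig):
    lo = int(0.3 * config.n_nodes)
    hi = int(0.7 * config.n_nodes)
    return lo, hi


def measure_cv(activation_times, positions_cm, fit_window=None) -> float:
    """CV (cm/s) from a least-squares fit of position on activation time.

    Raises :class:`ConductionBlockError` if any node inside the window
    never activated and :class:`EstimatorDegenerateError` for a flat
    (simultaneous) front.
    """
    act = np.asarray(activation_times, dtype=float)
    pos = np.asarray(positions_cm, dtype=float)
    if fit_window is None:
        lo, hi = 0, act.size
    else:
        lo, hi = fit_window
    act = act[lo:hi]
    pos = pos[lo:hi]
    if np.isnan(act).any():
        raise ConductionBlockError(
            "CV undefined: unactivated node inside the fit window")
    if act.size < 5:
        raise InvalidInputError("need >= 5 activated positions in the window")
    spread = act.max() - act.min()
    if spread <= 1e-9:
        raise EstimatorDegenerateError(
            "all activation times equal; front speed unresolvable")
    slope = np.polyfit(act, pos, 1)[0]  # cm/ms
    return float(slope * 1000.0)


def detect_block(activated, positions_cm, stim_mask, ):
    """(blocked?, furthest activated position).

    Block = any node beyond the stimulated region failed to activate.
    """
    activated = np.asarray(activated, dtype=bool)
    beyond = ~np.asarray(stim_mask, dtype=bool)
    blocked = bool((~activated[beyond]).any())
    if activated.any():
        last = float(np.asarray(positions_cm)[activated].max())
    else:
        last = 0.0
    return blocked, last
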