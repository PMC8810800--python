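"""2D monodomain tissue with nonconducting obstacles.

A 1 cm x 1 cm sheet is discretized into 100 x 100 nodes
(dx = dy = 0.01 cm) carrying the human ventricular membrane model.
Fibrotic obstacles are modeled by *disconnecting* nodes: every conductive
edge into or out of an obstacle node is severed (conductivity zero) and
the node carries no membrane model.  Two obstacle geometries are
provided: uniformly random isotropic nodes, and vertically elongated
1-node-wide strips mimicking interstitial fibrosis.

Conduction is initiated from a corner patch and quantified by an
activation map and an average conduction velocity: the trimmed median of
local front speeds ``1/|grad T|`` from central differences of the
activation-time field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cable1d import diffusion_coefficient
from .cell import build_cell, pace_to_equilibrium, _check_finite
from .errors import (
    ConductionBlockError,
    InvalidInputError,
    PlacementFailureError,
)
from .models import get_model

__all__ = [
    "TissueGrid",
    "ActivationMap",
    "generate_random_obstacles",
    "generate_vertical_obstacles",
    "run_tissue",
    "average_cv_2d",
]


def _check_fraction(fraction):
    if not (0.0 <= fraction < 1.0):
        raise InvalidInputError(f"fraction must be in [0, 1), got {fraction}")


def obstacle_count(nx: int, ny: int, fraction: float) -> int:
    """Exact obstacle-node count contract: round(fraction * nx * ny)."""
    return int(round(fraction * nx * ny))


def generate_random_obstacles(nx: int, ny: int, fraction: float,
                              seed: int) -> np.ndarray:
    """Random isotropic obstacle mask, exactly round(fraction*nx*ny) nodes.

    Nodes are drawn uniformly without replacement with a seeded generator,
    so the mask is reproducible for a fixed seed.
    """
    _check_fraction(fraction)
    count = obstacle_count(nx, ny, fraction)
    rng = np.random.default_rng(seed)
    mask = np.zeros(ny * nx, dtype=bool)
    if count:
        idx = rng.choice(ny * nx, size=count, replace=False)
        mask[idx] = True
    return mask.reshape(ny, nx)


def generate_vertical_obstacles(nx: int, ny: int, fraction: float,
                                strip_length: int, seed: int,
                                max_attempts: int = 200000) -> np.ndarray:
    """Vertically elongated obstacle mask with the exact count contract.

    1-node-wide vertical strips of ``strip_length`` nodes are dropped at
    seeded random positions (clipped at the bottom border, overlaps
    merged) until coverage reaches the target, then the last strip is
    trimmed to land exactly on round(fraction*nx*ny) nodes.
    """
    _check_fraction(fraction)
    if not (1 <= strip_length <= ny):
        raise InvalidInputError(
            f"strip_length must be in [1, {ny}], got {strip_length}")
    target = obstacle_count(nx, ny, fraction)
    rng = np.random.default_rng(seed)
    mask = np.zeros((ny, nx), dtype=bool)
    count = 0
    attempts = 0
    while count < target:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementFailureError(
                f"could not reach coverage {target} after {attempts} strips")
        x = int(rng.integers(0, nx))
        y0 = int(rng.integers(0, ny))
        y1 = min(ny, y0 + strip_length)
        col = mask[y0:y1, x]
        fresh = np.flatnonzero(~col)
        room = target - count
        if fresh.size > room:
            fresh = fresh[:room]  # trim the final strip to the exact count
        col[fresh] = True
        count += fresh.size
    return mask


@dataclass
class TissueGrid:
    """2D simulation domain: membrane modifiers plus an obstacle mask."""

    nx: int = 100
    ny: int = 100
    dx_cm: float = 0.01
    species: str = "human"
    obstacle_mask: np.ndarray | None = None   # (ny, nx) bool
    seed: int | None = None
    x_level: float = 0.0
    gbar_1x: float | None = None
    gNa_scale: float = 1.0
    cell_radius_um: float = 10.0
    ri_kohm_cm: float = 0.4
    cm_uf_cm2: float = 1.0
    dt: float = 0.01
    pacing_hz: float | None = None
    prepace_beats: int = 30
    prepace_criterion_pct: float = 0.01

    def __post_init__(self):
        if self.obstacle_mask is None:
            self.obstacle_mask = np.zeros((self.ny, self.nx), dtype=bool)
        self.obstacle_mask = np.asarray(self.obstacle_mask, dtype=bool)
        if self.obstacle_mask.shape != (self.ny, self.nx):
            raise InvalidInputError("obstacle mask shape must be (ny, nx)")

    @property
    def diffusion_cm2_ms(self) -> float:
        return diffusion_coefficient(self.cell_radius_um, self.ri_kohm_cm,
                                     self.cm_uf_cm2)


@dataclass
class StimPatch:
    """Rectangular stimulus patch (node indices, top-left corner default)."""

    x0: int = 0
    y0: int = 0
    size: int = 15
    amplitude: float = 100.0
    duration_ms: float = 1.0


@dataclass
class ActivationMap:
    """Per-node activation times plus summary conduction statistics."""

    activation_time: np.ndarray    # (ny, nx) ms; nan = obstacle/unactivated
    obstacle_mask: np.ndarray
    stim_origin: tuple
    activated_fraction: float      # of non-obstacle nodes
    average_cv_cm_s: float | None
    seed: int | None = None

    @property
    def blocked(self) -> bool:
        return self.activated_fraction < 0.95


def _edge_weights(mask):
    """Conductive edge indicators; edges touching an obstacle are severed."""
    open_ = ~mask
    we = np.zeros_like(open_, dtype=float)
    we[:, :-1] = open_[:, :-1] & open_[:, 1:]
    ww = np.zeros_like(we)
    ww[:, 1:] = we[:, :-1]
    ws = np.zeros_like(we)
    ws[:-1, :] = open_[:-1, :] & open_[1:, :]
    wn = np.zeros_like(we)
    wn[1:, :] = ws[:-1, :]
    return wn, ws, we, ww


def laplacian(v, weights):
    """5-point graph Laplacian with severed edges and no-flux borders."""
    wn, ws, we, ww = weights
    lap = np.zeros_like(v)
    lap[:, :-1] += we[:, :-1] * (v[:, 1:] - v[:, :-1])
    lap[:, 1:] += ww[:, 1:] * (v[:, :-1] - v[:, 1:])
    lap[:-1, :] += ws[:-1, :] * (v[1:, :] - v[:-1, :])
    lap[1:, :] += wn[1:, :] * (v[:-1, :] - v[1:, :])
    return lap


def run_tissue(
    grid: TissueGrid,
    stim: StimPatch | None = None,
    *,
    initial_state=None,
    t_max_ms: float = 200.0,
    activation_threshold: float = -20.0,
    quiescence_ms: float = 30.0,
    record_dt: float | None = None,
):
    """Integrate one corner-paced beat and return the activation map.

    The membrane model lives only on non-obstacle nodes; obstacle nodes
    have no state and all their conductive connections severed.  The run
    stops early once every non-obstacle node has activated (plus a small
    margin) or when no new node has activated for ``quiescence_ms``
    (established block).

    Returns ``(ActivationMap, movie)`` where movie is ``None`` or
    ``(t_rec, vm_frames)`` with obstacle nodes as nan.
    """
    if stim is None:
        stim = StimPatch()
    model = get_model(grid.species)
    mask = grid.obstacle_mask
    ny, nx = mask.shape
    active_idx = np.flatnonzero(~mask.ravel())
    n = active_idx.size
    if n == 0:
        raise InvalidInputError("no conducting nodes in grid")

    cell = build_cell(
        grid.species,
        x_level=grid.x_level,
        gbar_1x=grid.gbar_1x,
        gNa_scale=grid.gNa_scale,
        pacing_hz=grid.pacing_hz,
        dt=grid.dt,
    )
    if initial_state is None:
        pace_to_equilibrium(cell, criterion_pct=grid.prepace_criterion_pct,
                            max_beats=grid.prepace_beats)
        initial_state = cell.state
    S = np.repeat(np.asarray(initial_state).reshape(-1, 1), n, axis=1)
    P = np.repeat(cell.params.reshape(-1, 1), n, axis=1)

    weights = _edge_weights(mask)
    rest_v = float(np.asarray(initial_state)[0])
    vfull = np.full((ny, nx), rest_v)

    stim_mask2d = np.zeros((ny, nx), dtype=bool)
    stim_mask2d[stim.y0:stim.y0 + stim.size, stim.x0:stim.x0 + stim.size] = True
    istim_on = np.where(stim_mask2d.ravel()[active_idx], stim.amplitude, 0.0)
    istim_off = np.zeros(n)
    clamped = np.zeros(n, dtype=np.bool_)
    iout = np.empty((model.n_current, n))

    dt = grid.dt
    alpha = grid.diffusion_cm2_ms / grid.dx_cm ** 2
    n_steps = int(round(t_max_ms / dt))
    stim_steps = max(1, int(round(stim.duration_ms / dt)))

    act_time = np.full(n, np.nan)
    activated = np.zeros(n, dtype=bool)
    dvdt_best = np.zeros(n)
    v_prev = S[0].copy()
    last_new_activation = 0.0

    movie_t, movie_v = [], []
    rec_every = None if record_dt is None else max(1, int(round(record_dt / dt)))

    step = model.step
    for k in range(n_steps):
        t = k * dt
        if rec_every is not None and k % rec_every == 0:
            frame = np.full((ny, nx), np.nan)
            frame.ravel()[active_idx] = S[0]
            movie_t.append(t)
            movie_v.append(frame)
        istim = istim_on if k < stim_steps else istim_off
        step(S, P, dt, istim, clamped, iout)
        v = S[0]
        vfull.ravel()[active_idx] = v
        lap = laplacian(vfull, weights).ravel()[active_idx]
        v += dt * alpha * lap
        dvdt = (v - v_prev) / dt
        better = dvdt > dvdt_best
        dvdt_best[better] = dvdt[better]
        act_time[better] = t + dt
        newly = (v >= activation_threshold) & ~activated
        if newly.any():
            activated |= newly
            last_new_activation = t
        v_prev[:] = v
        if k % 1000 == 0:
            _check_finite(S, model, t)
            if activated.all() and t > last_new_activation + 5.0:
                break
            if t - last_new_activation > quiescence_ms and t > 20.0:
                break

    act_time[~activated] = np.nan
    tmap = np.full((ny, nx), np.nan)
    tmap.ravel()[active_idx] = act_time
    frac = float(activated.mean())

    amap = ActivationMap(
        activation_time=tmap,
        obstacle_mask=mask,
        stim_origin=(stim.y0, stim.x0),
        activated_fraction=frac,
        average_cv_cm_s=None,
        seed=grid.seed,
    )
    if frac >= 0.95:
        amap.average_cv_cm_s = average_cv_2d(amap, dx_cm=grid.dx_cm)
    movie = None
    if rec_every is not None:
        movie = (np.array(movie_t), np.array(movie_v))
    return amap, movie


def _block_nanmean(a, block):
    """Block-average a 2D field, ignoring nans inside each block."""
    ny, nx = a.shape
    by, bx = ny // block, nx // block
    trimmed = a[: by * block, : bx * block]
    tiles = trimmed.reshape(by, block, bx, block).swapaxes(1, 2)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(tiles.reshape(by, bx, block * block), axis=2)
    return out


def average_cv_2d(amap: ActivationMap, dx_cm: float = 0.01,
                  trim: float = 0.05, coarse_block: int = 5) -> float:
    """Average macroscopic conduction speed (cm/s) from the activation map.

    The activation-time field is first block-averaged over
    ``coarse_block x coarse_block`` patches (nan-aware, so obstacle nodes
    drop out) and local front speed ``1/|grad T|`` is then evaluated by
    central differences on the coarsened field.  Coarse-graining makes the
    isochrone spacing -- and hence the estimate -- reflect the macroscopic
    front progression including obstacle-induced detours, which per-node
    gradients miss because they only sample the unobstructed interior
    where the front travels at its intrinsic speed.  The top and bottom
    ``trim`` fraction of local speeds are discarded and the median of the
    rest is returned.
    """
    tmap = amap.activation_time
    if amap.activated_fraction < 0.95:
        raise ConductionBlockError(
            f"average CV undefined: only {amap.activated_fraction:.2f} "
            "of nodes activated")
    coarse = _block_nanmean(tmap, coarse_block)
    gy, gx = np.gradient(coarse, dx_cm * coarse_block)   # ms/cm
    gmag = np.hypot(gx, gy)
    valid = np.isfinite(gmag) & (gmag > 1e-12)
    speeds = 1000.0 / gmag[valid]        # cm/s
    if speeds.size < 10:
        raise ConductionBlockError("too few valid local speeds")
    lo, hi = np.quantile(speeds, [trim, 1.0 - trim])
    mid = speeds[(speeds >= lo) & (speeds <= hi)]
    return float(np.median(mid))
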