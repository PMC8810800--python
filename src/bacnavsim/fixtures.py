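"""Synthetic inputs: toy excitable cell, analytic test fields, canonical
experiment configurations.

The toy model (see :mod:`bacnavsim.models.toy`) gives the PDE machinery a
fast membrane with documented stable parameters; the analytic fields
provide closed-form ground truth for the CV estimator and the pseudo-ECG
quadrature; the canonical configs enumerate the headline in-silico
experiments (single-cell dose series, 1D cable series, 2D obstacle
tissues, Brugada cable grid) with the stated geometry and disease
parameters.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError
from .cell import CellModel, build_cell
from .models import get_model

__all__ = [
    "make_toy_model",
    "toy_fine_reference",
    "planar_front",
    "circular_front",
    "gaussian_wave",
    "canonical_configs",
]

#: documented stable region for the toy parameters
TOY_STABLE = {"k": (1.0, 20.0), "a": (0.01, 0.49), "eps0": (1e-4, 0.1),
              "mu1": (0.01, 1.0), "mu2": (0.01, 1.0)}


def make_toy_model(params: dict | None = None, *, dt: float = 0.01,
                   pacing_hz: float = 10.0) -> CellModel:
    """Two-variable excitable toy cell with validated parameters."""
    model = get_model("toy")
    p = dict(zip(model.param_names, model.default_params))
    p.update(params or {})
    for name, (lo, hi) in TOY_STABLE.items():
        if not (lo <= p[name] <= hi):
            raise InvalidInputError(
                f"toy parameter {name}={p[name]} outside stable "
                f"region [{lo}, {hi}]")
    cell = build_cell("toy", pacing_hz=pacing_hz, dt=dt)
    for name in model.param_names:
        cell.params[model.param_names.index(name)] = p[name]
    return cell


def toy_fine_reference(params: dict | None = None, *, dt: float = 1e-3,
                       duration_ms: float = 120.0,
                       stim=(30.0, 1.0)):
    """Fine-step reference trajectory of a single stimulated toy beat.

    Serves as the stored-oracle stand-in: recomputed at run time with a
    10x finer step than the production default.
    """
    cell = make_toy_model(params, dt=dt)
    cell.stim_amplitude, cell.stim_duration = stim
    cell.pacing_hz = 1000.0 / duration_ms
    t, v, _ = cell.run_beat(record_dt=0.1)
    return t, v


def planar_front(nx=100, ny=100, dx_cm=0.01, speed_cm_s=30.0):
    """Activation-time field of an ideal planar front moving along +x."""
    x = (np.arange(nx) + 0.5) * dx_cm
    tmap = np.tile(x / (speed_cm_s / 1000.0), (ny, 1))
    return tmap


def circular_front(nx=100, ny=100, dx_cm=0.01, speed_cm_s=30.0,
                   origin=(0.0, 0.0)):
    """Activation-time field of a circular front from a corner origin."""
    x = (np.arange(nx) + 0.5) * dx_cm
    y = (np.arange(ny) + 0.5) * dx_cm
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx - origin[0], yy - origin[1])
    return r / (speed_cm_s / 1000.0)


def gaussian_wave(n_x=165, dx_cm=0.01, n_t=300, dt_ms=1.0,
                  speed_cm_ms=0.04, width_cm=0.15, amplitude_mv=100.0,
                  baseline_mv=-80.0, center0_cm=0.4):
    """Traveling Gaussian depolarization wave Vm(t, x) for ECG oracles.

    The wave starts ``center0_cm`` inside the fiber so that early frames
    are not truncated by the boundary.
    """
    x = (np.arange(n_x) + 0.5) * dx_cm
    t = np.arange(n_t) * dt_ms
    center = center0_cm + speed_cm_ms * t
    vm = baseline_mv + amplitude_mv * np.exp(
        -((x[:, None] - center[None, :]) ** 2) / (2.0 * width_cm ** 2))
    return t, vm, x


def canonical_configs() -> dict:
    """One config dict per headline experiment.

    Keys group by stage; every dict is consumable by
    :func:`bacnavsim.io.run_experiment` after adding an ``outdir``.
    """
    configs = {}
    doses = (0.0, 0.5, 1.0, 2.0)
    for gna, tag in ((1.0, "normal"), (0.5, "reduced")):
        for x in doses:
            configs[f"cell_human_{tag}_{x:g}x"] = {
                "stage": "cell",
                "species": "human",
                "pacing_hz": 1.0,
                "x_level": x,
                "gbar_1x": "calibrated",
                "gNa_scale": gna,
            }
            configs[f"cable_human_{tag}_{x:g}x"] = {
                "stage": "cable",
                "species": "human",
                "n_cells": 100,
                "cell_length_um": 100.0,
                "cell_radius_um": 10.0,
                "ri_kohm_cm": 0.4,
                "x_level": x,
                "gbar_1x": "calibrated",
                "gNa_scale": gna,
            }
    for x in doses:
        configs[f"tissue_random15_{x:g}x"] = {
            "stage": "tissue",
            "species": "human",
            "pattern": "random",
            "fraction": 0.15,
            "nx": 100, "ny": 100, "dx_cm": 0.01,
            "x_level": x,
            "gbar_1x": "calibrated",
            "seed": 7,
        }
    for x in (0.0, 1.0):
        configs[f"tissue_vertical20_{x:g}x"] = {
            "stage": "tissue",
            "species": "human",
            "pattern": "vertical",
            "fraction": 0.20,
            "strip_length": 10,
            "nx": 100, "ny": 100, "dx_cm": 0.01,
            "x_level": x,
            "gbar_1x": "calibrated",
            "seed": 7,
        }
    configs["tissue_homogeneous_0x"] = {
        "stage": "tissue",
        "species": "human",
        "pattern": "random",
        "fraction": 0.0,
        "nx": 100, "ny": 100, "dx_cm": 0.01,
        "x_level": 0.0,
        "seed": 7,
    }
    for severity in ("none", "mild", "severe"):
        for x in (0.0, 0.2, 0.5):
            configs[f"brugada_{severity}_{x:g}x"] = {
                "stage": "brugada",
                "severity": severity,
                "x_level": x,
                "gbar_1x": "calibrated",
                "pacing_hz": 2.5,
            }
    return configs
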