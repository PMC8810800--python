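"""Config parsing, experiment driving, structured result writing.

Every run directory receives a ``manifest.json`` recording the config
hash, seeds, software version, per-stage runtimes and the output file
registry.  Grids (activation maps, obstacle masks) are written as CSV
with the literal string ``NA`` marking obstacle/not-activated sentinels;
summaries as JSON with full double precision; traces as tidy CSV.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .brugada import (
    SEVERITIES,
    apply_brugada,
    build_transmural_cable,
    ecg_deviation,
    run_transmural,
)
from .cable1d import CableConfig, run_cable
from .calibration import calibrate_1x, calibrated_gbar_1x
from .cell import build_cell, pace_to_equilibrium, simulate_ap
from .errors import ConfigError
from .metrics import extract_features
from .tissue2d import (
    TissueGrid,
    generate_random_obstacles,
    generate_vertical_obstacles,
    run_tissue,
)

__all__ = ["load_config", "run_experiment", "export_activation_map",
           "read_activation_map", "RunManifest"]

STAGES = ("calibrate", "cell", "cable", "tissue", "brugada")

NA = "NA"


def load_config(path) -> dict:
    """Read a YAML/JSON experiment config."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            cfg = yaml.safe_load(fh)
        else:
            cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping", field="<root>")
    return cfg


def _require(cfg, key, typ, default=None, lo=None, hi=None):
    val = cfg.get(key, default)
    if val is None:
        raise ConfigError(f"missing required config key {key!r}", field=key)
    if typ is float and isinstance(val, int):
        val = float(val)
    if not isinstance(val, typ):
        raise ConfigError(
            f"config key {key!r} must be {typ.__name__}, got {type(val).__name__}",
            field=key)
    if lo is not None and val < lo:
        raise ConfigError(f"config key {key!r} must be >= {lo}", field=key)
    if hi is not None and val >= hi:
        raise ConfigError(f"config key {key!r} must be < {hi}", field=key)
    return val


@dataclass
class RunManifest:
    """Provenance record for one run directory (append-only)."""

    config_hash: str
    version: str
    seeds: dict = field(default_factory=dict)
    runtimes_s: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    status: str = "running"

    def write(self, outdir: Path):
        path = Path(outdir) / "manifest.json"
        entries = []
        if path.exists():
            entries = json.loads(path.read_text())
        entries.append(asdict(self))
        path.write_text(json.dumps(entries, indent=2))


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _resolve_gbar(cfg):
    x = float(cfg.get("x_level", 0.0) or 0.0)
    if x == 0.0:
        return 0.0, None
    g = cfg.get("gbar_1x", "calibrated")
    if g == "calibrated":
        g = calibrated_gbar_1x(cfg.get("species", "human"))
    return x, float(g)


def run_experiment(config, outdir, seed: int = 0) -> Path:
    """Execute the stage named in ``config`` and write results + manifest.

    ``config`` may be a path or a dict.  Returns the run directory.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = _require(config, "stage", str)
    if stage not in STAGES:
        raise ConfigError(
            f"unknown stage {stage!r}; expected one of {STAGES}",
            field="stage")
    manifest = RunManifest(config_hash=_config_hash(config),
                           version=__version__,
                           seeds={"seed": seed})
    t0 = time.time()
    try:
        summary = _STAGE_RUNNERS[stage](config, outdir, seed, manifest)
        manifest.status = "ok"
    except Exception:
        manifest.status = "failed"
        manifest.runtimes_s[stage] = time.time() - t0
        manifest.write(outdir)
        raise
    manifest.runtimes_s[stage] = time.time() - t0
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    manifest.outputs.append(str(summary_path))
    manifest.write(outdir)
    return outdir


def _stage_calibrate(cfg, outdir, seed, manifest):
    species = cfg.get("species", "human")
    cell = build_cell(species)
    report = calibrate_1x(cell)
    return report.to_dict()


def _stage_cell(cfg, outdir, seed, manifest):
    species = cfg.get("species", "human")
    x, gbar = _resolve_gbar(cfg)
    cell = build_cell(
        species,
        x_level=x,
        gbar_1x=gbar,
        gNa_scale=float(cfg.get("gNa_scale", 1.0)),
        pacing_hz=cfg.get("pacing_hz"),
        dt=float(cfg.get("dt_ms", 0.01)),
    )
    pr = pace_to_equilibrium(
        cell,
        criterion_pct=float(cfg.get("criterion_pct", 0.01)),
        max_beats=int(cfg.get("max_beats", 30)),
    )
    tr = simulate_ap(cell)
    feats = extract_features(tr.t, tr.vm)
    trace_path = outdir / "trace.csv"
    _write_trace_csv(trace_path, tr)
    manifest.outputs.append(str(trace_path))
    return {
        "species": species, "x_level": x, "gbar_1x": gbar,
        "converged": pr.converged, "beats": pr.beats,
        "max_rel_change_pct": pr.max_rel_change_pct,
        "rmp_mV": feats.rmp, "apa_mV": feats.apa,
        "apd_ms": {str(k): v for k, v in feats.apd.items()},
        "dvdt_max_V_s": feats.dvdt_max,
    }


def _stage_cable(cfg, outdir, seed, manifest):
    x, gbar = _resolve_gbar(cfg)
    cc = CableConfig(
        species=cfg.get("species", "human"),
        n_cells=int(cfg.get("n_cells", 100)),
        cell_length_um=float(cfg.get("cell_length_um", 100.0)),
        cell_radius_um=float(cfg.get("cell_radius_um", 10.0)),
        ri_kohm_cm=float(cfg.get("ri_kohm_cm", 0.4)),
        dt=float(cfg.get("dt_ms", 0.01)),
        x_level=x,
        gbar_1x=gbar,
        gNa_scale=float(cfg.get("gNa_scale", 1.0)),
        pacing_hz=cfg.get("pacing_hz"),
        prepace_beats=int(cfg.get("prepace_beats", 30)),
    )
    res = run_cable(cc)
    act_path = outdir / "activation_times.csv"
    with open(act_path, "w") as fh:
        fh.write("position_cm,activation_ms\n")
        for xpos, tact in zip(res.positions_cm, res.activation_time):
            fh.write(f"{xpos!r},{tact!r}\n".replace("nan", NA))
    manifest.outputs.append(str(act_path))
    return {
        "species": cc.species, "x_level": x, "gNa_scale": cc.gNa_scale,
        "blocked": res.blocked,
        "cv_cm_s": res.cv_cm_s,
        "last_activated_cm": res.last_activated_cm,
    }


def _stage_tissue(cfg, outdir, seed, manifest):
    nx = _require(cfg, "nx", int, 100)
    ny = _require(cfg, "ny", int, 100)
    fraction = _require(cfg, "fraction", float, 0.0, lo=0.0, hi=1.0)
    pattern = cfg.get("pattern", "random")
    mask_seed = int(cfg.get("seed", seed))
    if pattern == "random":
        mask = generate_random_obstacles(nx, ny, fraction, mask_seed)
    elif pattern == "vertical":
        mask = generate_vertical_obstacles(
            nx, ny, fraction, int(cfg.get("strip_length", 10)), mask_seed)
    else:
        raise ConfigError(f"unknown obstacle pattern {pattern!r}",
                          field="pattern")
    x, gbar = _resolve_gbar(cfg)
    grid = TissueGrid(
        nx=nx, ny=ny, dx_cm=float(cfg.get("dx_cm", 0.01)),
        species=cfg.get("species", "human"),
        obstacle_mask=mask, seed=mask_seed,
        x_level=x, gbar_1x=gbar,
        gNa_scale=float(cfg.get("gNa_scale", 1.0)),
        dt=float(cfg.get("dt_ms", 0.01)),
        prepace_beats=int(cfg.get("prepace_beats", 30)),
    )
    amap, _ = run_tissue(grid)
    mask_path = outdir / "obstacle_mask.csv"
    np.savetxt(mask_path, mask.astype(int), fmt="%d", delimiter=",")
    map_path = outdir / "activation_map.csv"
    export_activation_map(amap, map_path)
    manifest.outputs += [str(mask_path), str(map_path)]
    manifest.seeds["obstacle_seed"] = mask_seed
    return {
        "pattern": pattern, "fraction": fraction, "seed": mask_seed,
        "x_level": x, "obstacle_nodes": int(mask.sum()),
        "activated_fraction": amap.activated_fraction,
        "average_cv_cm_s": amap.average_cv_cm_s,
        "blocked": amap.blocked,
    }


def _stage_brugada(cfg, outdir, seed, manifest):
    severity_name = cfg.get("severity", "none")
    if severity_name not in SEVERITIES:
        raise ConfigError(
            f"unknown severity {severity_name!r}; expected "
            f"{sorted(SEVERITIES)}", field="severity")
    x = float(cfg.get("x_level", 0.0) or 0.0)
    gbar = None
    if x > 0:
        g = cfg.get("gbar_1x", "calibrated")
        gbar = (calibrated_gbar_1x("human") if g == "calibrated"
                else float(g))
    cable = build_transmural_cable(
        x_level=x, gbar_1x=gbar,
        pacing_hz=float(cfg.get("pacing_hz", 2.5)))
    cable = apply_brugada(cable, SEVERITIES[severity_name])
    res = run_transmural(
        cable, prepace_beats=int(cfg.get("prepace_beats", 30)))
    ecg_path = outdir / "pseudo_ecg.csv"
    with open(ecg_path, "w") as fh:
        fh.write("t_ms,phi_e\n")
        for tt, p in zip(res.ecg.t, res.ecg.phi_e):
            fh.write(f"{tt!r},{p!r}\n")
    manifest.outputs.append(str(ecg_path))
    for name, idx in res.layer_cells.items():
        p = outdir / f"ap_{name}_cell{idx}.csv"
        with open(p, "w") as fh:
            fh.write("t_ms,vm_mV\n")
            for tt, vv in zip(res.t, res.vm[idx - 1]):
                fh.write(f"{tt!r},{vv!r}\n")
        manifest.outputs.append(str(p))
    out = {
        "severity": severity_name, "x_level": x,
        "ecg_samples": len(res.ecg.t),
    }
    healthy_dir = cfg.get("healthy_ecg")
    if healthy_dir:
        import pandas as pd

        ref = pd.read_csv(Path(healthy_dir))
        from .brugada import EcgTrace

        healthy = EcgTrace(t=ref["t_ms"].to_numpy(),
                           phi_e=ref["phi_e"].to_numpy(),
                           electrode_cm=res.ecg.electrode_cm)
        out["ecg_deviation"] = ecg_deviation(res.ecg, healthy)
    return out


_STAGE_RUNNERS = {
    "calibrate": _stage_calibrate,
    "cell": _stage_cell,
    "cable": _stage_cable,
    "tissue": _stage_tissue,
    "brugada": _stage_brugada,
}


def _write_trace_csv(path, tr):
    cols = ["time_ms", "Vm_mV"] + list(tr.currents)
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for k in range(len(tr.t)):
            row = [repr(float(tr.t[k])), repr(float(tr.vm[k]))]
            row += [repr(float(tr.currents[c][k])) for c in tr.currents]
            fh.write(",".join(row) + "\n")


def export_activation_map(amap, path):
    """Write the activation-time grid as CSV; sentinel ``NA`` marks
    obstacle or never-activated nodes."""
    grid = amap.activation_time
    with open(path, "w") as fh:
        for row in grid:
            fh.write(",".join(
                NA if not np.isfinite(v) else repr(float(v))
                for v in row) + "\n")


def read_activation_map(path) -> np.ndarray:
    """Round-trip reader for :func:`export_activation_map` (nan = NA)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            rows.append([np.nan if tok == NA else float(tok)
                         for tok in line.strip().split(",")])
    return np.array(rows)
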