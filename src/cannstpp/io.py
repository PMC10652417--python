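"""Result serialisation: CSV for series and grids, JSON for summaries.

Output formatting is deterministic — writing the same result twice
produces byte-identical files — so runs can be diffed.  Every writer
drops a ``provenance.json`` (config snapshot, its hash, code version)
sufficient to regenerate the numbers without guessing parameters.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .model import RAD_PER_MS_TO_DEG_PER_S
from .protocols import PhaseMapResult, VelocityScan
from .simulate import TrackingResult
from .stability import StabilityMap, StabilityResult

_FLOAT_FMT = "%.10g"


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def write_provenance(outdir: Path, config_dict: Optional[dict]) -> None:
    payload = json.dumps(config_dict, sort_keys=True) if config_dict else ""
    _write_json(
        {
            "package": "cannstpp",
            "version": __version__,
            "config": config_dict,
            "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        },
        outdir / "provenance.json",
    )


def write_tracking(
    result: TrackingResult, output_dir, name: str = "track",
    config_dict: Optional[dict] = None,
) -> list:
    """``<name>.csv`` (t_ms, z_rad, z0_rad, s_rad) + ``<name>_summary.json``."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {"t_ms": result.times, "z_rad": result.z, "z0_rad": result.z0,
         "s_rad": result.s}
    )
    csv_path = outdir / f"{name}.csv"
    frame.to_csv(csv_path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    summary = {k: _jsonable(v) for k, v in result.summary().items()}
    summary["v_ext_deg_per_s"] = _jsonable(result.v_ext * RAD_PER_MS_TO_DEG_PER_S)
    json_path = outdir / f"{name}_summary.json"
    _write_json(summary, json_path)
    write_provenance(outdir, config_dict)
    return [csv_path, json_path]


def write_velocity_scan(
    scan: VelocityScan, output_dir, name: str = "velocity_scan",
    config_dict: Optional[dict] = None,
) -> list:
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {
            "v_ext_rad_per_ms": scan.v_ext,
            "v_ext_deg_per_s": scan.v_ext * RAD_PER_MS_TO_DEG_PER_S,
            "s_rad": scan.s,
            "steady": scan.steady.astype(int),
            "tau_ant_ms": scan.tau_ant,
        }
    )
    csv_path = outdir / f"{name}.csv"
    frame.to_csv(csv_path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    interval = scan.anticipation_interval()
    summary = {
        "A": scan.A,
        "alpha": _jsonable(scan.alpha),
        "beta": _jsonable(scan.beta),
        "anticipation_interval_rad_per_ms": interval,
        "anticipation_interval_deg_per_s": (
            None if interval is None
            else [v * RAD_PER_MS_TO_DEG_PER_S for v in interval]
        ),
        "T_ant_ms": _jsonable(scan.max_anticipatory_time()),
    }
    json_path = outdir / f"{name}_summary.json"
    _write_json(summary, json_path)
    write_provenance(outdir, config_dict)
    return [csv_path, json_path]


def _grid_frame(values: np.ndarray, alphas, betas) -> pd.DataFrame:
    frame = pd.DataFrame(values, index=alphas, columns=betas)
    frame.index.name = "alpha"
    frame.columns.name = "beta"
    return frame


def write_phase_map(
    pm: PhaseMapResult, output_dir, config_dict: Optional[dict] = None
) -> list:
    """``v_int.csv`` and ``t_ant.csv`` with (alpha, beta) axis headers."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, grid_vals in (("v_int", pm.v_int), ("t_ant", pm.T_ant)):
        path = outdir / f"{name}.csv"
        _grid_frame(grid_vals, pm.alpha_values, pm.beta_values).to_csv(
            path, float_format=_FLOAT_FMT, lineterminator="\n"
        )
        paths.append(path)
    summary = {
        "n_static_cells": int(pm.static_mask.sum()),
        "n_collapsed_cells": int(pm.collapsed.sum()),
        "T_ant_max_ms": _jsonable(float(np.nanmax(pm.T_ant))),
        "v_int_max_rad_per_ms": _jsonable(float(np.nanmax(pm.v_int))),
    }
    json_path = outdir / "phase_map_summary.json"
    _write_json(summary, json_path)
    paths.append(json_path)
    write_provenance(outdir, config_dict)
    return paths


def write_stability_map(
    sm: StabilityMap, output_dir, config_dict: Optional[dict] = None
) -> list:
    """Per-cell CSV: alpha, beta, lambda_max, phase."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    AA, BB = np.meshgrid(sm.alpha_values, sm.beta_values, indexing="ij")
    frame = pd.DataFrame(
        {
            "alpha": AA.ravel(),
            "beta": BB.ravel(),
            "lambda_max": sm.lambda_max.ravel(),
            "phase": np.where(sm.phase.ravel(), "moving", "static"),
        }
    )
    csv_path = outdir / "stability.csv"
    frame.to_csv(csv_path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    write_provenance(outdir, config_dict)
    return [csv_path]


def write_stability_result(
    res: StabilityResult, output_dir, config_dict: Optional[dict] = None
) -> list:
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = ("u", "S", "Q")
    entries = {
        f"M_{labels[i]}{labels[j]}": res.M[i, j]
        for i in range(3)
        for j in range(3)
    }
    summary = {
        "matrix": entries,
        "eigenvalues_real": [float(v) for v in res.eigenvalues.real],
        "eigenvalues_imag": [float(v) for v in res.eigenvalues.imag],
        "lambda_max": res.lambda_max,
        "phase": res.phase,
        "fd_error": res.fd_error,
    }
    json_path = outdir / "stability_regime.json"
    _write_json(summary, json_path)
    write_provenance(outdir, config_dict)
    return [json_path]
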