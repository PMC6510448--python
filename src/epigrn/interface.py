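"""Experiment configuration, validation and result serialization.

Every experiment writes its outputs plus a ``manifest.json`` recording the
resolved configuration, seeds, package version and the files produced, so any
numeric result file can be regenerated from its manifest alone.  Outputs are
written to a temporary name and renamed into place (atomic on POSIX).
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import yaml

from . import __version__, er_model
from .er_model import hme_phase_diagram
from .grn_model import grn_phase_diagram
from .params import load_model_file, reference_er_params, reference_grn_params
from .ssa import estimate_transition_times

__all__ = ["run_experiment", "validate_model_file", "write_manifest", "EXPERIMENTS"]


class SchemaError(ValueError):
    """Configuration does not match the experiment schema."""


def _atomic_write(path: str, writer) -> str:
    tmp = f"{path}.tmp"
    writer(tmp)
    os.replace(tmp, path)
    return path


def write_manifest(out_dir: str, config: dict, files: list[str]) -> str:
    manifest = {
        "version": __version__,
        "config": config,
        "files": sorted(os.path.basename(f) for f in files),
    }
    path = os.path.join(out_dir, "manifest.json")
    _atomic_write(path, lambda p: open(p, "w").write(json.dumps(manifest, indent=2, default=str)))
    return path


def _get_er(config):
    name = config.get("system", "ders1")
    if "model_file" in config:
        return load_model_file(config["model_file"])["er_systems"][name]
    return reference_er_params(name)


def _get_grn(config):
    if "model_file" in config:
        model = load_model_file(config["model_file"])
        if model["grn"] is not None:
            return model["grn"]
    return reference_grn_params()


def _exp_phase_grn(config, out_dir, seed):
    n = int(config.get("n_grid", 101))
    hi = float(config.get("upper", 1.2))
    grid = np.linspace(0.0, hi, n)
    labels = grn_phase_diagram(_get_grn(config), grid, grid)
    p1, p2 = np.meshgrid(grid, grid, indexing="ij")
    df = pd.DataFrame({"pfrac1": p1.ravel(), "pfrac2": p2.ravel(), "region": labels.ravel()})
    path = os.path.join(out_dir, "phase_grn.csv")
    _atomic_write(path, lambda p: df.to_csv(p, index=False))
    return [path]


def _exp_phase_hme(config, out_dir, seed):
    params = _get_er(config)
    n = int(config.get("n_grid", 9))
    hi = float(config.get("upper", 3.0)) * params.enzyme_scale
    grid = np.linspace(max(hi / n, 1e-6), hi, n)
    labels = hme_phase_diagram(params, grid, grid)
    g1, g2 = np.meshgrid(grid, grid, indexing="ij")
    df = pd.DataFrame({"e_hdm": g1.ravel(), "e_hdac": g2.ravel(), "regime": labels.ravel()})
    path = os.path.join(out_dir, "phase_hme.csv")
    _atomic_write(path, lambda p: df.to_csv(p, index=False))
    return [path]


def _exp_transition_times(config, out_dir, seed):
    params = _get_er(config)
    tt = estimate_transition_times(
        params, n_events=int(config.get("n_events", 10)), seed=seed,
        t_max_per_passage=float(config.get("t_max_per_passage", 3e4)),
    )
    df = pd.DataFrame({
        "direction": ["closed_to_open"] * tt.n_open + ["open_to_closed"] * tt.n_close,
        "tau": np.concatenate([tt.samples_open, tt.samples_close]),
    })
    path = os.path.join(out_dir, "transition_times.csv")
    _atomic_write(path, lambda p: df.to_csv(p, index=False))
    summary = {
        "tau_open": tt.tau_open, "tau_close": tt.tau_close,
        "se_open": tt.se_open, "se_close": tt.se_close,
        "rare_open": tt.rare_open, "rare_close": tt.rare_close,
    }
    spath = os.path.join(out_dir, "transition_times.json")
    _atomic_write(spath, lambda p: open(p, "w").write(json.dumps(summary, indent=2)))
    return [path, spath]


def _exp_map(config, out_dir, seed):
    from .map_action import er_minimum_action

    params = _get_er(config)
    direction = config.get("direction", "open")
    res = er_minimum_action(params, direction, n_points=int(config.get("n_points", 64)))
    df = pd.DataFrame(res.path, columns=["m", "a"])
    df.insert(0, "time", res.times)
    path = os.path.join(out_dir, "map_path.csv")
    _atomic_write(path, lambda p: df.to_csv(p, index=False))
    meta = {
        "action": res.action, "converged": res.converged,
        "total_time": res.total_time, "direction": direction,
        "tau_s_exponent": res.action * params.n_sites,
    }
    mpath = os.path.join(out_dir, "map_result.json")
    _atomic_write(mpath, lambda p: open(p, "w").write(json.dumps(meta, indent=2)))
    return [path, mpath]


def _exp_simulate_er(config, out_dir, seed):
    from .ssa import er_network, gillespie_run

    params = _get_er(config)
    net = er_network(params)
    x0 = er_model.closed_state(params) if config.get("start", "closed") == "closed" else er_model.open_state(params)
    traj = gillespie_run(net, x0, float(config.get("t_max", 100.0)), seed,
                         max_events=int(config.get("max_events", 500_000)))
    df = pd.DataFrame(traj.states, columns=list(net.species))
    df.insert(0, "time", traj.times)
    path = os.path.join(out_dir, "er_trajectory.csv")
    _atomic_write(path, lambda p: df.to_csv(p, index=False))
    return [path]


def _exp_simulate_coupled(config, out_dir, seed):
    from .ssa import coupled_full_model, measure_differentiation_time

    ders = reference_er_params(config.get("ders", "ders1"))
    pers = reference_er_params(config.get("pers", "pers2"))
    model = coupled_full_model([ders, pers], _get_grn(config))
    tau, censored, n_events = measure_differentiation_time(
        model, seed, t_max=float(config.get("t_max", 2000.0)),
    )
    out = {"tau_D": tau, "censored": censored, "n_events": n_events}
    path = os.path.join(out_dir, "coupled_differentiation.json")
    _atomic_write(path, lambda p: open(p, "w").write(json.dumps(out, indent=2)))
    return [path]


def _exp_abc(config, out_dir, seed):
    from .ensemble import abc_rejection, default_prior_ranges, generate_raw_data

    ref = reference_er_params("reference")
    role = config.get("role", "ders")
    raw = generate_raw_data(ref, role, seed=seed)
    prior = default_prior_ranges(ref.c, spread=float(config.get("prior_spread", 3.0)))
    records, prov = abc_rejection(raw, prior, int(config.get("n_accept", 50)), seed=seed + 1)
    df = pd.DataFrame([r.c for r in records], columns=[f"c{j + 1}" for j in range(16)])
    df["role"] = role
    path = os.path.join(out_dir, "ensemble.csv")
    _atomic_write(path, lambda p: df.to_csv(p, index=False))
    ppath = os.path.join(out_dir, "abc_provenance.json")
    _atomic_write(ppath, lambda p: open(p, "w").write(json.dumps(prov, indent=2)))
    return [path, ppath]


def _exp_hybrid(config, out_dir, seed):
    from .hybrid import hybrid_run

    ders = reference_er_params(config.get("ders", "ders1"))
    pers = reference_er_params(config.get("pers", "pers2"))
    res = hybrid_run([ders, pers], _get_grn(config), float(config.get("t_max", 500.0)), seed)
    df = pd.DataFrame({
        "time": res.times,
        "x1": res.x[:, 0], "x2": res.x[:, 1],
        "eta1": res.eta[:, 0], "eta2": res.eta[:, 1],
        "acetyl1": res.acetyl[:, 0], "acetyl2": res.acetyl[:, 1],
    })
    path = os.path.join(out_dir, "hybrid_trajectory.csv")
    _atomic_write(path, lambda p: df.to_csv(p, index=False))
    meta = {"n_er_events": res.n_er_events, "n_resamples": res.n_resamples}
    mpath = os.path.join(out_dir, "hybrid_meta.json")
    _atomic_write(mpath, lambda p: open(p, "w").write(json.dumps(meta, indent=2)))
    return [path, mpath]


EXPERIMENTS = {
    "phase-grn": _exp_phase_grn,
    "phase-hme": _exp_phase_hme,
    "transition-times": _exp_transition_times,
    "map": _exp_map,
    "simulate-er": _exp_simulate_er,
    "simulate-coupled": _exp_simulate_coupled,
    "abc": _exp_abc,
    "hybrid": _exp_hybrid,
}


def run_experiment(config: dict) -> dict:
    """Dispatch a named experiment; returns the manifest dictionary.

    Required keys: ``experiment`` (one of EXPERIMENTS), ``out_dir``; optional
    ``seed`` (default 0) and experiment-specific settings.  Unknown experiment
    names are rejected before any computation; partial outputs are quarantined
    under ``<out_dir>/partial`` on failure.
    """
    if not isinstance(config, dict):
        raise SchemaError("config must be a mapping")
    name = config.get("experiment")
    if name not in EXPERIMENTS:
        raise SchemaError(
            f"unknown experiment {name!r}; choose one of {sorted(EXPERIMENTS)}"
        )
    out_dir = config.get("out_dir")
    if not out_dir:
        raise SchemaError("config must set out_dir")
    seed = int(config.get("seed", 0))
    os.makedirs(out_dir, exist_ok=True)
    try:
        files = EXPERIMENTS[name](config, out_dir, seed)
    except Exception:
        quarantine = os.path.join(out_dir, "partial")
        os.makedirs(quarantine, exist_ok=True)
        for f in os.listdir(out_dir):
            if f.endswith(".tmp"):
                os.replace(os.path.join(out_dir, f), os.path.join(quarantine, f))
        raise
    mpath = write_manifest(out_dir, config, files)
    with open(mpath) as fh:
        return json.load(fh)


def validate_model_file(path) -> dict:
    """Validate and normalise a model-definition file.

    Checks: every ER block carries exactly 16 rate constants and valid scales
    (delegated to `ERParams`); a custom reaction table, when present, must
    conserve sites and enzyme totals on every channel (violations are reported
    with the channel named).  Returns the normalised model dictionary.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: model file must be a mapping")
    if "channels" in raw:
        from .er_model import _load_table_dict

        _load_table_dict(raw)  # raises ConfigurationError naming bad channels
        return {"table": True}
    model = load_model_file(path)
    if not model["er_systems"] and model["grn"] is None:
        raise SchemaError(f"{path}: no er_systems or grn section found")
    return model
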