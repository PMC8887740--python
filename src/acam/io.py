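"""Run configuration, snapshot serialisation and structured output.

Every run writes a self-describing output directory: the resolved
configuration (bit-exact echo), a metadata document (code version, seed,
schema version), per-step observables, the bond event log, and columnar
per-snapshot node/bond tables (CSV).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, factory, protocols
from .tissue import Params, SimulationTrace, Tissue

SCHEMA_VERSION = 1

FIXTURES = {
    "single-cell-hexagon": factory.single_cell_in_hexagon,
    "three-cell": factory.three_cell_tissue,
    "fourteen-cell": factory.fourteen_cell_tissue,
}

#: configuration keys that map straight onto Params fields
PARAM_KEYS = (
    "kappa", "omega", "delta_max", "delta_gamma", "tau_adh", "gamma0",
    "mesh_spacing", "area_stiffness", "tol", "kernel_mode",
)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    return cfg


def build_from_config(cfg: dict):
    """(tissue, protocol, n_steps, seed, snapshot_every) from a config."""
    fx = cfg.get("fixture", {})
    name = fx.get("name")
    if name not in FIXTURES:
        raise ConfigError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    kw = {k: v for k, v in fx.items() if k != "name"}
    try:
        tissue = FIXTURES[name](**kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad fixture parameters: {exc}") from exc

    pr = dict(cfg.get("protocol", {"name": "background"}))
    pname = pr.pop("name", "background")
    if pname not in protocols.PROTOCOLS:
        raise ConfigError(
            f"unknown protocol {pname!r}; choose from {sorted(protocols.PROTOCOLS)}"
        )
    if pname == "background" and "gamma0" not in pr:
        pr["gamma0"] = tissue.params.gamma0
    try:
        protocol = protocols.PROTOCOLS[pname](**pr)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad protocol parameters: {exc}") from exc

    n_steps = int(cfg.get("n_steps", 100))
    seed = int(cfg.get("seed", 0))
    snapshot_every = int(cfg.get("snapshot_every", 10))
    return tissue, protocol, n_steps, seed, snapshot_every


def snapshot_frame(tissue: Tissue) -> pd.DataFrame:
    """Tidy per-node table of one tissue state."""
    from .cortex import segment_geometry

    rows = []
    for lp in tissue.loops:
        geo = segment_geometry(lp)
        nseg = lp.nseg
        for i in range(lp.n):
            s = i % nseg
            rows.append(
                {
                    "cell": lp.cell_id,
                    "node": i,
                    "label": lp.labels[i],
                    "x": lp.x[i, 0],
                    "y": lp.x[i, 1],
                    "gamma": lp.gamma[s],
                    "alpha": geo["alpha"][s],
                    "eps": geo["eps"][s],
                    "tension": geo["eps"][s],
                }
            )
    return pd.DataFrame(rows)


def bonds_frame(tissue: Tissue) -> pd.DataFrame:
    b = tissue.bonds
    return pd.DataFrame(
        {
            "cell_a": [tissue.loops[l].cell_id for l in b.a_loop],
            "node_a": b.a_node,
            "cell_b": [tissue.loops[l].cell_id if l >= 0 else l for l in b.b_loop],
            "node_b": b.b_node,
            "factor": b.factor,
            "birth": b.birth,
            "lifetime": b.life,
            "pin": b.pin,
        }
    )


def save_run(outdir, tissue: Tissue, trace: SimulationTrace, cfg: dict) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    meta = {
        "acam_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.get("seed", 0),
        "params": asdict(tissue.params),
        "n_cells": len(tissue.loops),
    }
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=float)
    if trace.observables is not None:
        trace.observables.to_csv(out / "observables.csv", index=False)
    with open(out / "events.csv", "w") as fh:
        fh.write("step,kind,payload\n")
        for step, kind, payload in trace.events:
            fh.write(f"{step},{kind},{json.dumps(payload)}\n")
    snapdir = out / "snapshots"
    snapdir.mkdir(exist_ok=True)
    for step, tis in trace.snapshots:
        snapshot_frame(tis).to_csv(snapdir / f"step_{step:05d}_nodes.csv", index=False)
        bonds_frame(tis).to_csv(snapdir / f"step_{step:05d}_bonds.csv", index=False)
    return out


def event_log_hash(trace: SimulationTrace) -> str:
    """Deterministic digest of the bond event log (reproducibility check)."""
    h = hashlib.sha256()
    for step, kind, payload in trace.events:
        h.update(f"{step}|{kind}|{json.dumps(payload, sort_keys=True)}".encode())
    return h.hexdigest()


def render_frames(rundir, outdir=None, every: int = 1) -> list[Path]:
    """Draw PNG frames from the snapshot tables of a finished run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rundir = Path(rundir)
    outdir = Path(outdir) if outdir else rundir / "frames"
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    snaps = sorted((rundir / "snapshots").glob("step_*_nodes.csv"))
    for k, snap in enumerate(snaps):
        if k % every:
            continue
        df = pd.read_csv(snap)
        fig, ax = plt.subplots(figsize=(7, 7))
        for cid, sub in df.groupby("cell"):
            xy = sub[["x", "y"]].to_numpy()
            ax.plot(
                np.r_[xy[:, 0], xy[0, 0]], np.r_[xy[:, 1], xy[0, 1]], lw=0.8
            )
        ax.set_aspect(1)
        ax.set_title(snap.stem)
        path = outdir / (snap.stem.replace("_nodes", "") + ".png")
        fig.savefig(path, dpi=90)
        plt.close(fig)
        frames.append(path)
    return frames
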