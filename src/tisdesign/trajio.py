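"""Trajectory container and text exports.

Trajectories and path ensembles live in a chunked HDF5 store (datasets:
positions, velocities, time, lambda); lambda series additionally export as
two-column plain text (time fs, lambda A).  Tables (rate reports, metrics,
PMF profiles) are delimited text with a header row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path as FsPath

import h5py
import numpy as np

from .dynamics import TrajectorySegment
from .paths import Path, PathEnsemble
from .pmf import PMFProfile
from .rates import CrossingProbabilities

__all__ = [
    "save_segment", "load_segment",
    "save_ensemble", "load_ensemble",
    "export_lambda_series", "export_pmf", "export_rate_report",
    "file_checksum",
]


def save_segment(path, segment: TrajectorySegment, name: str = "trajectory"):
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("time", data=segment.times, chunks=True)
        g.create_dataset("lambda", data=segment.lambdas, chunks=True)
        if segment.positions is not None:
            g.create_dataset("positions", data=segment.positions, chunks=True)
        if segment.velocities is not None:
            g.create_dataset("velocities", data=segment.velocities, chunks=True)
        g.attrs["dt"] = segment.dt
        g.attrs["position_stride"] = segment.position_stride


def load_segment(path, name: str = "trajectory") -> TrajectorySegment:
    with h5py.File(path, "r") as f:
        g = f[name]
        return TrajectorySegment(
            times=g["time"][()], lambdas=g["lambda"][()],
            positions=g["positions"][()] if "positions" in g else None,
            velocities=g["velocities"][()] if "velocities" in g else None,
            dt=float(g.attrs["dt"]),
            position_stride=int(g.attrs["position_stride"]))


def save_ensemble(path, ensemble: PathEnsemble, name: str = "ensemble"):
    """Store paths plus a manifest (condition, acceptance stats) as attrs."""
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.attrs["condition"] = json.dumps(ensemble.condition)
        g.attrs["n_attempted"] = ensemble.n_attempted
        g.attrs["n_accepted"] = ensemble.n_accepted
        g.attrs["seed_lineage"] = ensemble.seed_lineage
        for i, p in enumerate(ensemble.entries):
            pg = g.create_group(f"path{i:06d}")
            pg.create_dataset("time", data=p.times)
            pg.create_dataset("lambda", data=p.lambdas)
            if p.positions is not None:
                pg.create_dataset("positions", data=p.positions, chunks=True)
            if p.velocities is not None:
                pg.create_dataset("velocities", data=p.velocities, chunks=True)
            pg.attrs["endpoints"] = "".join(
                e if e != "neither" else "n" for e in p.endpoints)
            pg.attrs["multiplicity"] = p.multiplicity
            pg.attrs["path_id"] = p.path_id


def load_ensemble(path, name: str = "ensemble") -> PathEnsemble:
    decode = {"A": "A", "B": "B", "n": "neither"}
    with h5py.File(path, "r") as f:
        g = f[name]
        ens = PathEnsemble(condition=json.loads(g.attrs["condition"]),
                           n_attempted=int(g.attrs["n_attempted"]),
                           n_accepted=int(g.attrs["n_accepted"]),
                           seed_lineage=str(g.attrs["seed_lineage"]))
        for key in sorted(k for k in g.keys() if k.startswith("path")):
            pg = g[key]
            ep = tuple(decode[c] for c in pg.attrs["endpoints"])
            ens.entries.append(Path(
                times=pg["time"][()], lambdas=pg["lambda"][()],
                positions=pg["positions"][()] if "positions" in pg else None,
                velocities=pg["velocities"][()] if "velocities" in pg else None,
                endpoints=ep, multiplicity=int(pg.attrs["multiplicity"]),
                path_id=int(pg.attrs["path_id"])))
    return ens


def export_lambda_series(path, segment: TrajectorySegment):
    """Two columns: time (fs), lambda (A)."""
    np.savetxt(path, np.column_stack([segment.times, segment.lambdas]),
               header="time_fs lambda_A", fmt="%.6f")


def export_pmf(path, profile: PMFProfile):
    np.savetxt(path, np.column_stack([profile.grid, profile.free_energy]),
               header="lambda_A free_energy_kcal_mol", fmt="%.6f")


def export_rate_report(path, probs: CrossingProbabilities, flux: float,
                       k: float, sem: float | None = None):
    """Interface table (lambda, conditional, cumulative) plus a summary."""
    cum = probs.cumulative()
    lines = ["# interface_lambda_A conditional cumulative"]
    for i in range(len(probs.interfaces) - 1):
        lines.append(f"{probs.interfaces[i]:.4f} {probs.conditionals[i]:.6g} "
                     f"{cum[i + 1]:.6g}")
    lines.append(f"# flux_per_s {flux:.6g}")
    lines.append(f"# k_per_s {k:.6g}")
    if sem is not None:
        lines.append(f"# k_sem_per_s {sem:.6g}")
    FsPath(path).write_text("\n".join(lines) + "\n")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(FsPath(path).read_bytes())
    return h.hexdigest()
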