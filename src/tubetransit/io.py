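"""Result serialisation: arrival-curve CSV, scenario CSV, run manifests,
and XYZ trajectory frames for molecular viewers."""

import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import config_to_dict
from .engine import SimulationConfig
from .state import ArrivalCurve

CURVE_HEADER = ["time_min", "fraction", "n_absorbed", "n_total"]


@dataclass
class RunManifest:
    """Provenance for one set of outputs.

    Re-running the package on the embedded config reproduces the outputs
    bit-for-bit (the config carries the seed).
    """

    config: dict
    seed: int
    version: str = __version__
    outputs: list = field(default_factory=list)
    runtime_s: float = 0.0
    dt_s: float = 0.0
    rejection_rate: float = 0.0
    created: str = ""

    @classmethod
    def from_run(cls, config: SimulationConfig,
                 curve: ArrivalCurve) -> "RunManifest":
        stats = curve.stats
        return cls(config=config_to_dict(config), seed=config.seed,
                   runtime_s=stats.runtime_s if stats else 0.0,
                   dt_s=stats.dt if stats else 0.0,
                   rejection_rate=stats.rejection_rate if stats else 0.0,
                   created=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def to_yaml(self, path) -> None:
        data = {
            "version": self.version,
            "seed": self.seed,
            "created": self.created,
            "runtime_s": float(self.runtime_s),
            "dt_s": float(self.dt_s),
            "rejection_rate": float(self.rejection_rate),
            "outputs": list(self.outputs),
            "config": self.config,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def write_curve_csv(curve: ArrivalCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_curve_csv(path) -> ArrivalCurve:
    frame = pd.read_csv(path)
    missing = [c for c in CURVE_HEADER if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return ArrivalCurve(times=frame["time_min"].to_numpy() * 60.0,
                        fractions=frame["fraction"].to_numpy(),
                        n_total=int(frame["n_total"].iloc[0]))


def write_xyz(snapshots, path) -> None:
    """Write trajectory snapshots as multi-frame XYZ (coordinates in mm).

    Each frame holds every particle as element ``P`` at its position at
    one record time; viewable in standard molecular viewers.
    """
    with open(path, "w") as fh:
        for t, pos_mm in snapshots:
            fh.write(f"{len(pos_mm)}\n")
            fh.write(f"t = {t:.6g} s (coordinates in mm)\n")
            for x, y, z in np.asarray(pos_mm):
                fh.write(f"P {x:.6f} {y:.6f} {z:.6f}\n")


def write_outputs(curve: ArrivalCurve, table, manifest: RunManifest,
                  out_dir, snapshots=None) -> list:
    """Write curve CSV, optional scenario-table CSV, optional XYZ
    trajectory, and the manifest.  Returns the written paths."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory is not writable: {out_dir}")

    paths = []
    curve_path = os.path.join(out_dir, "arrival_curve.csv")
    write_curve_csv(curve, curve_path)
    paths.append(curve_path)
    if table is not None:
        table_path = os.path.join(out_dir, "scenario_table.csv")
        table.to_csv(table_path)
        paths.append(table_path)
    if snapshots is not None:
        xyz_path = os.path.join(out_dir, "trajectory.xyz")
        write_xyz(snapshots, xyz_path)
        paths.append(xyz_path)

    manifest.outputs = [os.path.basename(p) for p in paths]
    manifest_path = os.path.join(out_dir, "manifest.yaml")
    manifest.to_yaml(manifest_path)
    paths.append(manifest_path)
    return paths
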