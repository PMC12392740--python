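"""Trajectory and table I/O.

Trajectories are written as extended XYZ text: one block per frame, body
centers plus orientation quaternions, velocities, and body-frame angular
momenta as extra columns, with the box, time, and run metadata on the
comment line.  The format round-trips float64 exactly (17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from condcap.state import SystemState, Trajectory

__all__ = ["write_extxyz", "read_extxyz", "write_series_csv"]

_COLUMNS = "species:S:1:pos:R:3:quat:R:4:velo:R:3:angmom:R:3:image:I:3"


def write_extxyz(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as extended XYZ with quaternion columns."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in traj.frames:
            fh.write(f"{frame.n}\n")
            meta = {
                "Time": frame.time,
                "Lattice": " ".join(
                    f"{v:.17g}"
                    for v in [frame.box_L, 0.0, 0.0, 0.0, frame.box_L, 0.0, 0.0, 0.0, frame.box_L]
                ),
                "Properties": _COLUMNS,
            }
            if frame is traj.frames[0] and traj.metadata:
                # JSON double quotes would collide with the comment-line
                # quoting; store them as a placeholder
                meta["Metadata"] = json.dumps(traj.metadata, sort_keys=True).replace('"', "&q;")
            comment = " ".join(
                f'{k}="{v}"' if " " in str(v) or k == "Metadata" else f"{k}={v}"
                for k, v in meta.items()
            )
            fh.write(comment + "\n")
            for i in range(frame.n):
                cols = (
                    ["SUB"]
                    + [f"{x:.17g}" for x in frame.centers[i]]
                    + [f"{x:.17g}" for x in frame.orientations[i]]
                    + [f"{x:.17g}" for x in frame.velocities[i]]
                    + [f"{x:.17g}" for x in frame.angular_momenta[i]]
                    + [str(int(x)) for x in frame.images[i]]
                )
                fh.write(" ".join(cols) + "\n")


def _parse_comment(line: str) -> dict:
    out = {}
    i = 0
    while i < len(line):
        eq = line.find("=", i)
        if eq < 0:
            break
        key = line[i:eq].strip()
        rest = line[eq + 1 :]
        if rest.startswith('"'):
            end = rest.find('"', 1)
            val = rest[1:end]
            i = eq + 1 + end + 1
        else:
            end = rest.find(" ")
            if end < 0:
                val, i = rest, len(line)
            else:
                val = rest[:end]
                i = eq + 1 + end
        out[key] = val
    return out


def read_extxyz(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_extxyz`."""
    path = Path(path)
    traj = Trajectory()
    with path.open() as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            meta = _parse_comment(fh.readline().rstrip("\n"))
            lat = [float(x) for x in meta["Lattice"].split()]
            L = lat[0]
            time = float(meta.get("Time", 0.0))
            if "Metadata" in meta and not traj.metadata:
                traj.metadata = json.loads(meta["Metadata"].replace("&q;", '"'))
            centers = np.empty((n, 3))
            quats = np.empty((n, 4))
            vel = np.empty((n, 3))
            ang = np.empty((n, 3))
            img = np.empty((n, 3), dtype=np.int64)
            for i in range(n):
                parts = fh.readline().split()
                vals = [float(x) for x in parts[1:14]]
                centers[i] = vals[0:3]
                quats[i] = vals[3:7]
                vel[i] = vals[7:10]
                ang[i] = vals[10:13]
                img[i] = [int(x) for x in parts[14:17]]
            traj.frames.append(
                SystemState(
                    centers=centers,
                    orientations=quats,
                    velocities=vel,
                    angular_momenta=ang,
                    box_L=L,
                    time=time,
                    images=img,
                )
            )
    return traj


def write_series_csv(series, path: str | Path) -> None:
    """Per-frame observable series as CSV (see AssemblyTimeSeries)."""
    series.to_dataframe().to_csv(path, index=False)
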