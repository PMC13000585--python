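"""Extended-XYZ trajectory reader/writer and the reaction-events table.

The per-frame comment line carries ``time_ps=... box="lx ly lz"
unwrapped=...``; per-atom columns are element, x, y, z, molecule_id,
role. Coordinates are printed to six decimals and the reader/writer
round-trip is bit-exact at that precision.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .trajectory import Frame, ReactionSeries, Trajectory

__all__ = ["write_xyz", "read_xyz", "write_events_csv", "read_events_csv"]

_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _comment_line(frame: Frame, unwrapped: bool) -> str:
    parts = [f"time_ps={frame.time_ps:.6f}"]
    if frame.box is not None:
        parts.append('box="' + " ".join(f"{v:.6f}" for v in frame.box) + '"')
    parts.append(f"unwrapped={'T' if unwrapped else 'F'}")
    return " ".join(parts)


def write_xyz(trajectory: Trajectory, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for frame in trajectory.frames:
            fh.write(f"{frame.n_atoms}\n")
            fh.write(_comment_line(frame, trajectory.unwrapped) + "\n")
            for el, (x, y, z), mid, role in zip(
                frame.elements, frame.xyz, frame.molecule_ids, frame.roles
            ):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f} {mid} {role}\n")


def read_xyz(path: str | Path) -> Trajectory:
    frames: list[Frame] = []
    unwrapped = False
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        meta = {m.group(1): m.group(2) or m.group(3) for m in _KV_RE.finditer(lines[i + 1])}
        time_ps = float(meta.get("time_ps", 0.0))
        box = None
        if "box" in meta:
            box = np.array([float(v) for v in meta["box"].split()])
        unwrapped = meta.get("unwrapped", "F") == "T"
        elements, xyz, mids, roles = [], [], [], []
        for line in lines[i + 2 : i + 2 + n]:
            tok = line.split()
            elements.append(tok[0])
            xyz.append([float(tok[1]), float(tok[2]), float(tok[3])])
            mids.append(int(tok[4]))
            roles.append(tok[5])
        frames.append(
            Frame(
                time_ps=time_ps,
                elements=np.array(elements, dtype=object),
                xyz=np.array(xyz),
                molecule_ids=np.array(mids),
                roles=np.array(roles, dtype=object),
                box=box,
            )
        )
        i += 2 + n
    if len(frames) > 1:
        dt = frames[1].time_ps - frames[0].time_ps
    else:
        dt = 1.0
    return Trajectory(frames=frames, frame_interval_ps=dt, unwrapped=unwrapped)


def write_events_csv(series_list: Iterable[ReactionSeries], path: str | Path) -> None:
    """events.csv: one row per (realization, time) grid point."""
    rows = []
    for r, s in enumerate(series_list):
        for t, c in zip(s.times_ns, s.counts):
            rows.append((r, t, c))
    pd.DataFrame(rows, columns=["realization", "time_ns", "cumulative_count"]).to_csv(
        path, index=False
    )


def read_events_csv(path: str | Path) -> list[ReactionSeries]:
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("realization", sort=True):
        out.append(
            ReactionSeries(
                times_ns=grp["time_ns"].to_numpy(),
                counts=grp["cumulative_count"].to_numpy(),
            )
        )
    return out
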