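"""In-memory containers for labeled-atom trajectories.

Frames hold element symbols, Cartesian coordinates (Angstrom), a
molecule id, and a role tag per atom. Role tags mark the atoms the
analysis cares about: the phenoxyl oxygen (H-bond acceptor and reaction
site), the hydroperoxide hydrogen (the transferred atom), and donor
oxygens. Trajectories are uniformly spaced in time and carry an
``unwrapped`` flag because mean-squared-displacement analysis requires
unwrapped coordinates while distance-based analyses use the minimum
image under the periodic box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ROLES", "Frame", "Trajectory", "ReactionSeries", "minimum_image_vectors"]

ROLES = (
    "phenoxyl_O",
    "ring_C_ipso",
    "hydroperoxide_H",
    "hydroperoxide_O",
    "donor",
    "acceptor",
    "other",
)


@dataclass
class Frame:
    """One snapshot: coordinates plus per-atom labels and a periodic box."""

    time_ps: float
    elements: np.ndarray          # (n,) str
    xyz: np.ndarray               # (n, 3) float, Angstrom
    molecule_ids: np.ndarray      # (n,) int
    roles: np.ndarray             # (n,) str
    box: np.ndarray | None = None  # (3,) orthorhombic box lengths, Angstrom

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.roles = np.asarray(self.roles, dtype=object)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        n = len(self.elements)
        if self.xyz.shape != (n, 3):
            raise ValueError(f"xyz shape {self.xyz.shape} does not match {n} atoms")
        if len(self.molecule_ids) != n or len(self.roles) != n:
            raise ValueError("per-atom arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown role tags: {sorted(unknown)}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def select(self, role: str) -> np.ndarray:
        """Indices of atoms carrying a role tag."""
        return np.flatnonzero(self.roles == role)


@dataclass
class Trajectory:
    """Ordered, uniformly time-spaced frames with constant atom identity."""

    frames: list[Frame]
    frame_interval_ps: float
    unwrapped: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty trajectory")
        n = self.frames[0].n_atoms
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError("atom count varies across frames")
            expected = self.frames[0].time_ps + i * self.frame_interval_ps
            if abs(fr.time_ps - expected) > 1e-6:
                raise ValueError("frames are not uniformly spaced")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_ps(self) -> np.ndarray:
        return np.array([fr.time_ps for fr in self.frames])

    def coordinates(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_sel, 3)."""
        if indices is None:
            return np.stack([fr.xyz for fr in self.frames])
        idx = np.asarray(indices, dtype=int)
        return np.stack([fr.xyz[idx] for fr in self.frames])


@dataclass
class ReactionSeries:
    """Cumulative hydrogen-transfer counts on an ascending time grid (ns)."""

    times_ns: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times_ns.ndim != 1 or self.times_ns.size == 0:
            raise ValueError("time grid must be a nonempty 1-D array")
        if self.counts.shape != self.times_ns.shape:
            raise ValueError("counts and times have different shapes")
        if np.any(np.diff(self.times_ns) <= 0):
            raise ValueError("time grid must be strictly ascending")
        if np.any(np.diff(self.counts) < 0) or self.counts[0] < 0:
            raise ValueError("cumulative counts must be nonnegative and nondecreasing")


def minimum_image_vectors(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Minimum-image displacement(s) b - a under an orthorhombic box.

    Broadcasts over leading dimensions; with ``box=None`` returns the
    raw displacement.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        d = d - box * np.round(d / box)
    return d
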