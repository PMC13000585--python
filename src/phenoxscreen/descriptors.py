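"""Trajectory-derived molecular descriptors and the event detector.

Three descriptors summarize what controls reverse hydrogen transfer at
the phenoxyl oxygen:

* **diffusivity** ``D`` from the mean squared displacement via the
  Einstein relation (3-D: MSD slope = 6 D);
* **H-bond protection probability** ``p_HB``: the fraction of frames in
  which the phenoxyl oxygen accepts at least one hydrogen bond
  (donor-acceptor distance < 3 A and donor-H-acceptor angle > 150 deg);
* **percent buried volume** ``V_bur``: the fraction of a 3.5 A probe
  sphere centered on the phenoxyl oxygen occupied by the van der Waals
  volumes of surrounding atoms.

Cutoff comparisons are strict (< 3 A, > 150 deg, < 0.9 A); boundary
ties are excluded. All intermolecular distances use the minimum image
under the orthorhombic periodic box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import VDW_RADII
from .trajectory import Frame, ReactionSeries, Trajectory, minimum_image_vectors

__all__ = [
    "MsdCurve",
    "HBond",
    "StericMap",
    "DescriptorRecord",
    "compute_msd",
    "fit_diffusion",
    "detect_hbonds",
    "hbond_probability",
    "buried_volume",
    "steric_map",
    "detect_transfer_events",
]


@dataclass
class MsdCurve:
    """Mean squared displacement vs lag time, averaged over sliding origins."""

    lags_ps: np.ndarray
    msd: np.ndarray        # A^2
    n_origins: np.ndarray  # time origins averaged at each lag


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # donor-acceptor, A
    angle: float     # donor-hydrogen-acceptor, deg


@dataclass
class StericMap:
    """Height field of the vdW surface viewed along the O-C bond axis."""

    x: np.ndarray        # grid axes, A (plane perpendicular to the C->O axis)
    y: np.ndarray
    heights: np.ndarray  # signed top-surface height, A; NaN where no atom covers
    buried_pct: float    # molecule-only percent buried volume


@dataclass
class DescriptorRecord:
    """One regression design row: the three descriptors for a candidate."""

    candidate_id: int
    D: float       # A^2/ps
    p_HB: float    # fraction in [0, 1]
    V_bur: float   # percent of probe sphere in [0, 100]


def compute_msd(
    trajectory: Trajectory,
    role: str = "phenoxyl_O",
    max_lag_fraction: float = 1.0,
) -> MsdCurve:
    """MSD over all frame-grid lags with sliding-window origin averaging.

    ``msd(tau)`` is the average of ``|r(t + tau) - r(t)|^2`` over all
    selected particles and all time origins ``t``. Requires unwrapped
    coordinates: displacement magnitudes are meaningless across periodic
    wrapping.
    """
    if not trajectory.unwrapped:
        raise ValueError(
            "MSD requires unwrapped coordinates; regenerate or unwrap the trajectory"
        )
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames")
    idx = trajectory.frames[0].select(role)
    if len(idx) == 0:
        raise ValueError(f"no atoms with role {role!r}")
    pos = trajectory.coordinates(idx)  # (n_frames, n_sel, 3)
    n = trajectory.n_frames
    max_lag = max(1, int(max_lag_fraction * (n - 1)))
    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    n_origins = np.zeros(max_lag + 1, dtype=int)
    n_origins[0] = n
    for lag in lags[1:]:
        disp = pos[lag:] - pos[:-lag]
        msd[lag] = np.mean(np.sum(disp * disp, axis=-1))
        n_origins[lag] = n - lag
    return MsdCurve(lags_ps=lags * trajectory.frame_interval_ps, msd=msd,
                    n_origins=n_origins)


def fit_diffusion(
    curve: MsdCurve,
    fit_window: tuple[float, float] = (0.1, 0.5),
    dimensions: int = 3,
) -> tuple[float, float]:
    """Diffusion coefficient from the Einstein relation, with fit R^2.

    An ordinary least-squares line is fitted to MSD vs lag over the
    window given as fractions of the maximum lag (default the 10-50%
    span, where origin statistics are still good and ballistic/plateau
    artifacts are avoided); ``D = slope / (2 * dimensions)``.
    """
    lo, hi = fit_window
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("fit window must satisfy 0 <= lo < hi <= 1")
    t_max = curve.lags_ps[-1]
    mask = (curve.lags_ps >= lo * t_max) & (curve.lags_ps <= hi * t_max)
    if mask.sum() < 2:
        raise ValueError("degenerate fit window: fewer than 2 lags inside")
    x = curve.lags_ps[mask]
    y = curve.msd[mask]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope / (2.0 * dimensions), r2


_DONOR_ROLES = ("donor", "hydroperoxide_O")
_ACCEPTOR_ROLES = ("phenoxyl_O",)
_DH_BOND_MAX = 1.25  # A; O-H covalent attachment cutoff


def detect_hbonds(
    frame: Frame,
    donor_roles: tuple[str, ...] = _DONOR_ROLES,
    acceptor_roles: tuple[str, ...] = _ACCEPTOR_ROLES,
    d_cut: float = 3.0,
    angle_cut: float = 150.0,
) -> list[HBond]:
    """Geometric hydrogen bonds in one frame.

    A triple (donor O, its covalently attached H, acceptor O) is a
    hydrogen bond when the donor-acceptor minimum-image distance is
    strictly below ``d_cut`` and the donor-H-acceptor angle strictly
    above ``angle_cut``. Donor hydrogens are located by proximity
    (an H within 1.25 A of the donor oxygen, same molecule). Pairs with
    donor == acceptor are excluded; intramolecular donor/acceptor pairs
    (e.g. a carboxyl O-H protecting its own phenoxyl oxygen) count.
    """
    donors = np.concatenate([frame.select(r) for r in donor_roles]) \
        if donor_roles else np.array([], dtype=int)
    acceptors = np.concatenate([frame.select(r) for r in acceptor_roles]) \
        if acceptor_roles else np.array([], dtype=int)
    if len(donors) == 0 or len(acceptors) == 0:
        raise ValueError("no atoms matched the donor/acceptor role selections")
    # screen donor-acceptor pairs on distance first (vectorized)
    da = np.linalg.norm(
        minimum_image_vectors(
            frame.xyz[donors][:, None, :], frame.xyz[acceptors][None, :, :], frame.box
        ),
        axis=-1,
    )
    close = np.argwhere((da < d_cut) & (donors[:, None] != acceptors[None, :]))
    h_all = np.flatnonzero(frame.elements == "H")
    attached_cache: dict[int, np.ndarray] = {}
    bonds: list[HBond] = []
    for di, ai in close:
        d_idx, a_idx = int(donors[di]), int(acceptors[ai])
        if d_idx not in attached_cache:
            same_mol = h_all[frame.molecule_ids[h_all] == frame.molecule_ids[d_idx]]
            dh = np.linalg.norm(
                minimum_image_vectors(frame.xyz[d_idx], frame.xyz[same_mol], frame.box),
                axis=-1,
            ) if len(same_mol) else np.array([])
            attached_cache[d_idx] = same_mol[dh < _DH_BOND_MAX] if len(same_mol) else same_mol
        for h_idx in attached_cache[d_idx]:
            v1 = minimum_image_vectors(frame.xyz[h_idx], frame.xyz[d_idx], frame.box)
            v2 = minimum_image_vectors(frame.xyz[h_idx], frame.xyz[a_idx], frame.box)
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle > angle_cut:
                bonds.append(
                    HBond(d_idx, int(h_idx), a_idx, float(da[di, ai]), angle)
                )
    return bonds


def hbond_probability(
    trajectory: Trajectory,
    d_cut: float = 3.0,
    angle_cut: float = 150.0,
) -> float:
    """Mean per-radical fraction of frames with >= 1 protecting H-bond.

    For each phenoxyl oxygen, the fraction of frames in which it accepts
    at least one hydrogen bond; the returned value averages over the
    radicals present in the trajectory.
    """
    o_sites = trajectory.frames[0].select("phenoxyl_O")
    if len(o_sites) == 0:
        raise ValueError("trajectory contains no phenoxyl_O sites")
    protected = np.zeros(len(o_sites))
    for frame in trajectory.frames:
        bonds = detect_hbonds(frame, d_cut=d_cut, angle_cut=angle_cut)
        acceptors = {b.acceptor for b in bonds}
        protected += np.isin(o_sites, list(acceptors))
    return float(np.mean(protected / trajectory.n_frames))


def _sphere_cap_lens_fraction(r_probe: float, r_atom: float, d: float) -> float:
    """Analytic fraction of a probe sphere covered by one atom sphere."""
    if d >= r_probe + r_atom:
        return 0.0
    if d + r_probe <= r_atom:
        return 1.0
    if d + r_atom <= r_probe:
        return (r_atom / r_probe) ** 3
    lens = (
        np.pi
        * (r_probe + r_atom - d) ** 2
        * (d**2 + 2 * d * r_atom - 3 * r_atom**2 + 2 * d * r_probe + 6 * r_atom * r_probe - 3 * r_probe**2)
        / (12 * d)
    )
    return float(lens / (4.0 / 3.0 * np.pi * r_probe**3))


def buried_volume(
    frame: Frame,
    center_idx: int,
    probe_radius: float = 3.5,
    method: str = "grid",
    resolution: float = 0.1,
    n_samples: int = 100_000,
    seed: int = 0,
    vdw_radii: dict[str, float] | None = None,
) -> float:
    """Percent of the probe sphere occupied by nearby van der Waals volumes.

    The probe sphere (default radius 3.5 A = 0.35 nm) is centered on the
    phenoxyl oxygen; every other atom within range contributes its vdW
    sphere (minimum image; hydrogens included; the center atom itself is
    excluded, as is standard for buried-volume descriptors). ``grid``
    integrates on a cubic lattice of the given resolution; ``montecarlo``
    samples ``n_samples`` uniform points in the sphere.
    """
    if frame.roles[center_idx] != "phenoxyl_O":
        raise ValueError("center atom must be tagged phenoxyl_O")
    radii = vdw_radii or VDW_RADII
    missing = sorted({el for el in frame.elements} - set(radii))
    if missing:
        raise ValueError(f"no van der Waals radius for element(s): {missing}")
    center = frame.xyz[center_idx]
    others = np.arange(frame.n_atoms) != center_idx
    rel = minimum_image_vectors(center, frame.xyz[others], frame.box)
    r_atoms = np.array([radii[el] for el in frame.elements[others]])
    reach = np.linalg.norm(rel, axis=-1) - r_atoms < probe_radius
    rel, r_atoms = rel[reach], r_atoms[reach]
    if len(rel) == 0:
        return 0.0

    if method == "grid":
        ax = np.arange(-probe_radius, probe_radius + resolution / 2, resolution)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        pts = pts[np.einsum("ij,ij->i", pts, pts) <= probe_radius**2]
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-probe_radius, probe_radius, size=(int(n_samples * 2.0), 3))
        pts = pts[np.einsum("ij,ij->i", pts, pts) <= probe_radius**2][:n_samples]
    else:
        raise ValueError("method must be 'grid' or 'montecarlo'")

    covered = np.zeros(len(pts), dtype=bool)
    for a_xyz, a_r in zip(rel, r_atoms):
        d2 = np.einsum("ij,ij->i", pts - a_xyz, pts - a_xyz)
        covered |= d2 < a_r**2
        if covered.all():
            break
    return 100.0 * float(covered.mean())


def steric_map(
    geometry: Frame,
    probe_radius: float = 3.5,
    grid_step: float = 0.1,
    vdw_radii: dict[str, float] | None = None,
) -> StericMap:
    """Top-view vdW height field perpendicular to the ipso-C -> O axis.

    The single-molecule geometry is rotated so the ipso-carbon-to-oxygen
    axis points along +z with the phenoxyl oxygen at the origin; for
    each grid point of the perpendicular plane inside the probe circle,
    the map records the highest intersection of the vertical ray with
    any atom's vdW sphere, clipped to the probe sphere. Also reports the
    molecule-only percent buried volume at matching resolution.
    """
    o_idx = geometry.select("phenoxyl_O")
    c_idx = geometry.select("ring_C_ipso")
    if len(o_idx) != 1 or len(c_idx) != 1:
        raise ValueError("geometry must contain exactly one phenoxyl_O and one ring_C_ipso")
    center = geometry.xyz[o_idx[0]]
    axis = center - geometry.xyz[c_idx[0]]
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise ValueError("center and ipso carbon coincide")
    z = axis / norm
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, z)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - np.dot(ref, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])

    radii = vdw_radii or VDW_RADII
    local = (geometry.xyz - center) @ R.T
    others = np.arange(geometry.n_atoms) != o_idx[0]
    pos = local[others]
    r_atoms = np.array([radii[el] for el in geometry.elements[others]])

    ax = np.arange(-probe_radius, probe_radius + grid_step / 2, grid_step)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    heights = np.full(gx.shape, np.nan)
    rho2 = gx**2 + gy**2
    inside = rho2 <= probe_radius**2
    for (px, py, pz), r in zip(pos, r_atoms):
        d2 = (gx - px) ** 2 + (gy - py) ** 2
        hit = (d2 < r**2) & inside
        if not hit.any():
            continue
        top = pz + np.sqrt(np.maximum(r**2 - d2[hit], 0.0))
        cur = heights[hit]
        heights[hit] = np.where(np.isnan(cur) | (top > cur), top, cur)
    # clip to the probe sphere so heights are bounded by its radius
    cap = np.sqrt(np.maximum(probe_radius**2 - rho2, 0.0))
    heights = np.clip(heights, -cap, cap)

    pct = buried_volume(geometry, int(o_idx[0]), probe_radius=probe_radius,
                        method="grid", resolution=grid_step, vdw_radii=radii)
    return StericMap(x=ax, y=ax, heights=heights, buried_pct=pct)


def detect_transfer_events(
    trajectory: Trajectory,
    r_cut: float = 0.9,
) -> ReactionSeries:
    """Cumulative hydrogen-transfer events from a reaction trajectory.

    Frames are scanned in order; the first frame at which an unreacted
    (phenoxyl O, hydroperoxide H) pair comes strictly within ``r_cut``
    (minimum image) marks one irreversible event. Each oxygen and each
    hydrogen participates in at most one event, mirroring the finite
    reactant pool that saturates the count curve.
    """
    first = trajectory.frames[0]
    o_sites = first.select("phenoxyl_O")
    h_sites = first.select("hydroperoxide_H")
    reacted_o: set[int] = set()
    reacted_h: set[int] = set()
    times, counts = [], []
    n_events = 0
    for frame in trajectory.frames:
        free_o = np.array([o for o in o_sites if o not in reacted_o])
        free_h = np.array([h for h in h_sites if h not in reacted_h])
        if len(free_o) and len(free_h):
            d = np.linalg.norm(
                minimum_image_vectors(
                    frame.xyz[free_o][:, None, :], frame.xyz[free_h][None, :, :], frame.box
                ),
                axis=-1,
            )
            # greedy nearest-pair matching among sub-cutoff pairs
            while True:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                if not d[i, j] < r_cut:
                    break
                reacted_o.add(int(free_o[i]))
                reacted_h.add(int(free_h[j]))
                n_events += 1
                d[i, :] = np.inf
                d[:, j] = np.inf
        times.append(frame.time_ps / 1000.0)
        counts.append(n_events)
    return ReactionSeries(times_ns=np.array(times), counts=np.array(counts, dtype=float))
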