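"""Synthetic stand-ins for the reactive-MD inputs, with planted truth.

Each generator emits data whose ground truth is known exactly -- a
planted diffusivity, H-bond occupancy, or rate constant -- so every
downstream analysis stage can be validated as a recovery experiment.
The defaults mirror the study conditions: 100 phenoxyl radicals and 125
hydroperoxide donors per box, frames saved every 4 ps over 2 ns (500
frames), and three independent realizations per candidate.

All generators are bit-reproducible given (seed, parameters); a
realization ``r`` of a multi-realization call uses ``seed + r``.
"""

from __future__ import annotations

import numpy as np

from .geometry import build_hydroperoxide_proxy, build_radical_geometry
from .library import SubstitutionPattern
from .trajectory import Frame, ReactionSeries, Trajectory, minimum_image_vectors

__all__ = [
    "make_brownian_trajectory",
    "make_reaction_series",
    "build_radical_geometry",
    "make_hbond_scene",
    "make_mixture_frame",
    "simulate_transfer_trajectory",
]

DEFAULT_N_RADICALS = 100
DEFAULT_N_HYDROPEROXIDES = 125
DEFAULT_FRAME_INTERVAL_PS = 4.0
DEFAULT_N_FRAMES = 500  # 2 ns at 4 ps


def make_brownian_trajectory(
    n_particles: int,
    D_true: float,
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS,
    n_frames: int = DEFAULT_N_FRAMES,
    box: float = 50.0,
    seed: int = 0,
) -> Trajectory:
    """Unwrapped random-walk trajectory of point particles.

    Per-frame displacements are i.i.d. Gaussian with variance
    ``2 * D_true * frame_interval_ps`` per Cartesian component, the
    discrete-time realization of isotropic diffusion with coefficient
    ``D_true`` (A^2/ps). Particles are tagged ``phenoxyl_O`` so the MSD
    stage can select them by role like any other trajectory.
    """
    if D_true < 0:
        raise ValueError("D_true must be nonnegative")
    if frame_interval_ps <= 0:
        raise ValueError("frame_interval_ps must be positive")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * D_true * frame_interval_ps)
    start = rng.uniform(0.0, box, size=(n_particles, 3))
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, n_particles, 3))
    pos = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    boxv = np.full(3, float(box))
    frames = [
        Frame(
            time_ps=i * frame_interval_ps,
            elements=np.full(n_particles, "O", dtype=object),
            xyz=pos[i],
            molecule_ids=np.arange(n_particles),
            roles=np.full(n_particles, "phenoxyl_O", dtype=object),
            box=boxv,
        )
        for i in range(n_frames)
    ]
    return Trajectory(frames=frames, frame_interval_ps=frame_interval_ps,
                      unwrapped=True, metadata={"D_true": D_true, "seed": seed})


def make_reaction_series(
    k_true: float,
    n_radicals: int = DEFAULT_N_RADICALS,
    n_realizations: int = 3,
    seed: int = 0,
    times_ns: np.ndarray | None = None,
) -> list[ReactionSeries]:
    """Stochastic counterpart of the saturating-exponential model.

    Each radical reacts at an exponential time with rate ``k_true``
    (ns^-1); cumulative counts on the grid then have expectation
    ``n_radicals * (1 - exp(-k_true * t))``, the deterministic form the
    kinetics stage fits.
    """
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    if n_radicals < 1:
        raise ValueError("need at least one radical")
    if times_ns is None:
        times_ns = np.arange(1, DEFAULT_N_FRAMES + 1) * DEFAULT_FRAME_INTERVAL_PS / 1000.0
    times_ns = np.asarray(times_ns, dtype=float)
    if times_ns.size == 0:
        raise ValueError("empty time grid")
    out = []
    for r in range(n_realizations):
        rng = np.random.default_rng(seed + r)
        reaction_times = rng.exponential(1.0 / k_true, size=n_radicals)
        counts = (reaction_times[None, :] <= times_ns[:, None]).sum(axis=1)
        out.append(ReactionSeries(times_ns=times_ns.copy(), counts=counts.astype(float)))
    return out


def make_hbond_scene(
    n_frames: int = DEFAULT_N_FRAMES,
    occupancy_true: float = 0.6,
    d_bonded: float = 2.8,
    angle_bonded: float = 180.0,
    seed: int = 0,
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS,
) -> tuple[Trajectory, np.ndarray]:
    """Two-molecule scene with a planted per-frame H-bond occupancy.

    A phenoxyl-oxygen acceptor sits at the origin; a donor O-H pair is
    placed in the bonded geometry (donor-acceptor distance ``d_bonded``,
    donor-H-acceptor angle ``angle_bonded``) in a Bernoulli
    ``occupancy_true`` subset of frames and far away (> 4 A) otherwise.
    Returns the trajectory and the planted boolean truth labels.
    """
    if not 0.0 <= occupancy_true <= 1.0:
        raise ValueError("occupancy_true must be in [0, 1]")
    if not d_bonded < 3.0:
        raise ValueError("bonded-state distance must be < 3 A")
    if not angle_bonded > 150.0:
        raise ValueError("bonded-state angle must be > 150 deg")
    rng = np.random.default_rng(seed)
    bonded = rng.random(n_frames) < occupancy_true
    box = np.full(3, 30.0)
    center = box / 2.0
    oh = 0.97
    alpha = np.radians(angle_bonded)
    frames = []
    for i in range(n_frames):
        d_da = d_bonded if bonded[i] else 6.0
        # H placed so the donor-H-acceptor angle at H is exactly alpha
        # and the donor-acceptor distance exactly d_da
        h_x = oh * np.cos(alpha) + np.sqrt(d_da**2 - (oh * np.sin(alpha)) ** 2)
        hydrogen = center + np.array([h_x, 0.0, 0.0])
        donor = hydrogen + oh * np.array([-np.cos(alpha), np.sin(alpha), 0.0])
        frames.append(
            Frame(
                time_ps=i * frame_interval_ps,
                elements=np.array(["O", "O", "H"], dtype=object),
                xyz=np.stack([center, donor, hydrogen]),
                molecule_ids=np.array([0, 1, 1]),
                roles=np.array(["phenoxyl_O", "donor", "other"], dtype=object),
                box=box,
            )
        )
    traj = Trajectory(frames=frames, frame_interval_ps=frame_interval_ps,
                      unwrapped=False,
                      metadata={"occupancy_true": occupancy_true, "seed": seed})
    return traj, bonded


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_mixture_frame(
    patterns: list[SubstitutionPattern],
    n_radicals: int = DEFAULT_N_RADICALS,
    n_hydroperoxides: int = DEFAULT_N_HYDROPEROXIDES,
    box: float = 70.0,
    seed: int = 0,
    min_distance: float = 2.0,
    max_retries: int = 2000,
) -> Frame:
    """Randomly packed periodic box of radicals plus hydroperoxide donors.

    Rigid copies of the idealized geometries are placed with uniform
    random positions and orientations by rejection packing: a placement
    is accepted when every minimum-image intermolecular atom distance is
    at least ``min_distance``. Radical ``i`` uses
    ``patterns[i % len(patterns)]``.
    """
    if n_radicals < 0 or n_hydroperoxides < 0:
        raise ValueError("molecule counts must be nonnegative")
    if n_radicals > 0 and not patterns:
        raise ValueError("need at least one pattern to place radicals")
    rng = np.random.default_rng(seed)
    boxv = np.full(3, float(box))
    templates: list[Frame] = []
    for i in range(n_radicals):
        templates.append(build_radical_geometry(patterns[i % len(patterns)]))
    hp = build_hydroperoxide_proxy()
    templates.extend(hp for _ in range(n_hydroperoxides))

    placed_xyz: list[np.ndarray] = []
    elements, roles, mol_ids = [], [], []
    occupied = np.empty((0, 3))
    for mol_id, tpl in enumerate(templates):
        local = tpl.xyz - tpl.xyz.mean(axis=0)
        for attempt in range(max_retries):
            rot = _random_rotation(rng)
            shift = rng.uniform(0.0, box, size=3)
            cand = local @ rot.T + shift
            if occupied.size:
                d = minimum_image_vectors(occupied[:, None, :], cand[None, :, :], boxv)
                if np.min(np.linalg.norm(d, axis=-1)) < min_distance:
                    continue
            break
        else:
            raise RuntimeError(
                f"packing failed for molecule {mol_id} after {max_retries} retries; "
                f"achieved {mol_id}/{len(templates)} molecules in box {box} A"
            )
        placed_xyz.append(cand)
        occupied = np.concatenate([occupied, cand])
        elements.extend(tpl.elements)
        roles.extend(tpl.roles)
        mol_ids.extend([mol_id] * tpl.n_atoms)
    xyz = np.concatenate(placed_xyz) if placed_xyz else np.empty((0, 3))
    return Frame(
        time_ps=0.0,
        elements=np.array(elements, dtype=object),
        xyz=xyz % box,
        molecule_ids=np.array(mol_ids, dtype=int),
        roles=np.array(roles, dtype=object),
        box=boxv,
    )


def simulate_transfer_trajectory(
    mixture: Frame,
    k_true: float,
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS,
    n_frames: int = DEFAULT_N_FRAMES,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Piecewise-static toy dynamics with planted hydrogen-transfer events.

    Deliberately non-physical: atoms do not move except that, at each
    radical's exponentially drawn reaction time (rate ``k_true`` ns^-1),
    the nearest unreacted hydroperoxide hydrogen is teleported to 0.5 A
    from that radical's phenoxyl oxygen for all subsequent frames. The
    contract is only that the 0.9 A event criterion fires at the planted
    times. Returns the trajectory and the planted event times (ns, one
    per radical; inf = never reacts within coverage of available donors).
    """
    o_sites = mixture.select("phenoxyl_O")
    h_sites = mixture.select("hydroperoxide_H")
    if len(o_sites) == 0 or len(h_sites) == 0:
        raise ValueError("mixture must contain at least one radical and one hydroperoxide")
    rng = np.random.default_rng(seed)
    if k_true > 0:
        drawn = rng.exponential(1.0 / k_true, size=len(o_sites))
    else:
        drawn = np.full(len(o_sites), np.inf)
    total_ns = n_frames * frame_interval_ps / 1000.0

    # assign each reacting radical (in time order) its nearest free donor H
    event_times = np.full(len(o_sites), np.inf)
    moves: list[tuple[float, int, int]] = []  # (time_ns, h_atom, o_atom)
    free_h = list(h_sites)
    for rank in np.argsort(drawn):
        t = drawn[rank]
        if not np.isfinite(t) or t > total_ns or not free_h:
            continue
        o_atom = o_sites[rank]
        d = np.linalg.norm(
            minimum_image_vectors(mixture.xyz[o_atom], mixture.xyz[free_h], mixture.box),
            axis=-1,
        )
        h_atom = free_h.pop(int(np.argmin(d)))
        event_times[rank] = t
        moves.append((t, h_atom, o_atom))

    frames = []
    for i in range(n_frames):
        t_ns = (i + 1) * frame_interval_ps / 1000.0
        xyz = mixture.xyz.copy()
        for t_ev, h_atom, o_atom in moves:
            if t_ev <= t_ns:
                xyz[h_atom] = (mixture.xyz[o_atom] + np.array([0.5, 0.0, 0.0])) % mixture.box
        frames.append(
            Frame(
                time_ps=(i + 1) * frame_interval_ps,
                elements=mixture.elements,
                xyz=xyz,
                molecule_ids=mixture.molecule_ids,
                roles=mixture.roles,
                box=mixture.box,
            )
        )
    traj = Trajectory(frames=frames, frame_interval_ps=frame_interval_ps,
                      unwrapped=False,
                      metadata={"k_true": k_true, "seed": seed})
    return traj, event_times
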