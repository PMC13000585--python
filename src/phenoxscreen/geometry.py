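"""Idealized 3-D geometries for radicals and the hydroperoxide proxy.

Geometries are rigid, template-built structures from standard bond
lengths and angles -- not optimized conformers. Their purpose is to
exercise steric (buried volume, steric map) and packing analyses with
structures whose symmetry and sterics are controlled by construction.

Conventions: the aromatic ring lies in the xy plane with the phenoxyl
carbon (C1) on the +y axis, so the ring mirror symmetry (positions
2<->6, 3<->5) is the reflection x -> -x. Substituent local frames are
defined mirror-covariantly (the in-plane tangent flips handedness for
positions 5 and 6), which makes palindromic substitution patterns yield
exactly mirror-symmetric atom sets for ANY fragment orientation; only
position 4, which maps to itself, is restricted to orientations that
are themselves mirror-symmetric.

Fragment orientations (out-of-plane tilts alternating up at even ring
positions and down at odd ones, plus fixed torsional azimuths) were
chosen once so that no nonbonded atom pair in any filtered library
geometry comes closer than 1.6 A -- crowded ortho neighbors such as
tBu/Me interdigitate instead of clashing, standing in for the angle
strain and correlated rotations a real molecule would relax into.
"""

from __future__ import annotations

import numpy as np

from .library import SubstitutionPattern
from .trajectory import Frame

__all__ = ["build_radical_geometry", "build_hydroperoxide_proxy"]

# Bond lengths, Angstrom.
_CC_AROMATIC = 1.39
_CO_PHENOXYL = 1.25
_CH_AROMATIC = 1.09
_C_AR_SP3 = 1.51
_CC_SP3 = 1.53
_CH_SP3 = 1.09
_C_AR_OETHER = 1.36
_O_CH3 = 1.43
_C_AR_CARBOXYL = 1.48
_C_DBL_O = 1.21
_C_OH = 1.34
_O_H = 0.97
_O_O = 1.46

_COS_T = 1.0 / 3.0            # cos(180 deg - tetrahedral angle)
_SIN_T = np.sqrt(8.0) / 3.0

_W = np.array([0.0, 0.0, 1.0])  # ring normal

# Torsional azimuths (deg) and out-of-plane tilts (deg) of the fragment
# templates; the clash-free set described in the module docstring.
_ORIENT = {
    "tilt_me": 35.0, "az_me": 63.0,
    "tilt_tbu": 21.0, "az_tbu": 56.0, "az_tbuh": 82.0,
    "tilt_ome": 7.0, "bend_ome": 88.0, "az_omeh": 21.0,
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


class _Builder:
    def __init__(self) -> None:
        self.elements: list[str] = []
        self.xyz: list[np.ndarray] = []
        self.roles: list[str] = []
        self.bonds: list[tuple[int, int]] = []

    def add(self, element: str, pos: np.ndarray, role: str = "other",
            bond_to: int | None = None) -> int:
        idx = len(self.elements)
        self.elements.append(element)
        self.xyz.append(np.asarray(pos, dtype=float))
        self.roles.append(role)
        if bond_to is not None:
            self.bonds.append((bond_to, idx))
        return idx

    def frame(self, molecule_id: int = 0, time_ps: float = 0.0) -> Frame:
        n = len(self.elements)
        return Frame(
            time_ps=time_ps,
            elements=np.array(self.elements, dtype=object),
            xyz=np.array(self.xyz),
            molecule_ids=np.full(n, molecule_id),
            roles=np.array(self.roles, dtype=object),
        )


def _attach_substituent(b: _Builder, code: str, ring_idx: int,
                        ring_pos: np.ndarray, u: np.ndarray,
                        position: int) -> None:
    """Grow one substituent from a ring carbon along the radial unit u."""
    sign = -1.0 if position in (5, 6) else 1.0      # mirror-covariant handedness
    zsgn = 1.0 if position % 2 == 0 else -1.0        # tilt up at 2,4,6; down at 3,5
    at4 = position == 4
    P = _ORIENT

    def cone(axis: np.ndarray, ref: np.ndarray, az0: float) -> list[np.ndarray]:
        """Three unit vectors on the tetrahedral cone about axis."""
        a = _unit(axis)
        r = _unit(ref - np.dot(ref, a) * a)
        s = sign * np.cross(a, r)
        out = []
        for phi in (az0, az0 + 120.0, az0 + 240.0):
            p = np.radians(phi)
            out.append(_COS_T * a + _SIN_T * (np.cos(p) * r + np.sin(p) * s))
        return out

    def tilted(tau_deg: float) -> np.ndarray:
        t = np.radians(tau_deg)
        return np.cos(t) * u + zsgn * np.sin(t) * _W

    if code == "H":
        b.add("H", ring_pos + _CH_AROMATIC * u, bond_to=ring_idx)
    elif code == "Me":
        d0 = tilted(P["tilt_me"])
        c = ring_pos + _C_AR_SP3 * d0
        ci = b.add("C", c, bond_to=ring_idx)
        for d in cone(d0, zsgn * _W, 0.0 if at4 else P["az_me"]):
            b.add("H", c + _CH_SP3 * d, bond_to=ci)
    elif code == "tBu":
        d0 = tilted(P["tilt_tbu"])
        cq = ring_pos + _C_AR_SP3 * d0
        cqi = b.add("C", cq, bond_to=ring_idx)
        for d in cone(d0, zsgn * _W, 0.0 if at4 else P["az_tbu"]):
            cm = cq + _CC_SP3 * d
            cmi = b.add("C", cm, bond_to=cqi)
            ref = _W if abs(np.dot(_unit(d), _W)) < 0.95 else u
            for h in cone(d, ref, 60.0 if at4 else P["az_tbuh"]):
                b.add("H", cm + _CH_SP3 * h, bond_to=cmi)
    elif code == "OMe":
        o = ring_pos + _C_AR_OETHER * tilted(P["tilt_ome"])
        oi = b.add("O", o, bond_to=ring_idx)
        bend = np.radians(P["bend_ome"])  # methyl swings out of the ring plane
        dm = np.cos(bend) * u + zsgn * np.sin(bend) * _W
        cm = o + _O_CH3 * dm
        cmi = b.add("C", cm, bond_to=oi)
        for h in cone(dm, u, 0.0 if at4 else P["az_omeh"]):
            b.add("H", cm + _CH_SP3 * h, bond_to=cmi)
    elif code == "COOH":
        # carboxyl plane perpendicular to the ring (spanned by u and w)
        cc = ring_pos + _C_AR_CARBOXYL * u
        cci = b.add("C", cc, bond_to=ring_idx)
        d_dbl = _unit(0.5 * u + zsgn * np.sin(np.radians(60.0)) * _W)
        d_single = _unit(0.5 * u - zsgn * np.sin(np.radians(60.0)) * _W)
        b.add("O", cc + _C_DBL_O * d_dbl, bond_to=cci)
        oh = cc + _C_OH * d_single
        ohi = b.add("O", oh, role="donor", bond_to=cci)
        back = _unit(cc - oh)
        away = -zsgn * _W
        perp = _unit(away - np.dot(away, back) * back)
        hdir = np.cos(np.radians(105.0)) * back + np.sin(np.radians(105.0)) * perp
        b.add("H", oh + _O_H * hdir, bond_to=ohi)
    else:  # pragma: no cover - patterns validate codes upstream
        raise ValueError(f"unknown substituent code {code!r}")


def build_radical_geometry(
    pattern: SubstitutionPattern, *, return_bonds: bool = False
) -> Frame | tuple[Frame, list[tuple[int, int]]]:
    """Single-frame idealized structure of a substituted phenoxyl radical.

    Planar hexagonal ring (C-C 1.39 A) with an in-plane C-O of 1.25 A at
    position 1; the oxygen is tagged ``phenoxyl_O`` and the ipso carbon
    ``ring_C_ipso``. The carboxyl hydroxyl oxygen is tagged ``donor``
    (it is the only H-bond donor a radical can carry). With
    ``return_bonds=True`` also returns the covalent bond list as index
    pairs, used to separate bonded from nonbonded contacts in steric
    checks.
    """
    b = _Builder()
    # ring carbons: C1 at angle 90 deg, then clockwise C2..C6
    angles = np.radians(90.0 - 60.0 * np.arange(6))
    ring_pos = _CC_AROMATIC * np.stack(
        [np.cos(angles), np.sin(angles), np.zeros(6)], axis=1
    )
    ring_idx = [
        b.add("C", ring_pos[i], role="ring_C_ipso" if i == 0 else "other")
        for i in range(6)
    ]
    for i in range(6):
        b.bonds.append((ring_idx[i], ring_idx[(i + 1) % 6]))
    b.add("O", ring_pos[0] + _CO_PHENOXYL * _unit(ring_pos[0]),
          role="phenoxyl_O", bond_to=ring_idx[0])
    for k, code in enumerate(pattern.slots):
        i = k + 1
        _attach_substituent(b, code, ring_idx[i], ring_pos[i],
                            _unit(ring_pos[i]), position=i + 1)
    frame = b.frame()
    return (frame, b.bonds) if return_bonds else frame


def build_hydroperoxide_proxy() -> Frame:
    """Idealized tert-butyl hydroperoxide, the hydrogen-donor stand-in.

    A four-carbon stub carrying a tertiary -OOH replaces the full PAO
    (polyalphaolefin) trimer: downstream analyses only consume the
    labeled hydroperoxide O-H pair, and the small rigid body keeps
    mixture packing fast.
    """
    b = _Builder()
    cq = np.zeros(3)
    cqi = b.add("C", cq)
    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])

    def cone(axis, ref, az0):
        a = _unit(axis)
        r = _unit(ref - np.dot(ref, a) * a)
        s = np.cross(a, r)
        out = []
        for phi in (az0, az0 + 120.0, az0 + 240.0):
            p = np.radians(phi)
            out.append(_COS_T * a + _SIN_T * (np.cos(p) * r + np.sin(p) * s))
        return out

    o1 = cq + _O_CH3 * z
    o1i = b.add("O", o1, bond_to=cqi)
    for d in cone(-z, x, 0.0):
        cm = cq + _CC_SP3 * d
        cmi = b.add("C", cm, bond_to=cqi)
        for h in cone(d, z, 60.0):
            b.add("H", cm + _CH_SP3 * h, bond_to=cmi)
    # peroxide O-O, C-O-O angle ~107 deg
    bend = np.radians(180.0 - 107.0)
    o2 = o1 + _O_O * (np.cos(bend) * z + np.sin(bend) * x)
    o2i = b.add("O", o2, role="hydroperoxide_O", bond_to=o1i)
    back = _unit(o1 - o2)
    perp = _unit(x - np.dot(x, back) * back)
    hdir = np.cos(np.radians(100.0)) * back + np.sin(np.radians(100.0)) * perp
    b.add("H", o2 + _O_H * hdir, role="hydroperoxide_H", bond_to=o2i)
    return b.frame()
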