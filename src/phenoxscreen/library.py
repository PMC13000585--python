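"""Combinatorial phenoxyl-radical candidate library.

A candidate is a substituted phenoxyl radical: an aromatic six-ring with
an oxygen radical at position 1 and one substituent from the alphabet
{H, Me, OMe, tBu, COOH} at each of ring positions 2-6. Patterns that are
mirror images of each other (2<->6, 3<->5 swap) describe the same
molecule, so enumeration counts orbits of 5-letter strings under the
mirror involution: (5^5 + 5^3) / 2 = 1625 distinct patterns.

Structure-based filters then remove chemically unrealistic candidates
(sterically impossible tBu crowding, excessive substitution), leaving a
library of 718 radicals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .constants import ATOMIC_MASSES

__all__ = [
    "SUBSTITUENT_CODES",
    "SubstitutionPattern",
    "CandidateRecord",
    "mirror",
    "canonicalize",
    "enumerate_patterns",
    "passes_filters",
    "build_library",
    "pattern_to_smiles",
    "smiles_to_pattern",
    "molecular_mass",
    "position_substituent_counts",
    "library_to_frame",
]

#: Canonicalization total order on substituent codes (smaller = earlier).
SUBSTITUENT_CODES: tuple[str, ...] = ("H", "Me", "OMe", "tBu", "COOH")

_CODE_RANK = {c: i for i, c in enumerate(SUBSTITUENT_CODES)}

# Atoms added when a substituent replaces a ring hydrogen (net change).
_FORMULA_DELTA = {
    "H": {},
    "Me": {"C": 1, "H": 2},
    "OMe": {"C": 1, "H": 2, "O": 1},
    "tBu": {"C": 4, "H": 8},
    "COOH": {"C": 1, "O": 2},
}

# SMILES branch written after each ring carbon (empty = implicit H).
_SMILES_FRAGMENT = {
    "H": "",
    "Me": "C",
    "OMe": "OC",
    "tBu": "C(C)(C)C",
    "COOH": "C(=O)O",
}

#: Mass added relative to a ring hydrogen, g/mol.
MASS_CONTRIBUTION = {
    code: sum(ATOMIC_MASSES[el] * n for el, n in delta.items())
    for code, delta in _FORMULA_DELTA.items()
}

# Unsubstituted phenoxyl radical C6H5O.
_BASE_FORMULA = {"C": 6, "H": 5, "O": 1}
_BASE_MASS = sum(ATOMIC_MASSES[el] * n for el, n in _BASE_FORMULA.items())


@dataclass(frozen=True, order=True)
class SubstitutionPattern:
    """Assignment of one substituent code to each ring position 2-6.

    Position 1 carries the phenoxyl oxygen and is not a slot. Ordering
    (and hence canonical form) follows the code order H < Me < OMe <
    tBu < COOH applied lexicographically to the slot ranks.
    """

    slots: tuple[str, str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.slots) != 5:
            raise ValueError(f"expected 5 slots for positions 2-6, got {len(self.slots)}")
        for code in self.slots:
            if code not in _CODE_RANK:
                raise ValueError(f"unknown substituent code {code!r}")

    @property
    def rank_key(self) -> tuple[int, ...]:
        return tuple(_CODE_RANK[c] for c in self.slots)

    @property
    def n_substituents(self) -> int:
        return sum(1 for c in self.slots if c != "H")

    def slot(self, position: int) -> str:
        """Substituent code at ring position 2-6."""
        if not 2 <= position <= 6:
            raise ValueError("ring slot positions are 2-6")
        return self.slots[position - 2]


def mirror(pattern: SubstitutionPattern) -> SubstitutionPattern:
    """Ring mirror image: (s2,s3,s4,s5,s6) -> (s6,s5,s4,s3,s2)."""
    return SubstitutionPattern(pattern.slots[::-1])


def canonicalize(pattern: SubstitutionPattern) -> SubstitutionPattern:
    """The lexicographically smaller of a pattern and its mirror image."""
    m = mirror(pattern)
    return pattern if pattern.rank_key <= m.rank_key else m


def enumerate_patterns() -> set[SubstitutionPattern]:
    """All distinct substitution patterns modulo mirror symmetry.

    By Burnside's lemma over {identity, mirror} the count is
    (5^5 + 5^3) / 2 = 1625: the mirror fixes exactly the 5^3
    palindromic tuples.
    """
    return {
        canonicalize(SubstitutionPattern(slots))
        for slots in product(SUBSTITUENT_CODES, repeat=5)
    }


_RING_ADJACENT = ((0, 1), (1, 2), (2, 3), (3, 4))  # slot indices of (2,3),(3,4),(4,5),(5,6)


def passes_filters(
    pattern: SubstitutionPattern,
    *,
    max_tbu: int = 2,
    max_cooh: int = 2,
    max_substituents: int = 4,
    forbid_adjacent: bool = True,
    forbid_ortho_tbu_cooh: bool = True,
) -> bool:
    """Structure-based plausibility filters on a substitution pattern.

    A pattern passes when all hold:

    1. at most ``max_tbu`` tBu and at most ``max_cooh`` COOH groups;
    2. no ring-bonded adjacent pair -- positions (2,3), (3,4), (4,5),
       (5,6) -- is tBu/tBu or tBu/COOH (positions 2 and 6 both bond to
       C1 and are NOT adjacent to each other);
    3. the two ortho positions 2 and 6 do not carry one tBu and one
       COOH simultaneously;
    4. at most ``max_substituents`` non-H slots.

    The defaults reproduce the published 718-candidate library.
    """
    slots = pattern.slots
    counts = {c: slots.count(c) for c in ("tBu", "COOH")}
    if counts["tBu"] > max_tbu or counts["COOH"] > max_cooh:
        return False
    if forbid_adjacent:
        for i, j in _RING_ADJACENT:
            pair = {slots[i], slots[j]}
            if pair == {"tBu"} or pair == {"tBu", "COOH"}:
                return False
    if forbid_ortho_tbu_cooh and {slots[0], slots[4]} == {"tBu", "COOH"}:
        return False
    if pattern.n_substituents > max_substituents:
        return False
    return True


def molecular_mass(pattern: SubstitutionPattern) -> float:
    """Molecular mass of the substituted phenoxyl radical, g/mol."""
    return _BASE_MASS + sum(MASS_CONTRIBUTION[c] for c in pattern.slots)


def molecular_formula(pattern: SubstitutionPattern) -> dict[str, int]:
    """Element counts of the radical (C, H, O)."""
    formula = dict(_BASE_FORMULA)
    for code in pattern.slots:
        for el, n in _FORMULA_DELTA[code].items():
            formula[el] = formula.get(el, 0) + n
    return formula


def pattern_to_smiles(pattern: SubstitutionPattern) -> str:
    """RDKit-canonical SMILES of the radical encoded by a pattern.

    The raw string places the oxygen radical on ring atom 1 and walks
    positions 2-6; RDKit canonicalization makes the output independent
    of the walk direction.
    """
    frags = [_SMILES_FRAGMENT[c] for c in pattern.slots]
    body = "".join(f"c({f})" if f else "c" for f in frags[:4])
    tail = frags[4]
    raw = f"[O]c1{body}c1{tail}"
    mol = Chem.MolFromSmiles(raw)
    if mol is None:  # pragma: no cover - construction is total over the alphabet
        raise ValueError(f"internal SMILES construction failed for {pattern}")
    return Chem.MolToSmiles(mol)


def _classify_ring_substituent(ring_carbon: Chem.Atom, ring_idx: set[int]) -> str:
    """Map the branch attached to a ring carbon back to a substituent code."""
    branches = [
        nb for nb in ring_carbon.GetNeighbors() if nb.GetIdx() not in ring_idx
    ]
    if not branches:
        return "H"
    if len(branches) != 1:
        raise ValueError("ring carbon carries more than one substituent branch")
    a = branches[0]
    if a.GetSymbol() == "O":
        return "OMe"
    if a.GetSymbol() == "C":
        heavy = [nb for nb in a.GetNeighbors() if nb.GetIdx() != ring_carbon.GetIdx()
                 and nb.GetSymbol() != "H"]
        if not heavy:
            return "Me"
        if len(heavy) == 3 and all(nb.GetSymbol() == "C" for nb in heavy):
            return "tBu"
        if len(heavy) == 2 and all(nb.GetSymbol() == "O" for nb in heavy):
            return "COOH"
    raise ValueError("unrecognized substituent branch")


def smiles_to_pattern(smiles: str) -> SubstitutionPattern:
    """Invert :func:`pattern_to_smiles`: recover the canonical pattern.

    Locates the phenoxyl oxygen (exocyclic O bonded to an aromatic
    carbon, carrying the radical), walks the ring from the ipso carbon,
    classifies each branch, and canonicalizes over the two walk
    directions.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    phenoxyl_o = None
    for atom in mol.GetAtoms():
        if (atom.GetSymbol() == "O" and atom.GetDegree() == 1
                and atom.GetNumRadicalElectrons() == 1
                and atom.GetNeighbors()[0].GetIsAromatic()):
            phenoxyl_o = atom
            break
    if phenoxyl_o is None:
        raise ValueError("no phenoxyl oxygen radical found")
    ipso = phenoxyl_o.GetNeighbors()[0]
    ring_info = mol.GetRingInfo()
    ring = next(r for r in ring_info.AtomRings() if ipso.GetIdx() in r and len(r) == 6)
    ring_idx = set(ring)
    # Walk the ring starting at ipso, in one of the two directions.
    pos = ring.index(ipso.GetIdx())
    walk = [ring[(pos + k) % 6] for k in range(6)]
    codes = [
        _classify_ring_substituent(mol.GetAtomWithIdx(i), ring_idx) for i in walk[1:]
    ]
    return canonicalize(SubstitutionPattern(tuple(codes)))


@dataclass(frozen=True)
class CandidateRecord:
    """One filtered library entry: pattern plus derived identity fields."""

    candidate_id: int
    pattern: SubstitutionPattern
    smiles: str
    molecular_mass: float
    n_substituents: int


def build_library() -> list[CandidateRecord]:
    """Enumerate, filter, and serialize the candidate set (718 records).

    Records are ordered lexicographically on the canonical slot tuples
    (under the code order), so candidate ids are stable across runs.
    """
    survivors = sorted(
        (p for p in enumerate_patterns() if passes_filters(p)),
        key=lambda p: p.rank_key,
    )
    return [
        CandidateRecord(
            candidate_id=i,
            pattern=p,
            smiles=pattern_to_smiles(p),
            molecular_mass=molecular_mass(p),
            n_substituents=p.n_substituents,
        )
        for i, p in enumerate(survivors)
    ]


def library_to_frame(library: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Tabular view of the library (the candidates.csv schema)."""
    return pd.DataFrame(
        {
            "id": [r.candidate_id for r in library],
            **{
                f"slot_{pos}": [r.pattern.slot(pos) for r in library]
                for pos in range(2, 7)
            },
            "smiles": [r.smiles for r in library],
            "molecular_mass": [r.molecular_mass for r in library],
            "n_substituents": [r.n_substituents for r in library],
        }
    )


def position_substituent_counts(library: Iterable[CandidateRecord]) -> pd.DataFrame:
    """Count of each non-H substituent at each ring position 2-6.

    Counts are taken over the canonical orientation of each record (no
    double counting of mirror images), so positions 2/6 and 3/5 reflect
    the stored representative.
    """
    counts = pd.DataFrame(
        0,
        index=pd.Index(range(2, 7), name="position"),
        columns=[c for c in SUBSTITUENT_CODES if c != "H"],
    )
    for rec in library:
        for pos in range(2, 7):
            code = rec.pattern.slot(pos)
            if code != "H":
                counts.loc[pos, code] += 1
    return counts
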