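"""Hydrogen-suppressed molecular graphs for xanthone and its brominated congeners.

Xanthone (XTH, dibenzo-gamma-pyrone, C13H8O2) carries eight substitutable
CH positions, numbered 1-8 around the two benzo rings with 1 and 8 peri to
the carbonyl.  The scaffold has a mirror symmetry exchanging position i with
9 - i, which is what reduces the 255 non-empty bromination subsets to 135
symmetry-distinct congeners.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .elements import DEFAULT_ELEMENTS, Element

#: Mirror map of the xanthone scaffold (C2v symmetry): position i <-> 9 - i.
MIRROR = {i: 9 - i for i in range(1, 9)}

#: Multiplicative prefixes used in congener names (2 -> "DB" as in 2,8-DBXTH).
_PREFIX = {1: "MB", 2: "DB", 3: "TrB", 4: "TeB", 5: "PeB", 6: "HxB", 7: "HpB", 8: "OcB"}


@dataclass
class Atom:
    """One heavy atom: element, implicit hydrogens, optional coordinates."""

    index: int
    element: Element
    h_count: int = 0
    position: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.h_count < 0:
            raise ValueError("h_count must be >= 0")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
            if self.position.shape != (3,):
                raise ValueError("position must be a 3-vector")


@dataclass
class MolecularGraph:
    """A connected hydrogen-suppressed graph with bond orders.

    Bond orders are stored for file I/O fidelity but are not used by the
    descriptor construction (geometry and branching degrees carry the
    structural information).
    """

    name: str
    atoms: list[Atom]
    bonds: set[tuple[int, int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        norm = set()
        for i, j, order in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bad bond ({i}, {j})")
            norm.add((min(i, j), max(i, j), order))
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def has_positions(self) -> bool:
        return all(a.position is not None for a in self.atoms)

    def positions(self) -> np.ndarray:
        missing = [a.label or str(a.index) for a in self.atoms if a.position is None]
        if missing:
            raise ValueError(f"atoms without coordinates: {', '.join(missing)}")
        return np.array([a.position for a in self.atoms])

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, _ in self.bonds:
            a[i, j] = a[j, i] = 1.0
        return a

    def is_connected(self) -> bool:
        if not self.atoms:
            return False
        seen = {0}
        stack = [0]
        while stack:
            for j in self.neighbors(stack.pop()):
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_atoms


@dataclass(frozen=True)
class SubstitutionPattern:
    """A set of brominated positions in {1..8}, canonical under the mirror map."""

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(sorted(set(self.positions)))
        if any(p < 1 or p > 8 for p in pos):
            raise ValueError(f"positions must lie in 1..8, got {self.positions}")
        object.__setattr__(self, "positions", pos)

    @classmethod
    def from_string(cls, text: str) -> "SubstitutionPattern":
        """Parse "1,2,8"; "0", "" and "XTH" denote the unsubstituted parent."""
        text = text.strip()
        if text in ("", "0", "XTH", "xth"):
            return cls(())
        try:
            return cls(tuple(int(t) for t in text.split(",")))
        except ValueError as exc:
            raise ValueError(f"bad substitution pattern {text!r}") from exc

    def mirror(self) -> "SubstitutionPattern":
        return SubstitutionPattern(tuple(MIRROR[p] for p in self.positions))

    def canonical(self) -> "SubstitutionPattern":
        other = self.mirror()
        return self if self.positions <= other.positions else other

    def __str__(self) -> str:
        return ",".join(map(str, self.positions)) if self.positions else "XTH"

    def __len__(self) -> int:
        return len(self.positions)


def congener_name(pattern: SubstitutionPattern) -> str:
    """Name like "2,8-DBXTH"; the empty pattern is "XTH"."""
    k = len(pattern)
    if k == 0:
        return "XTH"
    return f"{','.join(map(str, pattern.positions))}-{_PREFIX[k]}XTH"


# Fig-label order of the 15 skeleton atoms: C1..C8, the four ring-fusion
# carbons, the ether oxygen, the carbonyl carbon, the carbonyl oxygen.
_SKELETON_LABELS = [
    "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8",
    "C4a", "C10a", "C8a", "C9a", "O10", "C9", "O9",
]
_SKELETON_INDEX = {lab: i for i, lab in enumerate(_SKELETON_LABELS)}

_SKELETON_BONDS = [
    # benzo ring A (positions 1-4)
    ("C1", "C2", 1), ("C2", "C3", 1), ("C3", "C4", 1),
    ("C4", "C4a", 1), ("C4a", "C9a", 1), ("C9a", "C1", 1),
    # benzo ring B (positions 5-8)
    ("C5", "C6", 1), ("C6", "C7", 1), ("C7", "C8", 1),
    ("C8", "C8a", 1), ("C8a", "C10a", 1), ("C10a", "C5", 1),
    # central pyranone ring closure
    ("C4a", "O10", 1), ("O10", "C10a", 1), ("C9a", "C9", 1), ("C9", "C8a", 1),
    # carbonyl
    ("C9", "O9", 2),
]


def build_xanthone() -> MolecularGraph:
    """Build the 15-heavy-atom xanthone scaffold (no coordinates).

    Positions 1-8 carry one implicit hydrogen each; fusion carbons, the
    carbonyl carbon and both oxygens carry none.
    """
    atoms = []
    for i, lab in enumerate(_SKELETON_LABELS):
        sym = "O" if lab.startswith("O") else "C"
        h = 1 if lab in {f"C{p}" for p in range(1, 9)} else 0
        atoms.append(Atom(index=i, element=DEFAULT_ELEMENTS[sym], h_count=h, label=lab))
    bonds = {(_SKELETON_INDEX[a], _SKELETON_INDEX[b], o) for a, b, o in _SKELETON_BONDS}
    return MolecularGraph(name="XTH", atoms=atoms, bonds=bonds)


def brominate(graph: MolecularGraph, pattern: SubstitutionPattern) -> MolecularGraph:
    """Append one Br per pattern position, bonded to that ring carbon.

    Atom ordering is deterministic: skeleton atoms first, then Br atoms in
    ascending position order.  Coordinates of the new Br atoms are left
    unset (the idealized-geometry generator fills them in).
    """
    atoms = [replace(a) for a in graph.atoms]
    bonds = set(graph.bonds)
    n = len(atoms)
    for k, p in enumerate(pattern.positions):
        lab = f"C{p}"
        if lab not in _SKELETON_INDEX:
            raise ValueError(f"position {p} outside 1..8")
        ci = _SKELETON_INDEX[lab]
        if atoms[ci].h_count < 1:
            raise ValueError(f"position {p} already substituted")
        atoms[ci].h_count -= 1
        atoms.append(Atom(index=n + k, element=DEFAULT_ELEMENTS["Br"], h_count=0,
                          label=f"Br{p}"))
        bonds.add((ci, n + k, 1))
    return MolecularGraph(name=congener_name(pattern), atoms=atoms, bonds=bonds)


def enumerate_patterns() -> list[SubstitutionPattern]:
    """All 135 symmetry-distinct non-empty bromination patterns.

    Every non-empty subset of {1..8} is reduced to its canonical
    representative under the mirror map; the list is sorted by bromine
    count, then lexicographically.
    """
    seen = set()
    for r in range(1, 9):
        for combo in itertools.combinations(range(1, 9), r):
            seen.add(SubstitutionPattern(combo).canonical().positions)
    return [SubstitutionPattern(p) for p in sorted(seen, key=lambda p: (len(p), p))]


def branching_degree(atom: Atom) -> int:
    """Branching degree v = z - h + 1 (valence electrons minus attached H, plus one)."""
    return atom.element.z - atom.h_count + 1


def branching_vector(graph: MolecularGraph) -> np.ndarray:
    return np.array([branching_degree(a) for a in graph.atoms], dtype=float)
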