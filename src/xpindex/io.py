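"""Structure file I/O: XYZ (with bond perception) and SDF/MOL V2000.

XYZ files carry no connectivity, so bonds are perceived from covalent
radii (two atoms are bonded when their distance is below 1.2 times the
radius sum); explicit hydrogens are folded into per-atom implicit counts.
SDF/MOL parsing goes through RDKit when available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .elements import DEFAULT_ELEMENTS
from .graph import Atom, MolecularGraph

#: Covalent radii (Angstrom) for the supported elements.
_COVALENT_RADIUS = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "Br": 1.20, "I": 1.39}
_BOND_SCALE = 1.2


def read_xyz(path) -> MolecularGraph:
    """Read an XYZ file into a hydrogen-suppressed graph with perceived bonds."""
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        n = int(lines[0].split()[0])
        body = lines[2:2 + n]
        syms, pos = [], []
        for line in body:
            parts = line.split()
            syms.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
        if len(syms) != n:
            raise ValueError("truncated atom block")
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed XYZ file {path}: {exc}") from exc
    pos = np.array(pos)
    unknown = sorted({s for s in syms if s not in _COVALENT_RADIUS})
    if unknown:
        raise ValueError(f"unsupported elements in {path}: {', '.join(unknown)}")

    # perceive bonds, then suppress hydrogens
    bonded = []
    for i in range(n):
        for j in range(i + 1, n):
            cut = _BOND_SCALE * (_COVALENT_RADIUS[syms[i]] + _COVALENT_RADIUS[syms[j]])
            if np.linalg.norm(pos[i] - pos[j]) <= cut:
                bonded.append((i, j))
    heavy = [i for i, s in enumerate(syms) if s != "H"]
    remap = {old: new for new, old in enumerate(heavy)}
    h_count = dict.fromkeys(heavy, 0)
    bonds = set()
    for i, j in bonded:
        if syms[i] == "H" and syms[j] == "H":
            continue
        if syms[i] == "H":
            h_count[j] += 1
        elif syms[j] == "H":
            h_count[i] += 1
        else:
            bonds.add((remap[i], remap[j], 1))
    atoms = [Atom(index=remap[i], element=DEFAULT_ELEMENTS[syms[i]],
                  h_count=h_count[i], position=pos[i], label=f"{syms[i]}{remap[i] + 1}")
             for i in heavy]
    return MolecularGraph(name=path.stem, atoms=atoms, bonds=bonds)


def write_xyz(graph: MolecularGraph, path, comment: str = "") -> None:
    """Write heavy atoms (implicit hydrogens are not expanded)."""
    pos = graph.positions()
    with open(path, "w") as fh:
        fh.write(f"{graph.n_atoms}\n{comment or graph.name}\n")
        for atom, p in zip(graph.atoms, pos):
            fh.write(f"{atom.element.symbol:<2s} {p[0]:14.8f} {p[1]:14.8f} {p[2]:14.8f}\n")


def read_sdf(path) -> MolecularGraph:
    """Read the first molecule of an SDF/MOL V2000 file (requires rdkit)."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SDF/MOL reading requires rdkit") from exc
    mol = Chem.MolFromMolFile(str(path), removeHs=True)
    if mol is None:
        raise ValueError(f"could not parse {path} as MOL/SDF")
    if mol.GetNumConformers() == 0:
        raise ValueError(f"{path} has no coordinates")
    conf = mol.GetConformer()
    atoms = []
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        if sym not in DEFAULT_ELEMENTS:
            raise ValueError(f"unsupported element {sym!r} in {path}")
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(index=a.GetIdx(), element=DEFAULT_ELEMENTS[sym],
                          h_count=a.GetTotalNumHs(),
                          position=np.array([p.x, p.y, p.z]),
                          label=f"{sym}{a.GetIdx() + 1}"))
    bonds = {(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
              max(1, int(b.GetBondTypeAsDouble()))) for b in mol.GetBonds()}
    return MolecularGraph(name=Path(path).stem, atoms=atoms, bonds=bonds)


def read_structure(path) -> MolecularGraph:
    """Dispatch on file extension (.xyz, .sdf, .mol)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        return read_xyz(path)
    if suffix in (".sdf", ".mol"):
        return read_sdf(path)
    raise ValueError(f"unrecognized structure format {suffix!r}")
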