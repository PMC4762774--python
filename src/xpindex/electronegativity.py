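"""Group and equilibrium electronegativities.

A substituent group is represented as a tree rooted at its anchor atom.
Its group electronegativity is the stepwise equal-weight average: a
single-atom group is just that atom's Pauling electronegativity, and a
deeper group averages the anchor with one equally weighted term per
attached subgroup, each subgroup averaged first.  For example

    chi(=CH2)   = (chi_C + 2 chi_H) / 3                       = 2.3167
    chi(-CHI2)  = (chi_C + chi_H + 2 chi_I) / 4               = 2.5175
    chi(-CH2CN) = (chi_C + 2 chi_H + (chi_C + chi_N)/2) / 4   = 2.4363

The equilibrium electronegativity of atom i in a molecule averages the
atom's own Pauling value with the group electronegativities of everything
attached to it:

    chi_i = (chi_iA + sum_G chi_G) / (1 + l)

where l counts the directly attached groups; each implicit hydrogen is a
single-atom group.  Group trees are grown away from atom i breadth-first,
never revisiting an atom already on the current root path (so rings
terminate naturally), and truncated at a configurable depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import DEFAULT_ELEMENTS, ElementTable
from .graph import MolecularGraph

DEFAULT_DEPTH_LIMIT = 3


@dataclass
class GroupTree:
    """A substituent tree; ``symbol`` is the anchor atom's element."""

    symbol: str
    children: list["GroupTree"] = field(default_factory=list)

    @classmethod
    def leaf(cls, symbol: str) -> "GroupTree":
        return cls(symbol)


def group_en(tree: GroupTree, elements: ElementTable = DEFAULT_ELEMENTS) -> float:
    """Equal-weight recursive group electronegativity of a substituent tree."""
    chi = elements[tree.symbol].chi_pauling
    if not tree.children:
        return chi
    total = chi + sum(group_en(c, elements) for c in tree.children)
    return total / (1 + len(tree.children))


def _grow_tree(graph: MolecularGraph, root: int, path: frozenset[int],
               depth: int, depth_limit: int) -> GroupTree:
    """Grow the group tree rooted at ``root``, away from the atoms in ``path``."""
    atom = graph.atoms[root]
    tree = GroupTree(atom.element.symbol)
    if depth >= depth_limit:
        return tree
    tree.children.extend(GroupTree.leaf("H") for _ in range(atom.h_count))
    new_path = path | {root}
    for j in graph.neighbors(root):
        if j not in new_path:
            tree.children.append(_grow_tree(graph, j, new_path, depth + 1, depth_limit))
    return tree


def equilibrium_en(graph: MolecularGraph, atom_index: int,
                   depth_limit: int = DEFAULT_DEPTH_LIMIT,
                   elements: ElementTable = DEFAULT_ELEMENTS) -> float:
    """Equilibrium electronegativity of one atom in the molecule."""
    if not 0 <= atom_index < graph.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range")
    if depth_limit < 1:
        raise ValueError("depth_limit must be >= 1")
    atom = graph.atoms[atom_index]
    chi = elements[atom.element.symbol].chi_pauling
    chi_h = elements["H"].chi_pauling
    groups = [chi_h] * atom.h_count
    for j in graph.neighbors(atom_index):
        tree = _grow_tree(graph, j, frozenset({atom_index}), 1, depth_limit)
        groups.append(group_en(tree, elements))
    return (chi + sum(groups)) / (1 + len(groups))


def en_vector(graph: MolecularGraph, depth_limit: int = DEFAULT_DEPTH_LIMIT,
              elements: ElementTable = DEFAULT_ELEMENTS) -> np.ndarray:
    """Equilibrium electronegativities of every heavy atom, in atom order."""
    return np.array([equilibrium_en(graph, i, depth_limit, elements)
                     for i in range(graph.n_atoms)])
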