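"""The XP1/XP2 eigenvalue descriptors.

Construction, for a molecule with n heavy atoms:

1. ``3D`` — the spatial topological distance matrix: pairwise distances in
   Angstrom, by default measured along the bond network (shortest path with
   real bond lengths as edge weights), optionally through space.
2. ``E`` — the equilibrium-electronegativity vector (one value per atom).
3. ``V`` — the branching-degree vector, v_i = z_i - h_i + 1.
4. ``S`` — the extension matrix combining the three.  Two readings of the
   product 3D x E x V are supported: the default "diagonal" strategy scales
   column j of 3D by chi_j * v_j; the "literal" strategy takes the stated
   vector product (3D e) v^T, which is rank one by construction.
5. ``Q = S S^T`` — the correction matrix, a Gram matrix and hence symmetric
   positive semidefinite.
6. XP1 = |smallest eigenvalue of Q|, XP2 = |largest eigenvalue of Q|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .elements import DEFAULT_ELEMENTS, ElementTable
from .electronegativity import DEFAULT_DEPTH_LIMIT, en_vector
from .graph import MolecularGraph, branching_vector

DEFAULT_TOL = 1e-8


@dataclass
class DistanceMatrix:
    """Pairwise inter-atomic distances (Angstrom)."""

    values: np.ndarray
    mode: str  # "bond-path" | "euclidean"


@dataclass
class Spectrum:
    """Real eigenvalues sorted ascending, with bookkeeping about the solve."""

    eigenvalues: np.ndarray
    max_imag_discarded: float
    symmetric_input: bool


@dataclass
class DescriptorMatrices:
    """All intermediate matrices of the construction for one molecule."""

    d3: DistanceMatrix
    e: np.ndarray
    v: np.ndarray
    s: np.ndarray
    q: np.ndarray
    strategy: str


@dataclass
class IndexResult:
    """XP1/XP2 plus the spectrum and the options that produced them."""

    name: str
    xp1: float
    xp2: float
    spectrum: Spectrum
    strategy: str
    distance_mode: str
    depth_limit: int

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "xp1": self.xp1,
            "xp2": self.xp2,
            "eigenvalues": self.spectrum.eigenvalues.tolist(),
            "strategy": self.strategy,
            "distance_mode": self.distance_mode,
            "depth_limit": self.depth_limit,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def spatial_distance_matrix(graph: MolecularGraph, mode: str = "bond-path") -> DistanceMatrix:
    """Spatial topological distances between all heavy-atom pairs.

    "bond-path" (default): shortest path through the bond network, each
    bond weighted by its Euclidean length.  "euclidean": straight-line
    distance.  All atoms must carry coordinates.
    """
    pos = graph.positions()
    if mode == "euclidean":
        diff = pos[:, None, :] - pos[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=-1))
    elif mode == "bond-path":
        n = graph.n_atoms
        w = np.zeros((n, n))
        for i, j, _ in graph.bonds:
            w[i, j] = w[j, i] = np.linalg.norm(pos[i] - pos[j])
        d = shortest_path(w, method="D", directed=False)
        if not np.all(np.isfinite(d)):
            raise ValueError(f"bond graph of {graph.name} is disconnected")
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return DistanceMatrix(values=d, mode=mode)


def extension_matrix(d3: np.ndarray, e: np.ndarray, v: np.ndarray,
                     strategy: str = "diagonal") -> np.ndarray:
    """Combine distances, electronegativities and branching degrees into S."""
    d3 = np.asarray(d3, dtype=float)
    e = np.asarray(e, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    n = d3.shape[0]
    if d3.shape != (n, n) or e.shape != (n,) or v.shape != (n,):
        raise ValueError(f"dimension mismatch: d3 {d3.shape}, e {e.shape}, v {v.shape}")
    if strategy == "diagonal":
        return d3 * (e * v)[None, :]
    if strategy == "literal":
        return np.outer(d3 @ e, v)
    raise ValueError(f"unknown strategy {strategy!r}")


def correction_matrix(s: np.ndarray) -> np.ndarray:
    """Q = S S^T (a Gram matrix, so symmetric positive semidefinite)."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError(f"S must be square, got shape {s.shape}")
    return s @ s.T


def spectrum(q: np.ndarray, tol: float = DEFAULT_TOL) -> Spectrum:
    """Eigenvalues of Q sorted ascending.

    A matrix symmetric to within ``tol`` (relative) goes through the
    symmetric solver.  Otherwise the general solver is used and imaginary
    parts are discarded only when negligible relative to the spectral
    radius; larger imaginary parts raise.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError(f"Q must be square, got shape {q.shape}")
    scale = np.abs(q).max() or 1.0
    symmetric = bool(np.abs(q - q.T).max() <= tol * scale)
    if symmetric:
        vals = np.linalg.eigvalsh(q)
        return Spectrum(np.sort(vals), 0.0, True)
    vals = np.linalg.eigvals(q)
    max_imag = float(np.abs(vals.imag).max())
    rho = float(np.abs(vals).max()) or 1.0
    if max_imag > tol * rho:
        raise ValueError(
            f"non-negligible imaginary eigenvalues (max |Im| = {max_imag:.4g}, "
            f"spectral radius {rho:.4g})")
    return Spectrum(np.sort(vals.real), max_imag, False)


def xp_indices(spec: Spectrum) -> tuple[float, float]:
    """XP1 = |smallest eigenvalue|, XP2 = |largest eigenvalue|."""
    vals = spec.eigenvalues
    if vals.size == 0:
        raise ValueError("empty spectrum")
    return float(abs(vals[0])), float(abs(vals[-1]))


def descriptor_matrices(graph: MolecularGraph, strategy: str = "diagonal",
                        distance_mode: str = "bond-path",
                        depth_limit: int = DEFAULT_DEPTH_LIMIT,
                        elements: ElementTable = DEFAULT_ELEMENTS) -> DescriptorMatrices:
    """All intermediate matrices (3D, E, V, S, Q) for one molecule."""
    d3 = spatial_distance_matrix(graph, distance_mode)
    e = en_vector(graph, depth_limit, elements)
    v = branching_vector(graph)
    s = extension_matrix(d3.values, e, v, strategy)
    q = correction_matrix(s)
    return DescriptorMatrices(d3=d3, e=e, v=v, s=s, q=q, strategy=strategy)


def compute_indices(graph: MolecularGraph, strategy: str = "diagonal",
                    distance_mode: str = "bond-path",
                    depth_limit: int = DEFAULT_DEPTH_LIMIT,
                    tol: float = DEFAULT_TOL,
                    elements: ElementTable = DEFAULT_ELEMENTS) -> IndexResult:
    """End-to-end XP1/XP2 computation for one coordinate-bearing molecule."""
    mats = descriptor_matrices(graph, strategy, distance_mode, depth_limit, elements)
    spec = spectrum(mats.q, tol)
    xp1, xp2 = xp_indices(spec)
    return IndexResult(name=graph.name, xp1=xp1, xp2=xp2, spectrum=spec,
                       strategy=strategy, distance_mode=distance_mode,
                       depth_limit=depth_limit)


def write_distance_matrix(path, dm: DistanceMatrix, labels: list[str]) -> None:
    """Write a square distance matrix as tab-delimited text with a label header."""
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in dm.values:
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def read_distance_matrix(path, mode: str = "bond-path") -> tuple[DistanceMatrix, list[str]]:
    """Read a distance matrix written by :func:`write_distance_matrix`."""
    with open(path) as fh:
        labels = fh.readline().split()
        rows = [[float(x) for x in line.split()] for line in fh if line.strip()]
    values = np.array(rows)
    n = len(labels)
    if values.shape != (n, n):
        raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
    return DistanceMatrix(values=values, mode=mode), labels
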