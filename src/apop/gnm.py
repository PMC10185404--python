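"""Gaussian network model: Kirchhoff (contact) matrix and its spectrum.

The GNM places identical harmonic springs between every pair of Cα nodes
within a distance cutoff.  Network topology is encoded in the Kirchhoff
matrix Γ: off-diagonal entries are −1 for contacting pairs (in units of the
base spring constant γ) and diagonals make every row sum to zero, so Γ is a
weighted graph Laplacian.  Its eigenvectors are vibrational modes; the
low-eigenvalue ("global") modes describe the collective motions that
allosteric perturbations act on.  The zero eigenvalue(s) — one per connected
component — correspond to uniform displacement and are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial.distance import pdist, squareform

from .errors import DisconnectedNetworkWarning, SpectrumError
from .structure_io import StructureModel

__all__ = [
    "GNMParameters",
    "KirchhoffMatrix",
    "GNMSpectrum",
    "build_kirchhoff",
    "decompose",
    "connected_components",
]

#: Relative eigenvalue threshold below which a mode counts as rigid-body.
DEFAULT_ZERO_TOL = 1e-8


@dataclass(frozen=True)
class GNMParameters:
    """Cutoff in Å and base spring constant γ in kcal mol⁻¹ Å⁻²."""

    cutoff: float = 10.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")


@dataclass
class KirchhoffMatrix:
    """N×N spring-weight matrix in units of γ, indexed by a node model.

    Invariants: symmetric, off-diagonals ≤ 0, rows sum to zero (hence
    positive semidefinite).  The base γ itself is carried in parameters, not
    here, so percentage eigenvalue shifts are γ-independent.
    """

    matrix: np.ndarray
    model: StructureModel | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or n < 2:
            raise ValueError("Kirchhoff matrix must be square with N >= 2")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def adjacency(self) -> np.ndarray:
        """Nonnegative spring-weight adjacency (off-diagonal part, negated)."""
        a = -self.matrix.copy()
        np.fill_diagonal(a, 0.0)
        return a


@dataclass
class GNMSpectrum:
    """Eigenvalues (ascending, zero modes removed) and orthonormal eigenvectors.

    ``eigenvectors[:, k]`` belongs to ``eigenvalues[k]``.  M + n_rigid_removed
    equals the node count N.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (N, M), columns aligned with eigenvalues
    n_rigid_removed: int = 1

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def build_kirchhoff(model: StructureModel, params: GNMParameters | None = None) -> KirchhoffMatrix:
    """Contact matrix Γ: −1 off-diagonal iff pair distance ≤ cutoff (inclusive).

    Diagonals are the node contact counts, built in integer arithmetic so row
    sums are exactly zero.
    """
    params = params or GNMParameters()
    if model.n_nodes < 2:
        raise ValueError("GNM needs at least two nodes")
    d = squareform(pdist(model.coords))
    contact = (d <= params.cutoff).astype(np.int64)
    np.fill_diagonal(contact, 0)
    k = -contact
    np.fill_diagonal(k, contact.sum(axis=1))
    return KirchhoffMatrix(matrix=k.astype(float), model=model)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|component| entry positive."""
    v = vectors.copy()
    for k in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, k])))
        if v[i, k] < 0:
            v[:, k] = -v[:, k]
    return v


def decompose(K: KirchhoffMatrix, zero_tol: float = DEFAULT_ZERO_TOL) -> GNMSpectrum:
    """Symmetric eigendecomposition of Γ with rigid/zero-mode removal.

    Eigenpairs with eigenvalue ≤ ``zero_tol`` × (largest eigenvalue) are
    removed; one such mode is the rigid-body mode of a connected network, and
    a disconnected network contributes one per component (warned).
    """
    w, v = np.linalg.eigh(K.matrix)
    w_max = float(w[-1])
    if w_max <= 0:
        raise SpectrumError("all eigenvalues are zero: network has no springs")
    keep = w > zero_tol * w_max
    n_removed = int((~keep).sum())
    if n_removed == 0:
        raise SpectrumError("no zero mode found: matrix is not a valid Laplacian")
    if n_removed > 1:
        warnings.warn(DisconnectedNetworkWarning(n_removed), stacklevel=2)
    if not keep.any():
        raise SpectrumError("all modes are rigid: no vibrational spectrum")
    return GNMSpectrum(
        eigenvalues=w[keep].copy(),
        eigenvectors=_fix_signs(v[:, keep]),
        n_rigid_removed=n_removed,
    )


def connected_components(K: KirchhoffMatrix) -> list[set[int]]:
    """Partition node indices by contact-graph connectivity."""
    adj = csr_matrix(K.adjacency() != 0)
    n, labels = _cc(adj, directed=False)
    comps: list[set[int]] = [set() for _ in range(n)]
    for i, lab in enumerate(labels):
        comps[int(lab)].add(i)
    return comps
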