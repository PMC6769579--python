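"""Heterogeneous lncRNA-disease-miRNA adjacency and its normalisation.

The network adjacency is the symmetric block matrix

    U = [[L,  A,  B ],
         [A', D,  C ],
         [B', C', M ]]

with L, D, M the within-type similarity networks and A, B, C the
lncRNA-disease, lncRNA-miRNA and disease-miRNA relation matrices.  Graph
convolutions consume the symmetrically normalised form
``Utilde = E^{-1/2} (U + I) E^{-1/2}`` where ``E`` is the diagonal degree
matrix of ``U + I``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import EntityCatalog

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class HeteroAdjacency:
    """The N x N block adjacency together with its catalog."""

    U: np.ndarray
    catalog: EntityCatalog

    @property
    def N(self) -> int:
        return self.U.shape[0]

    # block views (read-only slices of U)
    @property
    def L(self) -> np.ndarray:
        Nl = self.catalog.Nl
        return self.U[:Nl, :Nl]

    @property
    def A(self) -> np.ndarray:
        Nl, Nd = self.catalog.Nl, self.catalog.Nd
        return self.U[:Nl, Nl : Nl + Nd]

    @property
    def B(self) -> np.ndarray:
        Nl, Nd = self.catalog.Nl, self.catalog.Nd
        return self.U[:Nl, Nl + Nd :]

    @property
    def D(self) -> np.ndarray:
        Nl, Nd = self.catalog.Nl, self.catalog.Nd
        return self.U[Nl : Nl + Nd, Nl : Nl + Nd]

    @property
    def C(self) -> np.ndarray:
        Nl, Nd = self.catalog.Nl, self.catalog.Nd
        return self.U[Nl : Nl + Nd, Nl + Nd :]

    @property
    def M(self) -> np.ndarray:
        Nl, Nd = self.catalog.Nl, self.catalog.Nd
        return self.U[Nl + Nd :, Nl + Nd :]


@dataclass(frozen=True)
class NormalizedAdjacency:
    """``Utilde = E^{-1/2}(U+I)E^{-1/2}`` plus the degree vector of ``U+I``."""

    Utilde: np.ndarray
    E_diag: np.ndarray


def assemble_U(
    L: np.ndarray,
    D: np.ndarray,
    M: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    catalog: EntityCatalog,
) -> HeteroAdjacency:
    """Assemble the heterogeneous block adjacency from its six base matrices."""
    Nl, Nd, Nm = catalog.Nl, catalog.Nd, catalog.Nm
    expected = {
        "L": ((Nl, Nl), L),
        "D": ((Nd, Nd), D),
        "M": ((Nm, Nm), M),
        "A": ((Nl, Nd), A),
        "B": ((Nl, Nm), B),
        "C": ((Nd, Nm), C),
    }
    for name, (shape, mat) in expected.items():
        if np.shape(mat) != shape:
            raise ValueError(f"matrix {name} has shape {np.shape(mat)}, expected {shape}")
    for name in ("L", "D", "M"):
        mat = expected[name][1]
        if not np.allclose(mat, np.asarray(mat).T, atol=_SYM_TOL):
            raise ValueError(f"similarity matrix {name} is not symmetric")
    U = np.block([
        [np.asarray(L), np.asarray(A), np.asarray(B)],
        [np.asarray(A).T, np.asarray(D), np.asarray(C)],
        [np.asarray(B).T, np.asarray(C).T, np.asarray(M)],
    ]).astype(np.float64)
    return HeteroAdjacency(U=U, catalog=catalog)


def normalize(het: HeteroAdjacency | np.ndarray) -> NormalizedAdjacency:
    """Symmetric degree normalisation of the self-looped adjacency.

    Adds the identity (self-connections), computes the degree vector
    ``E_ii = sum_j (U + I)_ij`` and returns ``E^{-1/2}(U+I)E^{-1/2}``.  With
    non-negative ``U`` every degree is >= 1, so no zero-division guard is
    needed, and the result has spectral radius <= 1.
    """
    U = het.U if isinstance(het, HeteroAdjacency) else np.asarray(het, dtype=np.float64)
    if U.ndim != 2 or U.shape[0] != U.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {U.shape}")
    if (U < 0).any():
        raise ValueError("adjacency has negative entries")
    if not np.allclose(U, U.T, atol=_SYM_TOL):
        raise ValueError("adjacency is not symmetric")
    Uhat = U + np.eye(U.shape[0])
    E = Uhat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(E)
    Utilde = Uhat * inv_sqrt[:, None] * inv_sqrt[None, :]
    return NormalizedAdjacency(Utilde=Utilde, E_diag=E)
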