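import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from lncdis.catalog import EntityCatalog
from lncdis.hetnet import assemble_U, normalize


def random_similarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix with unit diagonal and entries in [0, 1]."""
    S = rng.random((n, n))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def random_network(rng: np.random.Generator, Nl=3, Nd=4, Nm=2, p=0.4):
    """Small random heterogeneous network: (catalog, het, Utilde, matrices)."""
    catalog = EntityCatalog(
        lncRNAs=[f"l{i}" for i in range(Nl)],
        diseases=[f"d{j}" for j in range(Nd)],
        miRNAs=[f"m{k}" for k in range(Nm)],
    )
    L = random_similarity(rng, Nl)
    D = random_similarity(rng, Nd)
    M = random_similarity(rng, Nm)
    A = (rng.random((Nl, Nd)) < p).astype(float)
    B = (rng.random((Nl, Nm)) < p).astype(float)
    C = (rng.random((Nd, Nm)) < p).astype(float)
    het = assemble_U(L, D, M, A, B, C, catalog)
    return catalog, het, normalize(het).Utilde, dict(L=L, D=D, M=M, A=A, B=B, C=C)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_catalog():
    return EntityCatalog(
        lncRNAs=["l0", "l1", "l2", "l3"],
        diseases=["d0", "d1", "d2", "d3"],
        miRNAs=["m0", "m1"],
    )
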