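"""Stable entity indexing shared by every matrix in the pipeline.

All matrices in the package are laid out against one :class:`EntityCatalog`:
lncRNAs occupy global node indices ``0..Nl-1``, diseases ``Nl..Nl+Nd-1`` and
miRNAs ``Nl+Nd..N-1``.  Keeping a single ordered catalog makes block slicing
of the heterogeneous adjacency trivially consistent with the per-relation
matrices.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field


def _check_unique(names: list[str], kind: str) -> None:
    if len(set(names)) != len(names):
        seen: set[str] = set()
        dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {kind} name: {dup!r}")


@dataclass(frozen=True)
class EntityCatalog:
    """Ordered index over lncRNA, disease and miRNA names.

    Parameters
    ----------
    lncRNAs, diseases, miRNAs:
        Ordered, unique entity names.  The order defines matrix row/column
        order everywhere downstream.
    """

    lncRNAs: tuple[str, ...]
    diseases: tuple[str, ...]
    miRNAs: tuple[str, ...]
    _lnc_index: dict[str, int] = field(init=False, repr=False, compare=False)
    _dis_index: dict[str, int] = field(init=False, repr=False, compare=False)
    _mir_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __init__(self, lncRNAs, diseases, miRNAs):
        lncRNAs = tuple(lncRNAs)
        diseases = tuple(diseases)
        miRNAs = tuple(miRNAs)
        _check_unique(list(lncRNAs), "lncRNA")
        _check_unique(list(diseases), "disease")
        _check_unique(list(miRNAs), "miRNA")
        object.__setattr__(self, "lncRNAs", lncRNAs)
        object.__setattr__(self, "diseases", diseases)
        object.__setattr__(self, "miRNAs", miRNAs)
        object.__setattr__(self, "_lnc_index", {n: i for i, n in enumerate(lncRNAs)})
        object.__setattr__(self, "_dis_index", {n: i for i, n in enumerate(diseases)})
        object.__setattr__(self, "_mir_index", {n: i for i, n in enumerate(miRNAs)})

    @property
    def Nl(self) -> int:
        return len(self.lncRNAs)

    @property
    def Nd(self) -> int:
        return len(self.diseases)

    @property
    def Nm(self) -> int:
        return len(self.miRNAs)

    @property
    def N(self) -> int:
        return self.Nl + self.Nd + self.Nm

    def lnc_index(self, name: str) -> int:
        return self._lnc_index[name]

    def disease_index(self, name: str) -> int:
        return self._dis_index[name]

    def mirna_index(self, name: str) -> int:
        return self._mir_index[name]

    def disease_node(self, j: int) -> int:
        """Global node index of disease ``j`` (lncRNAs come first)."""
        return self.Nl + j

    def mirna_node(self, k: int) -> int:
        """Global node index of miRNA ``k``."""
        return self.Nl + self.Nd + k

    def digest(self) -> str:
        """Stable hash of the catalog, stored in checkpoints."""
        h = hashlib.sha256()
        for group in (self.lncRNAs, self.diseases, self.miRNAs):
            for name in group:
                h.update(name.encode("utf-8"))
                h.update(b"\x00")
            h.update(b"\x01")
        return h.hexdigest()
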