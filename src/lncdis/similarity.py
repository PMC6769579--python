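"""Disease semantic similarity and entity functional similarity.

Disease similarity follows the DAG-based semantic construction of Wang et
al.: each disease contributes 1 to itself and a geometrically decaying
contribution (decay ``Delta``, default 0.5) to each ancestor term, taking the
maximum over paths; the similarity of two diseases is the sum of their
contributions over shared ancestors, normalised by their total semantic
values.

lncRNA (and miRNA) functional similarity follows the best-match-average
construction of Chen et al. over the disease sets the entities are
associated with: each disease in one set is matched to its most similar
disease in the other set, and the matched similarities are averaged over
both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

#: standard semantic contribution decay factor per child->parent hop
DEFAULT_DECAY = 0.5


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease ontology fragment as a child -> parents map.

    ``terms`` is the full term set; ``parents`` maps each term to its
    (possibly empty) set of parent terms.  The graph must be acyclic and
    closed (every parent is itself a term).
    """

    terms: frozenset[str]
    parents: Mapping[str, frozenset[str]]
    children: Mapping[str, frozenset[str]] = field(init=False, repr=False, compare=False)

    def __init__(self, terms, parents):
        terms = frozenset(terms)
        norm = {t: frozenset(parents.get(t, ())) for t in terms}
        for t, ps in norm.items():
            missing = ps - terms
            if missing:
                raise ValueError(f"term {t!r} has parent(s) not in the DAG: {sorted(missing)}")
        try:
            # child depends on parent: parents must come first in topo order
            list(TopologicalSorter({t: norm[t] for t in terms}).static_order())
        except CycleError as exc:
            raise ValueError(f"cycle detected in disease DAG: {exc.args[1]}") from exc
        children: dict[str, set[str]] = {t: set() for t in terms}
        for t, ps in norm.items():
            for p in ps:
                children[p].add(t)
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "parents", norm)
        object.__setattr__(self, "children", {t: frozenset(c) for t, c in children.items()})

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents[t])


def read_dag(path: str | Path) -> DiseaseDAG:
    """Read a DAG from a 2-column ``child TAB parent`` TSV.

    A line with an empty second column declares a root term.  Terms appearing
    only as parents are added to the term set automatically.
    """
    parents: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (1, 2) or not parts[0].strip():
                raise ValueError(f"{path}:{lineno}: malformed DAG line {line!r}")
            child = parts[0].strip()
            parents.setdefault(child, set())
            if len(parts) == 2 and parts[1].strip():
                parent = parts[1].strip()
                parents.setdefault(parent, set())
                parents[child].add(parent)
    return DiseaseDAG(terms=parents.keys(), parents=parents)


def write_dag(path: str | Path, dag: DiseaseDAG) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(dag.terms):
            ps = sorted(dag.parents[term])
            if not ps:
                fh.write(f"{term}\n")
            for p in ps:
                fh.write(f"{term}\t{p}\n")


def semantic_profile(dag: DiseaseDAG, disease: str, decay: float = DEFAULT_DECAY) -> dict[str, float]:
    """Semantic contribution of ``disease`` to itself and every ancestor.

    The disease contributes 1 to itself; an ancestor ``a`` receives
    ``decay * contribution(c)`` maximised over its children ``c`` that lie on
    a path from the disease.
    """
    if disease not in dag.terms:
        raise KeyError(f"disease term {disease!r} not in DAG")
    if not 0.0 < decay < 1.0:
        raise ValueError(f"decay must lie in (0, 1), got {decay}")
    contrib: dict[str, float] = {disease: 1.0}
    # monotone max-propagation to parents; terminates because the DAG is acyclic
    frontier = [disease]
    while frontier:
        term = frontier.pop()
        value = decay * contrib[term]
        for parent in dag.parents[term]:
            if value > contrib.get(parent, 0.0):
                contrib[parent] = value
                frontier.append(parent)
    return contrib


def disease_similarity(
    dag: DiseaseDAG,
    diseases: Sequence[str],
    decay: float = DEFAULT_DECAY,
) -> np.ndarray:
    """Pairwise Wang semantic similarity matrix over ``diseases``.

    ``D[i, j] = sum_{t in anc(i) ∩ anc(j)} (S_i(t) + S_j(t)) / (DV_i + DV_j)``
    where ``S_i`` is the semantic profile of disease ``i`` and ``DV_i`` its
    total semantic value.
    """
    missing = [d for d in diseases if d not in dag.terms]
    if missing:
        raise KeyError(f"disease term(s) missing from DAG: {missing}")
    profiles = [semantic_profile(dag, d, decay) for d in diseases]
    totals = np.array([sum(p.values()) for p in profiles])
    n = len(diseases)
    D = np.eye(n)
    for i in range(n):
        pi = profiles[i]
        for j in range(i + 1, n):
            pj = profiles[j]
            shared = pi.keys() & pj.keys()
            if shared:
                num = sum(pi[t] + pj[t] for t in shared)
                D[i, j] = D[j, i] = num / (totals[i] + totals[j])
    return D


def functional_similarity(assoc: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Best-match-average functional similarity of entities from ``assoc``.

    ``assoc`` is a binary entity x disease matrix; ``D`` the disease
    similarity matrix.  For entities ``a, b`` with disease sets ``Da, Db``::

        sim(a, b) = ( sum_{d in Da} max_{e in Db} D[d, e]
                    + sum_{e in Db} max_{d in Da} D[d, e] ) / (|Da| + |Db|)

    An entity with no associated disease is assigned similarity 0 to every
    other entity and 1 to itself (no-information prior).
    """
    assoc = np.asarray(assoc)
    if assoc.shape[1] != D.shape[0]:
        raise ValueError(f"assoc has {assoc.shape[1]} disease columns but D is {D.shape}")
    n = assoc.shape[0]
    sets = [np.flatnonzero(assoc[i]) for i in range(n)]
    S = np.eye(n)
    for a in range(n):
        Da = sets[a]
        if Da.size == 0:
            continue
        for b in range(a + 1, n):
            Db = sets[b]
            if Db.size == 0:
                continue
            sub = D[np.ix_(Da, Db)]
            value = (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (Da.size + Db.size)
            S[a, b] = S[b, a] = value
    return S
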