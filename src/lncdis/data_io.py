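"""Reading and writing edge lists, dense matrices and score tables.

File conventions
----------------
* Edge lists are 2-column TSV (UTF-8); lines starting with ``#`` are comments.
* Dense matrices are TSV with a header row and an index column of entity
  names, written at full double precision.
* Score output is a 3-column TSV (lncRNA, disease, score) sorted by
  descending score, ties broken lexicographically.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import EntityCatalog

logger = logging.getLogger(__name__)

#: association roles -> (row entity group, column entity group)
ROLES = {
    "lnc-dis": ("lncRNAs", "diseases"),
    "lnc-mir": ("lncRNAs", "miRNAs"),
    "dis-mir": ("diseases", "miRNAs"),
}


def _role_shape(catalog: EntityCatalog, role: str) -> tuple[int, int]:
    try:
        row_group, col_group = ROLES[role]
    except KeyError:
        raise ValueError(f"unknown association role {role!r}; expected one of {sorted(ROLES)}")
    return len(getattr(catalog, row_group)), len(getattr(catalog, col_group))


def _role_indexers(catalog: EntityCatalog, role: str):
    lookup = {
        "lncRNAs": catalog.lnc_index,
        "diseases": catalog.disease_index,
        "miRNAs": catalog.mirna_index,
    }
    row_group, col_group = ROLES[role]
    return lookup[row_group], lookup[col_group]


def iter_edge_lines(path: str | Path) -> Iterable[tuple[int, str, str]]:
    """Yield ``(line_number, name_a, name_b)`` from a 2-column TSV edge list."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
            yield lineno, parts[0].strip(), parts[1].strip()


def read_edge_list(
    path: str | Path,
    catalog: EntityCatalog,
    role: str,
    *,
    strict: bool = True,
) -> np.ndarray:
    """Read a name-pair edge list into a binary association matrix.

    Duplicate pairs collapse to a single edge (a warning is logged).  In
    strict mode an unknown entity name raises ``KeyError``; otherwise the
    offending edges are skipped and collected in the log.
    """
    shape = _role_shape(catalog, role)
    row_of, col_of = _role_indexers(catalog, role)
    mat = np.zeros(shape, dtype=np.float64)
    n_dup = 0
    n_skipped = 0
    for lineno, a, b in iter_edge_lines(path):
        try:
            i, j = row_of(a), col_of(b)
        except KeyError:
            if strict:
                raise KeyError(f"{path}:{lineno}: unknown entity name in pair ({a!r}, {b!r})")
            n_skipped += 1
            continue
        if mat[i, j]:
            n_dup += 1
        mat[i, j] = 1.0
    if n_dup:
        logger.warning("%s: %d duplicate edge(s) collapsed", path, n_dup)
    if n_skipped:
        logger.warning("%s: %d edge(s) with unknown names skipped", path, n_skipped)
    return mat


def write_edge_list(path: str | Path, pairs: Iterable[tuple[str, str]]) -> None:
    """Write name pairs as a 2-column TSV edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def edge_pairs(mat: np.ndarray, row_names: Sequence[str], col_names: Sequence[str]):
    """Inverse of :func:`read_edge_list`: the name pairs of the 1-entries."""
    rows, cols = np.nonzero(mat)
    return [(row_names[i], col_names[j]) for i, j in zip(rows, cols)]


def read_matrix(path: str | Path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a dense labelled numeric table written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    mat = df.to_numpy(dtype=np.float64)
    if not np.issubdtype(mat.dtype, np.number) or np.isnan(mat).any():
        raise ValueError(f"{path}: non-numeric or missing cell in matrix")
    if expected_shape is not None and mat.shape != tuple(expected_shape):
        raise ValueError(f"{path}: expected shape {tuple(expected_shape)}, got {mat.shape}")
    return mat


def write_matrix(
    path: str | Path,
    mat: np.ndarray,
    row_names: Sequence[str],
    col_names: Sequence[str],
) -> None:
    """Write a dense matrix as labelled TSV at full double precision."""
    df = pd.DataFrame(np.asarray(mat), index=list(row_names), columns=list(col_names))
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_scores(pairs: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    """Write (lncRNA, disease, score) rows sorted by descending score.

    Ties are broken by (lncRNA name, disease name) lexicographic order so the
    output is deterministic.
    """
    rows = list(pairs)
    for lnc, dis, score in rows:
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for pair ({lnc!r}, {dis!r}): {score}")
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lncRNA\tdisease\tscore\n")
        for lnc, dis, score in rows:
            fh.write(f"{lnc}\t{dis}\t{score:.17g}\n")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_CATALOG_KINDS = ("lncRNA", "disease", "miRNA")


def write_catalog(path: str | Path, catalog: EntityCatalog) -> None:
    """Write the catalog as a 2-column ``kind TAB name`` TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for kind, names in zip(_CATALOG_KINDS,
                               (catalog.lncRNAs, catalog.diseases, catalog.miRNAs)):
            for name in names:
                fh.write(f"{kind}\t{name}\n")


def read_catalog(path: str | Path) -> EntityCatalog:
    groups: dict[str, list[str]] = {k: [] for k in _CATALOG_KINDS}
    for lineno, kind, name in iter_edge_lines(path):
        if kind not in groups:
            raise ValueError(f"{path}:{lineno}: unknown entity kind {kind!r}")
        groups[kind].append(name)
    return EntityCatalog(lncRNAs=groups["lncRNA"], diseases=groups["disease"],
                         miRNAs=groups["miRNA"])
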