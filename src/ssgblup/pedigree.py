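"""Pedigree handling: reading, validation, inbreeding and relationship matrices.

The numerator relationship matrix ``A`` is built with the tabular method,
its sparse inverse with Henderson's rules adjusted for parental inbreeding,
and per-animal inbreeding coefficients with a memoised kinship recursion.
All public entry points accept/return animals in topologically sorted order
(parents always precede offspring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: sentinel label for an unknown parent
UNKNOWN = "UNKNOWN"

#: values in input files interpreted as "parent unknown"
DEFAULT_MISSING_CODES = frozenset({"0", "", "NA", ".", "unknown", UNKNOWN})

#: dense A is refused above this many animals unless the caller raises the cap
DENSE_SIZE_CAP = 5_000


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass
class PedigreeTable:
    """A validated, topologically sorted pedigree.

    Attributes
    ----------
    ids:
        Animal labels in sorted order (parents before offspring).
    sire, dam:
        Integer positions of each animal's parents within ``ids``;
        ``-1`` encodes an unknown parent.
    f:
        Inbreeding coefficients, computed lazily via :func:`inbreeding`.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    _f: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise PedigreeError("parent index arrays do not match id count")
        for p in (self.sire, self.dam):
            bad = np.nonzero(p >= np.arange(n))[0]
            if bad.size:
                raise PedigreeError(
                    f"animal {self.ids[bad[0]]!r} appears before its parent "
                    "(pedigree not topologically sorted)"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.ids)}

    @property
    def f(self) -> np.ndarray:
        if self._f is None:
            self._f = inbreeding(self)
        return self._f

    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.ids, dtype=object)
        sire = np.where(self.sire >= 0, ids[self.sire.clip(min=0)], UNKNOWN)
        dam = np.where(self.dam >= 0, ids[self.dam.clip(min=0)], UNKNOWN)
        return pd.DataFrame(
            {"animal": ids, "sire": sire, "dam": dam, "F": self.f}
        )

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame().drop(columns="F")
        df = df.replace(UNKNOWN, "0")
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Symmetric relationship matrix indexed by animal labels."""

    ids: list[str]
    values: np.ndarray
    kind: str  # one of {"A", "A22", "G", "Hinv_block"}

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError(f"{self.kind} matrix is not symmetric")

    def loc(self, i: str, j: str) -> float:
        idx = {a: k for k, a in enumerate(self.ids)}
        return float(self.values[idx[i], idx[j]])

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


# ---------------------------------------------------------------------------
# reading / sorting


def _toposort(
    ids: list[str], sire: list[str], dam: list[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Kahn's algorithm over parent->offspring edges; names a cycle member."""
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                children[pos[p]].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    order: list[int] = []
    while queue:
        i = queue.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        stuck = next(ids[i] for i in range(n) if indeg[i] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving {stuck!r}")
    new_pos = {ids[i]: k for k, i in enumerate(order)}
    sorted_ids = [ids[i] for i in order]
    s_idx = np.array(
        [new_pos[sire[i]] if sire[i] != UNKNOWN else -1 for i in order],
        dtype=np.int64,
    )
    d_idx = np.array(
        [new_pos[dam[i]] if dam[i] != UNKNOWN else -1 for i in order],
        dtype=np.int64,
    )
    return sorted_ids, s_idx, d_idx


def pedigree_from_records(
    animals: list[str], sires: list[str], dams: list[str]
) -> PedigreeTable:
    """Validate and sort raw animal/sire/dam triples into a PedigreeTable.

    Parents not listed as animals are auto-inserted as founders (with a
    warning); duplicate animal ids and cycles are hard errors.
    """
    seen: set[str] = set()
    for a in animals:
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r}")
        seen.add(a)
    extra = []
    for plist in (sires, dams):
        for p in plist:
            if p != UNKNOWN and p not in seen:
                seen.add(p)
                extra.append(p)
    if extra:
        logger.warning(
            "%d parent(s) not listed as animals; inserted as founders", len(extra)
        )
    ids = list(extra) + list(animals)
    sire = [UNKNOWN] * len(extra) + list(sires)
    dam = [UNKNOWN] * len(extra) + list(dams)
    return PedigreeTable(*_toposort(ids, sire, dam))


def read_pedigree(
    path: str | Path,
    animal_col: str = "animal",
    sire_col: str = "sire",
    dam_col: str = "dam",
    missing_codes: frozenset[str] = DEFAULT_MISSING_CODES,
    sep: str = ",",
) -> PedigreeTable:
    """Read a delimited pedigree file and return the sorted, validated table."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (animal_col, sire_col, dam_col):
        if col not in df.columns:
            raise PedigreeError(f"pedigree file lacks column {col!r}")

    def norm(v: str) -> str:
        v = v.strip()
        return UNKNOWN if v in missing_codes else v

    animals = [norm(v) for v in df[animal_col]]
    if UNKNOWN in animals:
        raise PedigreeError("an animal id matches a missing-value code")
    sires = [norm(v) for v in df[sire_col]]
    dams = [norm(v) for v in df[dam_col]]
    return pedigree_from_records(animals, sires, dams)


# ---------------------------------------------------------------------------
# inbreeding and relationship matrices


def _kinship_factory(ped: PedigreeTable):
    """Memoised additive-relationship function a(i, j) on sorted indices.

    Implemented with an explicit work stack (deep pedigrees would overflow
    Python's recursion limit).
    """
    sire, dam = ped.sire, ped.dam
    memo: dict[tuple[int, int], float] = {}

    def deps(i: int, j: int) -> list[tuple[int, int]]:
        # i <= j; j is the younger animal, expand through j's parents
        if i == j:
            pairs = [(sire[i], dam[i])]
        else:
            pairs = [(i, sire[j]), (i, dam[j])]
        return [
            (min(p, q), max(p, q)) for p, q in pairs if p >= 0 and q >= 0
        ]

    def a(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        stack = [(i, j)]
        while stack:
            key = stack[-1]
            if key in memo:
                stack.pop()
                continue
            pending = [d for d in deps(*key) if d not in memo]
            if pending:
                stack.extend(pending)
                continue
            p, q = key
            if p == q:
                s, d = sire[p], dam[p]
                val = 1.0 + (
                    0.5 * memo[(min(s, d), max(s, d))] if s >= 0 and d >= 0 else 0.0
                )
            else:
                val = 0.0
                for par in (sire[q], dam[q]):
                    if par >= 0:
                        val += 0.5 * memo[(min(p, par), max(p, par))]
            memo[key] = val
            stack.pop()
        return memo[(i, j)]

    return a


def inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficient F per animal: half the parents' relationship."""
    a = _kinship_factory(ped)
    f = np.zeros(len(ped))
    for i in range(len(ped)):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            f[i] = 0.5 * a(s, d)
    return f


def a_matrix(
    ped: PedigreeTable,
    subset: list[str] | None = None,
    size_cap: int = DENSE_SIZE_CAP,
) -> RelationshipMatrix:
    """Dense numerator relationship matrix A via the tabular method.

    When ``subset`` is given the returned matrix is restricted to those
    animals, in the order given (useful for the genotyped block A22).
    """
    n = len(ped)
    if n > size_cap:
        raise PedigreeError(
            f"refusing dense A for {n} animals (cap {size_cap}); raise size_cap"
        )
    if subset is not None:
        idx = ped.index
        missing = [a for a in subset if a not in idx]
        if missing:
            raise PedigreeError(f"subset ids absent from pedigree: {missing[:10]}")

    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)

    if subset is None:
        return RelationshipMatrix(list(ped.ids), A, "A")
    sel = np.array([ped.index[a] for a in subset])
    return RelationshipMatrix(list(subset), A[np.ix_(sel, sel)], "A")


def a_inverse(ped: PedigreeTable) -> sp.csr_matrix:
    """Sparse A⁻¹ from Henderson's rules with inbreeding adjustment.

    Each animal contributes 1/d_i to its own diagonal, -1/(2 d_i) to the
    animal-parent cells and 1/(4 d_i) among its known parents, where d_i is
    the Mendelian-sampling variance 1 - (1+F_sire)/4 - (1+F_dam)/4 with the
    term dropped for each unknown parent.
    """
    n = len(ped)
    f = ped.f
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        d = 1.0 - sum(0.25 * (1.0 + f[p]) for p in parents)
        if d <= 0:
            raise PedigreeError(
                f"non-positive Mendelian sampling variance for {ped.ids[i]!r}"
            )
        b = 1.0 / d
        rows.append(i)
        cols.append(i)
        vals.append(b)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * b, -0.5 * b]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * b)
    m = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return m.tocsr()


def a22(
    ped: PedigreeTable,
    genotyped_ids: list[str],
    size_cap: int = DENSE_SIZE_CAP,
) -> RelationshipMatrix:
    """Pedigree relationship block for the genotyped animals, in their order."""
    if len(genotyped_ids) == 0:
        raise PedigreeError("empty genotyped id set")
    m = a_matrix(ped, subset=list(genotyped_ids), size_cap=size_cap)
    return RelationshipMatrix(m.ids, m.values, "A22")


def write_matrix_market(matrix: sp.spmatrix, path: str | Path) -> None:
    """Export a sparse symmetric matrix in MatrixMarket coordinate format."""
    from scipy.io import mmwrite

    mmwrite(str(path), sp.coo_matrix(matrix))
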