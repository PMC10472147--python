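"""Pedigree reading, validation, renumbering, and pedigree relationship matrices.

The pedigree is the substrate of the numerator relationship matrix ``A``
(tabular method with inbreeding), its sparse inverse (Henderson's rules with
Meuwissen & Luo inbreeding coefficients), the genotyped-animal sub-block
``A22``, and the sib-strata classification used to summarise relationship
distributions (low-related / half-sib / full-sib).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import PedigreeError
from .relmatrix import RelationshipMatrix

UNKNOWN = "0"

_MISSING_TOKENS = {"", "0", "0.0", "na", "nan", "none", "null", "."}


def _norm_label(value) -> str:
    """Normalise an id cell; unknown-parent codes collapse to ``"0"``."""
    if value is None:
        return UNKNOWN
    if isinstance(value, float) and np.isnan(value):
        return UNKNOWN
    s = str(value).strip()
    return UNKNOWN if s.lower() in _MISSING_TOKENS else s


class RelationshipStratum(str, Enum):
    """Pairwise sib stratum: RT1 low-related, RT2 half-sib, RT3 full-sib."""

    RT1 = "RT1"
    RT2 = "RT2"
    RT3 = "RT3"


@dataclass(frozen=True)
class Pedigree:
    """Validated, topologically renumbered pedigree.

    ``sire``/``dam`` hold 1-based indices into ``ids`` (0 = unknown parent),
    so ``ids[sire[i] - 1]`` is the sire label of animal ``ids[i]``.  The
    ordering is topological: every parent index precedes its offspring.
    """

    ids: tuple[str, ...]
    sire: np.ndarray
    dam: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        """Label -> 1-based renumbered index."""
        return {lab: i + 1 for i, lab in enumerate(self.ids)}

    def parents_of(self, label: str) -> tuple[str | None, str | None]:
        i = self.index[str(label)] - 1
        s, d = int(self.sire[i]), int(self.dam[i])
        return (self.ids[s - 1] if s else None, self.ids[d - 1] if d else None)

    def to_frame(self) -> pd.DataFrame:
        """Renumbered cross-reference table ``animal,sire,dam,index``."""
        sire_lab = [self.ids[s - 1] if s else UNKNOWN for s in self.sire]
        dam_lab = [self.ids[d - 1] if d else UNKNOWN for d in self.dam]
        return pd.DataFrame(
            {
                "animal": list(self.ids),
                "sire": sire_lab,
                "dam": dam_lab,
                "index": np.arange(1, self.n + 1),
            }
        )

    def write_crossref(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _find_cycle(parents: dict[str, tuple[str, str]]) -> list[str]:
    """Locate one parent-link cycle for a readable error message."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {a: WHITE for a in parents}
    for start in parents:
        if colour[start] != WHITE:
            continue
        stack = [(start, iter([p for p in parents[start] if p != UNKNOWN]))]
        colour[start] = GREY
        path = [start]
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in parents:
                    continue
                if colour[nxt] == GREY:
                    return path[path.index(nxt):] + [nxt]
                if colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    path.append(nxt)
                    stack.append((nxt, iter([p for p in parents[nxt] if p != UNKNOWN])))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                path.pop()
                stack.pop()
    return []


def read_pedigree(source) -> Pedigree:
    """Read and validate a pedigree, inserting founders and renumbering.

    Parameters
    ----------
    source
        Path to a headered CSV ``animal,sire,dam`` ("0"/empty = unknown
        parent), a DataFrame with those columns, or an iterable of
        ``(animal, sire, dam)`` triples.

    Returns
    -------
    Pedigree
        Topologically renumbered; parents referenced but never listed as
        animals are auto-inserted as unknown-parent founders.  Ties in the
        topological sort are broken by first-appearance order, so output is
        deterministic.

    Raises
    ------
    PedigreeError
        On a parent-link cycle (named in the message) or on an animal
        recorded with two different parent sets.
    """
    if isinstance(source, pd.DataFrame):
        rows = source.itertuples(index=False)
        triples = [(r[0], r[1], r[2]) for r in rows]
    elif isinstance(source, (str, bytes)) or hasattr(source, "read"):
        df = pd.read_csv(source, dtype=str)
        cols = [c.lower() for c in df.columns]
        for need in ("animal", "sire", "dam"):
            if need not in cols:
                raise PedigreeError(f"pedigree file missing column {need!r}")
        df.columns = cols
        triples = list(df[["animal", "sire", "dam"]].itertuples(index=False))
    else:
        triples = [(a, s, d) for a, s, d in source]

    parents: dict[str, tuple[str, str]] = {}
    rank: dict[str, int] = {}
    for a, s, d in triples:
        a, s, d = _norm_label(a), _norm_label(s), _norm_label(d)
        if a == UNKNOWN:
            raise PedigreeError("animal id may not be the unknown code '0'")
        if a in parents:
            if parents[a] != (s, d):
                raise PedigreeError(
                    f"animal {a!r} recorded with conflicting parent sets "
                    f"{parents[a]} and {(s, d)}"
                )
            continue
        parents[a] = (s, d)
        rank.setdefault(a, len(rank))
    # founder auto-insertion, in first-mention order
    for a in list(parents):
        for p in parents[a]:
            if p != UNKNOWN and p not in parents:
                parents[p] = (UNKNOWN, UNKNOWN)
                rank.setdefault(p, len(rank))

    # Kahn topological sort; ready set popped by input rank for determinism
    children: dict[str, list[str]] = {a: [] for a in parents}
    pending = {}
    for a, (s, d) in parents.items():
        deps = {p for p in (s, d) if p != UNKNOWN}
        pending[a] = len(deps)
        for p in deps:
            children[p].append(a)
    ready = [(rank[a], a) for a, k in pending.items() if k == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        _, a = heapq.heappop(ready)
        order.append(a)
        for c in children[a]:
            pending[c] -= 1
            if pending[c] == 0:
                heapq.heappush(ready, (rank[c], c))
    if len(order) != len(parents):
        cycle = _find_cycle(parents)
        raise PedigreeError(
            "pedigree contains a cycle: " + " -> ".join(cycle)
            if cycle
            else "pedigree contains a cycle"
        )

    idx = {a: i + 1 for i, a in enumerate(order)}
    sire = np.array([idx.get(parents[a][0], 0) for a in order], dtype=np.int64)
    dam = np.array([idx.get(parents[a][1], 0) for a in order], dtype=np.int64)
    return Pedigree(ids=tuple(order), sire=sire, dam=dam)


# ---------------------------------------------------------------------------
# numerator relationship matrix and its inverse
# ---------------------------------------------------------------------------


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    ``a_ii = 1 + 0.5 * a_{sire(i), dam(i)}`` and
    ``a_ij = 0.5 * (a_{j, sire(i)} + a_{j, dam(i)})`` for ``j < i``;
    unknown parents contribute 0 (unrelated, non-inbred base animals).
    """
    n = ped.n
    a = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i] - 1, dam[i] - 1  # -1 = unknown
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * a[s, :i]
        if d >= 0:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(kind="A", ids=ped.ids, values=a)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo algorithm.

    Works ancestor-by-ancestor without forming A, so it scales to large
    pedigrees.  Returns ``F`` with ``F[i]`` for animal ``ped.ids[i]``.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    # F indexed 0..n with slot 0 = unknown parent; F[0] = -1 makes the
    # Mendelian-sampling term come out right for unknown parents.
    F = np.zeros(n + 1)
    F[0] = -1.0
    for i in range(1, n + 1):
        s, d = sire[i - 1], dam[i - 1]
        if s == 0 and d == 0:
            F[i] = 0.0
            continue
        L = {i: 1.0}
        aii = 0.0
        for j in range(i, 0, -1):
            lj = L.get(j)
            if lj is None:
                continue
            sj, dj = sire[j - 1], dam[j - 1]
            if sj:
                L[sj] = L.get(sj, 0.0) + 0.5 * lj
            if dj:
                L[dj] = L.get(dj, 0.0) + 0.5 * lj
            dvar = 0.5 - 0.25 * (F[sj] + F[dj])
            aii += lj * lj * dvar
        F[i] = aii - 1.0
    return F[1:]


def build_A_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse A-inverse by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of animal ``i`` uses the parents'
    inbreeding coefficients (Meuwissen & Luo), so the result is exact for
    inbred pedigrees: ``A_inverse @ A == I``.
    """
    n = ped.n
    F = inbreeding(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire[i] - 1, ped.dam[i] - 1
        if s >= 0 and d >= 0:
            dvar = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            dvar = 0.75 - 0.25 * F[max(s, d)]
        else:
            dvar = 1.0
        w = 1.0 / dvar
        add(i, i, w)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * w)
                add(p, i, -0.5 * w)
        known = [p for p in (s, d) if p >= 0]
        for p in known:
            for q in known:
                add(p, q, 0.25 * w)
    ainv = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n, n), dtype=float
    )
    ainv.sum_duplicates()
    return RelationshipMatrix(kind="A_inverse", ids=ped.ids, values=ainv)


def extract_A22(A: RelationshipMatrix, genotyped_ids: Sequence[str]) -> RelationshipMatrix:
    """Principal submatrix of A over the genotyped animals, in their order."""
    if A.kind != "A":
        raise PedigreeError(f"extract_A22 expects kind 'A', got {A.kind!r}")
    idx = A.index_of(genotyped_ids)
    sub = A.to_dense()[np.ix_(idx, idx)]
    return RelationshipMatrix(
        kind="A22", ids=tuple(str(g) for g in genotyped_ids), values=sub
    )


# ---------------------------------------------------------------------------
# sib strata
# ---------------------------------------------------------------------------


def classify_pair(ped: Pedigree, i: str, j: str) -> RelationshipStratum:
    """Classify an animal pair: RT3 full-sib, RT2 half-sib, RT1 otherwise.

    RT3 requires the same recorded sire AND the same recorded dam; RT2 a
    single shared recorded parent.  Unknown parents never count as shared,
    so pairs with partially unknown pedigree default to RT1 unless a
    recorded parent forces RT2.
    """
    i, j = str(i), str(j)
    if i == j:
        raise PedigreeError("classify_pair requires two distinct animals")
    index = ped.index
    ii, jj = index[i] - 1, index[j] - 1
    si, di = int(ped.sire[ii]), int(ped.dam[ii])
    sj, dj = int(ped.sire[jj]), int(ped.dam[jj])
    if si and di and si == sj and di == dj:
        return RelationshipStratum.RT3
    pi = {p for p in (si, di) if p}
    pj = {p for p in (sj, dj) if p}
    return RelationshipStratum.RT2 if pi & pj else RelationshipStratum.RT1


def _strata_masks(ped: Pedigree, ids: Sequence[str]) -> dict[RelationshipStratum, np.ndarray]:
    """Boolean upper-triangle pair masks per stratum, vectorised."""
    index = ped.index
    pos = np.array([index[str(i)] - 1 for i in ids])
    s = ped.sire[pos]
    d = ped.dam[pos]
    same_sire = (s[:, None] == s[None, :]) & (s[:, None] != 0)
    same_dam = (d[:, None] == d[None, :]) & (d[:, None] != 0)
    cross_sd = (s[:, None] == d[None, :]) & (s[:, None] != 0)
    cross_ds = (d[:, None] == s[None, :]) & (d[:, None] != 0)
    rt3 = same_sire & same_dam
    shared_any = same_sire | same_dam | cross_sd | cross_ds
    rt2 = shared_any & ~rt3
    upper = np.triu(np.ones_like(rt3, dtype=bool), k=1)
    return {
        RelationshipStratum.RT3: rt3 & upper,
        RelationshipStratum.RT2: rt2 & upper,
        RelationshipStratum.RT1: ~shared_any & upper,
    }


def summarize_strata(
    M: RelationshipMatrix,
    ped: Pedigree,
    bins: int = 20,
) -> dict[str, dict]:
    """Per-stratum summary of the off-diagonal entries of ``M``.

    Pairs of ``M.ids`` are classified with :func:`classify_pair` semantics;
    each stratum reports count, mean, min, max and a histogram.  Empty
    strata report count 0 with statistics absent (None).
    """
    for lab in M.ids:
        if lab not in ped.index:
            raise PedigreeError(f"matrix id {lab!r} not in pedigree")
    dense = M.to_dense()
    masks = _strata_masks(ped, M.ids)
    out: dict[str, dict] = {}
    for stratum, mask in masks.items():
        vals = dense[mask]
        entry: dict = {"count": int(vals.size)}
        if vals.size:
            hist, edges = np.histogram(vals, bins=bins)
            entry.update(
                mean=float(vals.mean()),
                min=float(vals.min()),
                max=float(vals.max()),
                histogram={"counts": hist.tolist(), "edges": edges.tolist()},
            )
        else:
            entry.update(mean=None, min=None, max=None, histogram=None)
        out[stratum.value] = entry
    return out
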