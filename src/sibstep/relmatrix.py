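"""Relationship-matrix container shared by the pedigree and genomic modules.

A :class:`RelationshipMatrix` couples a symmetric matrix with the ordered
animal labels that index it and a tag saying which construction produced it
(``A``, ``A_inverse``, ``A22``, ``G`` or ``H_inverse``).  All downstream code
(H-inverse assembly, mixed-model equations) relies on the id ordering carried
here, never on positional conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from .exceptions import SibstepError

VALID_KINDS = ("A", "A_inverse", "A22", "G", "H_inverse")


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with explicit id ordering.

    Parameters
    ----------
    kind
        One of ``A``, ``A_inverse``, ``A22``, ``G``, ``H_inverse``.
    ids
        Ordered animal labels; ``values[i, j]`` refers to ``ids[i]``/``ids[j]``.
    values
        Dense ndarray or scipy sparse matrix, n x n.
    meta
        Construction parameters (blend weight, frequency source, ...).
    """

    kind: str
    ids: tuple[str, ...]
    values: object
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise SibstepError(f"unknown relationship-matrix kind {self.kind!r}")
        self.ids = tuple(str(i) for i in self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise SibstepError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def index_of(self, labels: Sequence[str]) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.ids)}
        try:
            return np.array([lookup[str(lab)] for lab in labels], dtype=int)
        except KeyError as exc:
            raise SibstepError(f"id {exc.args[0]!r} not present in {self.kind} matrix")

    def is_symmetric(self, tol: float = 1e-10) -> bool:
        m = self.to_dense()
        scale = max(1.0, float(np.abs(m).max())) if m.size else 1.0
        return bool(np.abs(m - m.T).max() <= tol * scale) if m.size else True

    # -- sparse text export: `row_id col_id value`, lower triangle ----------

    def write_sparse_text(self, path) -> None:
        """Write nonzero lower-triangle entries (incl. diagonal), row-major."""
        m = self.to_dense()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("row_id\tcol_id\tvalue\n")
            for i in range(self.n):
                row = m[i, : i + 1]
                for j in np.nonzero(row)[0]:
                    fh.write(f"{self.ids[i]}\t{self.ids[j]}\t{row[j]:.12g}\n")

    @classmethod
    def read_sparse_text(cls, path, kind: str) -> "RelationshipMatrix":
        ids: list[str] = []
        seen: dict[str, int] = {}
        entries: list[tuple[str, str, float]] = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("row_id"):
                raise SibstepError(f"{path}: missing sparse-matrix header")
            for line in fh:
                r, c, v = line.rstrip("\n").split("\t")
                for lab in (r, c):
                    if lab not in seen:
                        seen[lab] = len(ids)
                        ids.append(lab)
                entries.append((r, c, float(v)))
        n = len(ids)
        m = np.zeros((n, n))
        for r, c, v in entries:
            i, j = seen[r], seen[c]
            m[i, j] = v
            m[j, i] = v
        return cls(kind=kind, ids=tuple(ids), values=m)
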