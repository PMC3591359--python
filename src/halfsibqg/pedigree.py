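"""Pedigree container, CSV I/O and the numerator relationship matrix.

A pedigree is a list of (individual, sire, dam) trios.  Parents that are
never listed as individuals are treated as founders, as are individuals
whose parents are recorded as missing ("0" or empty).  The additive
(numerator) relationship matrix A is built with the tabular method; the
designs supported here are non-inbred half-sib/full-sib families, but the
recursion is correct for arbitrary acyclic pedigrees.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_PARENT = ("", "0", "NA", "nan", None)


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, ...)."""


def _norm_parent(x) -> str | None:
    if x is None:
        return None
    s = str(x).strip()
    return None if s in ("", "0", "NA", "nan") else s


@dataclass
class Pedigree:
    """Validated pedigree in topological order (parents precede offspring).

    ``entries`` holds (individual_id, sire_id, dam_id) with ``None`` for an
    unknown (founder) parent.  Construct via :meth:`from_entries` or
    :func:`read_pedigree` so validation and topological sorting run.
    """

    entries: list[tuple[str, str | None, str | None]]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------------
    @classmethod
    def from_entries(
        cls, entries: list[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        entries = [(str(i), _norm_parent(s), _norm_parent(d)) for i, s, d in entries]
        ids = [e[0] for e in entries]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate individual id: {i!r}")
            seen.add(i)
        # implicit founders: parents never listed as individuals
        implicit = []
        for _, s, d in entries:
            for p in (s, d):
                if p is not None and p not in seen:
                    seen.add(p)
                    implicit.append((p, None, None))
        entries = implicit + entries
        ordered = cls._toposort(entries)
        ped = cls(entries=ordered)
        ped._index = {e[0]: k for k, e in enumerate(ordered)}
        return ped

    @staticmethod
    def _toposort(entries):
        by_id = {e[0]: e for e in entries}
        children: dict[str, list[str]] = {i: [] for i in by_id}
        indeg = {i: 0 for i in by_id}
        for i, s, d in entries:
            for p in {s, d} - {None}:
                if p == i:
                    raise PedigreeError(f"cycle detected involving id {i!r}")
                children[p].append(i)
                indeg[i] += 1
        queue = deque(i for i, _, _ in entries if indeg[i] == 0)
        ordered = []
        while queue:
            i = queue.popleft()
            ordered.append(by_id[i])
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(ordered) != len(entries):
            bad = next(i for i in indeg if indeg[i] > 0)
            raise PedigreeError(f"cycle detected involving id {bad!r}")
        return ordered

    # ------------------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def index_of(self, individual_id: str) -> int:
        return self._index[individual_id]

    @property
    def founders(self) -> list[str]:
        return [i for i, s, d in self.entries if s is None and d is None]

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    # ------------------------------------------------------------------
    def subset(self, keep_ids) -> "Pedigree":
        """Pedigree restricted to ``keep_ids`` plus all their ancestors."""
        want = set(keep_ids)
        by_id = {e[0]: e for e in self.entries}
        stack = list(want)
        while stack:
            i = stack.pop()
            _, s, d = by_id[i]
            for p in (s, d):
                if p is not None and p not in want:
                    want.add(p)
                    stack.append(p)
        return Pedigree.from_entries([e for e in self.entries if e[0] in want])


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with columns id, sire, dam (header required)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {c.lower().strip(): c for c in df.columns}
    for need in ("id", "sire", "dam"):
        if need not in cols:
            raise PedigreeError(f"pedigree file missing column {need!r}")
    entries = list(
        zip(df[cols["id"]], df[cols["sire"]], df[cols["dam"]], strict=True)
    )
    return Pedigree.from_entries(entries)


def write_pedigree(ped: Pedigree, path) -> None:
    df = pd.DataFrame(
        [(i, s or "0", d or "0") for i, s, d in ped.entries],
        columns=["id", "sire", "dam"],
    )
    if isinstance(path, io.TextIOBase):
        df.to_csv(path, index=False)
    else:
        df.to_csv(path, index=False)


# ----------------------------------------------------------------------
# Numerator relationship matrix
# ----------------------------------------------------------------------
@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix A indexed by individual id."""

    ids: list[str]
    values: np.ndarray

    def loc(self, i: str, j: str) -> float:
        idx = {v: k for k, v in enumerate(self.ids)}
        return float(self.values[idx[i], idx[j]])


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method A: a(i,j) = ½[a(j,s_i) + a(j,d_i)], a(i,i) = 1 + ½a(s_i,d_i).

    Founders are assumed non-inbred and mutually unrelated.
    """
    n = len(ped)
    A = np.zeros((n, n))
    idx = ped._index
    for k, (i, s, d) in enumerate(ped.entries):
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        row = np.zeros(k)
        if si is not None:
            row += 0.5 * A[si, :k]
        if di is not None:
            row += 0.5 * A[di, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[si, di] if (si is not None and di is not None) else 0.0)
    return RelationshipMatrix(ids=ped.ids, values=A)
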