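"""Pedigree container with validation, recoding and generation pruning.

A pedigree is stored as parallel arrays of 0-based sire/dam indices
(-1 = unknown parent) together with the original animal labels, kept in a
topological order so that parents always precede their offspring.  All
relationship-matrix code in :mod:`rngwas.relmat` relies on that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "PedigreeError"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, unknown parents...)."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    Attributes
    ----------
    ids : ndarray
        Original animal labels, in topological order.
    sire, dam : ndarray of int
        0-based positions of each animal's parents within ``ids``;
        ``-1`` encodes an unknown parent.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if not (len(self.sire) == len(self.dam) == n):
            raise PedigreeError("ids, sire and dam must have equal length")
        for par in (self.sire, self.dam):
            bad = (par >= np.arange(n)) & (par >= 0)
            if bad.any():
                raise PedigreeError(
                    "pedigree is not topologically sorted: parent listed at or "
                    f"after offspring for rows {np.flatnonzero(bad)[:5].tolist()}"
                )
            if (par < -1).any() or (par >= n).any():
                raise PedigreeError("parent index out of range")
        self._pos = {a: i for i, a in enumerate(self.ids.tolist())}
        if len(self._pos) != n:
            raise PedigreeError("duplicate animal ids in pedigree")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def position(self, animal) -> int:
        """0-based row of ``animal``; KeyError if absent."""
        return self._pos[animal]

    def positions(self, animals) -> np.ndarray:
        return np.array([self._pos[a] for a in animals], dtype=np.int64)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, unknown=0) -> "Pedigree":
        """Build from a (animal, sire, dam) table; ``unknown`` marks missing parents.

        The table need not be sorted: a topological order is derived, and a
        cycle (an animal that is its own ancestor) raises :class:`PedigreeError`.
        Parents that never appear as animals are added as founders.
        """
        cols = list(frame.columns[:3])
        animal = frame[cols[0]].to_numpy()
        sire = frame[cols[1]].to_numpy()
        dam = frame[cols[2]].to_numpy()
        if len(set(animal.tolist())) != len(animal):
            dup = frame[cols[0]][frame[cols[0]].duplicated()].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup!r}")
        known = set(animal.tolist())
        parents: dict = {}
        extra = []
        for a, s, d in zip(animal.tolist(), sire.tolist(), dam.tolist()):
            s = None if s == unknown or (isinstance(s, float) and np.isnan(s)) else s
            d = None if d == unknown or (isinstance(d, float) and np.isnan(d)) else d
            parents[a] = (s, d)
            for p in (s, d):
                if p is not None and p not in known:
                    known.add(p)
                    extra.append(p)
        for p in extra:
            parents[p] = (None, None)

        # stable Kahn's algorithm over the parent -> offspring DAG: ties are
        # broken by input row order, so an already-sorted table round-trips
        import heapq

        rank = {a: i for i, a in enumerate(parents)}
        order: list = []
        indeg = {a: sum(p is not None for p in ps) for a, ps in parents.items()}
        children: dict = {a: [] for a in parents}
        for a, (s, d) in parents.items():
            for p in (s, d):
                if p is not None:
                    children[p].append(a)
        heap = [(rank[a], a) for a, k in indeg.items() if k == 0]
        heapq.heapify(heap)
        while heap:
            _, a = heapq.heappop(heap)
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(heap, (rank[c], c))
        if len(order) != len(parents):
            cyc = sorted((a for a, k in indeg.items() if k > 0), key=str)
            raise PedigreeError(f"pedigree contains a cycle involving {cyc[:5]}")

        pos = {a: i for i, a in enumerate(order)}
        sire_ix = np.array(
            [-1 if parents[a][0] is None else pos[parents[a][0]] for a in order]
        )
        dam_ix = np.array(
            [-1 if parents[a][1] is None else pos[parents[a][1]] for a in order]
        )
        return cls(np.asarray(order), sire_ix, dam_ix)

    def to_frame(self, unknown=0) -> pd.DataFrame:
        sire = np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], unknown)
        dam = np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], unknown)
        return pd.DataFrame({"animal": self.ids, "sire": sire, "dam": dam})

    def generations(self) -> np.ndarray:
        """Generation number per animal: founders 0, else 1 + max(parents)."""
        gen = np.zeros(self.n, dtype=np.int64)
        for i in range(self.n):
            g = 0
            if self.sire[i] >= 0:
                g = max(g, gen[self.sire[i]] + 1)
            if self.dam[i] >= 0:
                g = max(g, gen[self.dam[i]] + 1)
            gen[i] = g
        return gen

    def prune(self, focal_ids, depth: int = 3) -> "Pedigree":
        """Restrict to focal animals plus at most ``depth`` ancestor generations.

        Parent links of retained animals whose parents fall outside the pruned
        set are cut (treated as unknown), which is the conventional way of
        truncating pedigree depth before building relationship matrices.
        """
        keep = np.zeros(self.n, dtype=bool)
        frontier = list(self.positions(focal_ids))
        keep[frontier] = True
        for _ in range(depth):
            nxt = []
            for i in frontier:
                for p in (self.sire[i], self.dam[i]):
                    if p >= 0 and not keep[p]:
                        keep[p] = True
                        nxt.append(p)
            frontier = nxt
        idx = np.flatnonzero(keep)
        remap = {old: new for new, old in enumerate(idx.tolist())}
        sire = np.array([remap.get(self.sire[i], -1) for i in idx])
        dam = np.array([remap.get(self.dam[i], -1) for i in idx])
        return Pedigree(self.ids[idx], sire, dam)
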