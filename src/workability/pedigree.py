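"""Pedigree container and additive-relationship algebra.

A pedigree is an ordered list of (animal, sire, dam) triples with parents
preceding their offspring and unknown parents coded as missing. Under the
infinitesimal model the additive-genetic covariance among animals is
proportional to the numerator relationship matrix A, whose entries follow
the classical tabular recursion:

    a(i, i) = 1 + F_i = 1 + a(s_i, d_i) / 2
    a(i, j) = (a(i, s_j) + a(i, d_j)) / 2     (j later in pedigree order)

with a missing parent contributing zero. The Mendelian-sampling variance of
animal i (relative to the additive variance) is

    D_i = 0.5 - 0.25 (F_s + F_d)   both parents known
        = 0.75 - 0.25 F_s          one parent known
        = 1.0                      founders

and underlies both the direct sparse construction of A^{-1} (Henderson's
rules) and exact simulation of breeding values down the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "PedigreeError"]

#: sentinel for an unknown parent in CSV files (animal-breeding convention)
UNKNOWN = "0"


class PedigreeError(ValueError):
    """Raised when a pedigree violates its ordering or structural contract."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or str(x) in ("", "0", "nan")


@dataclass
class Pedigree:
    """Ordered animal/sire/dam triples with unknown parents coded as missing.

    Parameters
    ----------
    animals : sequence of str
        Animal identifiers in an order where every parent precedes its
        offspring.
    sires, dams : sequence of str or None
        Parent identifiers aligned with ``animals``; ``None`` marks an
        unknown parent.
    """

    animals: list[str]
    sires: list[str | None]
    dams: list[str | None]
    _index: dict[str, int] = field(init=False, repr=False)
    _kin_cache: dict[tuple[int, int], float] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.animals = [str(a) for a in self.animals]
        self.sires = [None if _is_missing(s) else str(s) for s in self.sires]
        self.dams = [None if _is_missing(d) else str(d) for d in self.dams]
        if not (len(self.animals) == len(self.sires) == len(self.dams)):
            raise PedigreeError("animals, sires and dams must have equal length")
        self._index = {}
        for i, a in enumerate(self.animals):
            if a in self._index:
                raise PedigreeError(f"duplicate animal id {a!r}")
            self._index[a] = i
        for i, (a, s, d) in enumerate(zip(self.animals, self.sires, self.dams)):
            for p in (s, d):
                if p is None:
                    continue
                if p == a:
                    raise PedigreeError(f"animal {a!r} is its own parent")
                j = self._index.get(p)
                if j is None:
                    raise PedigreeError(f"parent {p!r} of {a!r} absent from pedigree")
                if j >= i:
                    raise PedigreeError(f"parent {p!r} does not precede offspring {a!r}")
        self._kin_cache = {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a DataFrame with columns animal, sire, dam (0=unknown)."""
        return cls(
            list(frame["animal"].astype(str)),
            [None if _is_missing(s) else str(s) for s in frame["sire"]],
            [None if _is_missing(d) else str(d) for d in frame["dam"]],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animals,
                "sire": [s if s is not None else UNKNOWN for s in self.sires],
                "dam": [d if d is not None else UNKNOWN for d in self.dams],
            }
        )

    # -- basic queries -------------------------------------------------

    def __len__(self) -> int:
        return len(self.animals)

    def __contains__(self, animal: str) -> bool:
        return str(animal) in self._index

    def index_of(self, animal: str) -> int:
        return self._index[str(animal)]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer sire/dam indices aligned with ``animals``; -1 = unknown."""
        s = np.array([-1 if p is None else self._index[p] for p in self.sires])
        d = np.array([-1 if p is None else self._index[p] for p in self.dams])
        return s, d

    def is_founder(self) -> np.ndarray:
        s, d = self.parent_indices()
        return (s < 0) & (d < 0)

    # -- relationship algebra ------------------------------------------

    def kinship_pair(self, i: int, j: int) -> float:
        """Additive relationship a(i, j) by memoized tabular recursion."""
        if i > j:
            i, j = j, i
        key = (i, j)
        cached = self._kin_cache.get(key)
        if cached is not None:
            return cached
        si, di = self.sires[j], self.dams[j]
        if i == j:
            if si is None or di is None:
                val = 1.0
            else:
                val = 1.0 + 0.5 * self.kinship_pair(self._index[si], self._index[di])
        else:
            val = 0.0
            if si is not None:
                val += 0.5 * self.kinship_pair(i, self._index[si])
            if di is not None:
                val += 0.5 * self.kinship_pair(i, self._index[di])
        self._kin_cache[key] = val
        return val

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficient F_i = a(sire_i, dam_i)/2 for every animal."""
        s, d = self.parent_indices()
        f = np.zeros(len(self))
        for i in range(len(self)):
            if s[i] >= 0 and d[i] >= 0:
                f[i] = 0.5 * self.kinship_pair(int(s[i]), int(d[i]))
        return f

    def mendelian_variances(self) -> np.ndarray:
        """Within-family (Mendelian-sampling) variance D_i for every animal."""
        s, d = self.parent_indices()
        f = self.inbreeding()
        dvar = np.ones(len(self))
        both = (s >= 0) & (d >= 0)
        dvar[both] = 0.5 - 0.25 * (f[s[both]] + f[d[both]])
        one_s = (s >= 0) & (d < 0)
        dvar[one_s] = 0.75 - 0.25 * f[s[one_s]]
        one_d = (s < 0) & (d >= 0)
        dvar[one_d] = 0.75 - 0.25 * f[d[one_d]]
        return dvar

    # -- editing -------------------------------------------------------

    def prune_singleton_parents(self, keep: Iterable[str]) -> "Pedigree":
        """Drop founder parents with a single offspring that are not in ``keep``.

        Removing an unrelated founder parent of exactly one animal and
        recoding that parent as unknown leaves the relationship matrix among
        the remaining animals unchanged (the founder is unrelated to
        everything else, and the offspring's diagonal stays 1 + F); it is the
        standard renumbering shortcut that exactly marginalizes the parent
        out of the animal model.
        """
        keep_set = {str(k) for k in keep}
        n_off = {}
        for p in self.sires + self.dams:
            if p is not None:
                n_off[p] = n_off.get(p, 0) + 1
        founders = set(np.array(self.animals)[self.is_founder()])
        drop = {
            a
            for a in self.animals
            if a in founders and a not in keep_set and n_off.get(a, 0) == 1
        }
        animals, sires, dams = [], [], []
        for a, s, d in zip(self.animals, self.sires, self.dams):
            if a in drop:
                continue
            animals.append(a)
            sires.append(None if s in drop else s)
            dams.append(None if d in drop else d)
        return Pedigree(animals, sires, dams)

    def subset_closure(self, animals: Sequence[str]) -> "Pedigree":
        """Restrict to ``animals`` plus all their ancestors, preserving order."""
        wanted = set()
        stack = [self._index[str(a)] for a in animals]
        while stack:
            i = stack.pop()
            if i in wanted:
                continue
            wanted.add(i)
            for p in (self.sires[i], self.dams[i]):
                if p is not None:
                    stack.append(self._index[p])
        idx = sorted(wanted)
        sel = set(idx)
        return Pedigree(
            [self.animals[i] for i in idx],
            [self.sires[i] if self.sires[i] is not None and self._index[self.sires[i]] in sel else None for i in idx],
            [self.dams[i] if self.dams[i] is not None and self._index[self.dams[i]] in sel else None for i in idx],
        )
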