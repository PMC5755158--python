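"""Pedigree container and CSV I/O.

A pedigree is an ordered list of (animal, sire, dam) triples; unknown parents
are coded as ``None`` internally and as ``0`` (or an empty field) on disk.
Records are kept topologically sorted so that every parent precedes its
offspring, the ordering required by the tabular relationship-matrix recursion
and by generation-order simulation of breeding values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

UNKNOWN = ("0", "", "NA", "na", ".", "none", "None")


class PedigreeError(ValueError):
    """Malformed pedigree: duplicate ids, self-parentage, or a cycle."""


@dataclass(frozen=True)
class PedigreeRecord:
    animal: str
    sire: str | None
    dam: str | None


@dataclass
class Pedigree:
    """Topologically sorted pedigree with O(1) id lookup."""

    records: list[PedigreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {r.animal: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            seen: set[str] = set()
            for r in self.records:
                if r.animal in seen:
                    raise PedigreeError(f"duplicate animal id {r.animal!r}")
                seen.add(r.animal)
        for i, r in enumerate(self.records):
            for parent in (r.sire, r.dam):
                if parent is None:
                    continue
                j = self._index.get(parent)
                if j is None:
                    raise PedigreeError(
                        f"parent {parent!r} of {r.animal!r} not in pedigree"
                    )
                if j >= i:
                    raise PedigreeError(
                        f"pedigree not sorted: parent {parent!r} does not "
                        f"precede {r.animal!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.animal for r in self.records]

    def index_of(self, animal: str) -> int:
        return self._index[animal]

    def parent_indices(self) -> list[tuple[int, int]]:
        """(sire_idx, dam_idx) per record, -1 for unknown."""
        out = []
        for r in self.records:
            s = self._index[r.sire] if r.sire is not None else -1
            d = self._index[r.dam] if r.dam is not None else -1
            out.append((s, d))
        return out

    @classmethod
    def from_triples(
        cls, triples: Iterable[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        """Build from unordered triples; missing parents become founders."""
        return cls(_toposort(list(triples)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": [r.animal for r in self.records],
                "sire": [r.sire if r.sire is not None else "0" for r in self.records],
                "dam": [r.dam if r.dam is not None else "0" for r in self.records],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _normalize(value) -> str | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in UNKNOWN or s.lower() == "nan":
        return None
    return s


def _toposort(
    triples: Sequence[tuple[str, str | None, str | None]]
) -> list[PedigreeRecord]:
    declared = {}
    for a, s, d in triples:
        a, s, d = _normalize(a), _normalize(s), _normalize(d)
        if a is None:
            raise PedigreeError("empty animal id")
        if a in declared:
            raise PedigreeError(f"duplicate animal id {a!r}")
        if a in (s, d):
            raise PedigreeError(f"animal {a!r} listed as its own parent")
        declared[a] = (s, d)
    # referenced-but-undeclared parents become founders
    for s, d in list(declared.values()):
        for p in (s, d):
            if p is not None and p not in declared:
                declared[p] = (None, None)
    # Kahn's algorithm, deterministic by insertion order then id
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(a: str, stack: list[str]) -> None:
        st = state.get(a, 0)
        if st == 1:
            cycle = stack[stack.index(a):] + [a]
            raise PedigreeError("pedigree cycle: " + " -> ".join(cycle))
        if st == 2:
            return
        state[a] = 1
        stack.append(a)
        for p in declared[a]:
            if p is not None:
                visit(p, stack)
        stack.pop()
        state[a] = 2
        order.append(a)

    for a in sorted(declared):
        visit(a, [])
    return [PedigreeRecord(a, declared[a][0], declared[a][1]) for a in order]


def read_pedigree(path: str | Path) -> Pedigree:
    """Read an animal,sire,dam CSV (header required; unknown parent 0/empty).

    Rows may appear in any order; the result is topologically sorted and
    parents referenced but never declared are added as founders.
    """
    df = pd.read_csv(path, dtype=str)
    cols = [c.lower().strip() for c in df.columns]
    required = {"animal", "sire", "dam"}
    if not required.issubset(cols):
        raise PedigreeError(f"pedigree file must have columns {sorted(required)}")
    df.columns = cols
    triples = list(zip(df["animal"], df["sire"], df["dam"]))
    return Pedigree.from_triples(triples)
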