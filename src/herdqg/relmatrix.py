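"""Numerator relationship matrix from a pedigree (tabular method).

A[i, j] is the expected additive genetic relationship (twice the kinship
coefficient) between animals i and j.  The tabular recursion over a
parent-first ordering is

    a_ii = 1 + a_{s(i), d(i)} / 2
    a_ij = (a_{j, s(i)} + a_{j, d(i)}) / 2      for j earlier than i,

with unknown parents contributing 0.  Diagonal entries are 1 + F_i where F_i
is the inbreeding coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree


@dataclass
class RelMatrix:
    """Dense symmetric A with its id index."""

    A: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self._index = {a: i for i, a in enumerate(self.ids)}

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = np.array([self._index[a] for a in ids])
        return self.A[np.ix_(idx, idx)]

    def value(self, a: str, b: str) -> float:
        return float(self.A[self._index[a], self._index[b]])

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.A) - 1.0


def numerator_relationship_matrix(ped: Pedigree) -> RelMatrix:
    n = len(ped)
    parents = ped.parent_indices()
    A = np.zeros((n, n))
    for i, (s, d) in enumerate(parents):
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        if i == 0:
            continue
        # off-diagonal row against all earlier animals, vectorized
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[:i, s]
        if d >= 0:
            row += 0.5 * A[:i, d]
        A[i, :i] = row
        A[:i, i] = row
    return RelMatrix(A, ped.ids)
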