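"""Exact rational linear algebra on small integer matrices.

Structural predicates on reaction networks (rank, kernels, positive
dependence of reaction vectors) must be decided exactly: the censuses are
integer counts and a single sign error flips them.  The matrices involved
are tiny (at most ~5 x 4), so plain Fraction-based Gaussian elimination is
both exact and fast enough for the enumeration hot loops.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

Matrix = list[list[Fraction]]


def _to_frac_matrix(rows: Sequence[Sequence]) -> Matrix:
    return [[Fraction(x) for x in row] for row in rows]


def rank(rows: Sequence[Sequence]) -> int:
    """Rank over the rationals via fraction Gaussian elimination."""
    m = _to_frac_matrix(rows)
    if not m or not m[0]:
        return 0
    nrows, ncols = len(m), len(m[0])
    r = 0
    for col in range(ncols):
        piv = next((i for i in range(r, nrows) if m[i][col] != 0), None)
        if piv is None:
            continue
        m[r], m[piv] = m[piv], m[r]
        inv = 1 / m[r][col]
        m[r] = [v * inv for v in m[r]]
        for i in range(nrows):
            if i != r and m[i][col] != 0:
                f = m[i][col]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        r += 1
        if r == nrows:
            break
    return r


def rref(rows: Sequence[Sequence]) -> tuple[Matrix, list[int]]:
    """Reduced row echelon form and pivot column indices."""
    m = _to_frac_matrix(rows)
    if not m or not m[0]:
        return m, []
    nrows, ncols = len(m), len(m[0])
    pivots: list[int] = []
    r = 0
    for col in range(ncols):
        piv = next((i for i in range(r, nrows) if m[i][col] != 0), None)
        if piv is None:
            continue
        m[r], m[piv] = m[piv], m[r]
        inv = 1 / m[r][col]
        m[r] = [v * inv for v in m[r]]
        for i in range(nrows):
            if i != r and m[i][col] != 0:
                f = m[i][col]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        pivots.append(col)
        r += 1
        if r == nrows:
            break
    return m, pivots


def nullspace(rows: Sequence[Sequence]) -> list[list[Fraction]]:
    """Basis of the right kernel, one vector per free column."""
    if not rows or not rows[0]:
        return []
    ncols = len(rows[0])
    red, pivots = rref(rows)
    free = [c for c in range(ncols) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * ncols
        v[fc] = Fraction(1)
        for r, pc in enumerate(pivots):
            v[pc] = -red[r][fc]
        basis.append(v)
    return basis


def left_nullspace(rows: Sequence[Sequence]) -> list[list[Fraction]]:
    """Basis of the left kernel (vectors w with w^T A = 0)."""
    if not rows:
        return []
    transposed = [list(col) for col in zip(*rows)]
    return nullspace(transposed)


def solve(rows: Sequence[Sequence], rhs: Sequence) -> list[Fraction] | None:
    """One exact solution of A x = b, or None if inconsistent."""
    if not rows:
        return None
    ncols = len(rows[0])
    aug = [list(row) + [b] for row, b in zip(rows, rhs)]
    red, pivots = rref(aug)
    # inconsistent iff a pivot lands in the rhs column
    if ncols in pivots:
        return None
    x = [Fraction(0)] * ncols
    for r, pc in enumerate(pivots):
        x[pc] = red[r][ncols]
    return x


def independent_rows(rows: Sequence[Sequence], k: int) -> list[int]:
    """Indices of the first k linearly independent rows, in order."""
    chosen: list[list] = []
    idx: list[int] = []
    for i, row in enumerate(rows):
        if rank(chosen + [list(row)]) == len(chosen) + 1:
            chosen.append(list(row))
            idx.append(i)
            if len(idx) == k:
                return idx
    raise ValueError(f"matrix has fewer than {k} independent rows")


def cross3(a: Sequence, b: Sequence) -> tuple:
    """Cross product of two length-3 vectors (exact if inputs are exact)."""
    return (
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    )


def sign(x) -> int:
    return int(x > 0) - int(x < 0)
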