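"""Cyclic S-matrices from the twin-prime quadratic-residue construction.

An S-matrix of order ``n`` is a binary {0,1} matrix that maximizes the
determinant among all n x n binary matrices; such matrices exist for
``n = 4w - 1`` and admit the closed-form inverse

    S^{-1} = 2/(n+1) * (2 S^T - J),

with ``J`` the all-ones matrix.  Cyclic S-matrices are additionally fully
determined by their first row: row ``i`` is the left circular shift of the
first row by ``i`` places, ``S[i, j] = S[0, (i + j) mod n]``.  The cyclic
property is what makes them practical for single-pixel imaging: every
encoding pattern is a physical translation of one master mask.

For twin primes ``p`` and ``q = p + 2`` a cyclic S-matrix of order
``n = p*q`` is built from the quadratic-residue indicator functions

    f(j) = +1 if j is a QR (mod p), 0 if j = 0 (mod p), -1 otherwise
    g(j) = +1 if j is a QR (mod q), 0 if j = 0 (mod q), -1 otherwise

with the first row given by  S[0, j] = 0 iff (f(j) - g(j)) * g(j) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy

__all__ = [
    "SMatrix",
    "twin_prime_smatrix",
    "smatrix_inverse",
    "validate_smatrix",
    "quadratic_residues",
]


def quadratic_residues(p: int) -> frozenset[int]:
    """Nonzero quadratic residues modulo ``p`` by exhaustive squaring."""
    return frozenset((z * z) % p for z in range(1, p)) - {0}


@dataclass(frozen=True)
class SMatrix:
    """A binary cyclic S-matrix with its twin-prime provenance.

    Attributes
    ----------
    p, q : int
        The twin primes, ``q = p + 2``.
    n : int
        Matrix order, ``n = p * q``; always ``n = 3 (mod 4)``.
    first_row : ndarray of shape (n,)
        The generating row; every other row is its left circular shift.
    matrix : ndarray of shape (n, n)
        Dense {0,1} integer matrix.
    """

    p: int
    q: int
    first_row: np.ndarray
    matrix: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.p * self.q

    @property
    def row_weight(self) -> int:
        """Number of ones in every row and column, (n+1)/2."""
        return (self.n + 1) // 2


def _residue_sign(j: int, modulus: int, residues: frozenset[int]) -> int:
    r = j % modulus
    if r == 0:
        return 0
    return 1 if r in residues else -1


def twin_prime_smatrix(p: int, q: int) -> SMatrix:
    """Construct the cyclic S-matrix of order ``p*q`` for twin primes.

    Parameters
    ----------
    p, q : int
        Twin primes with ``q = p + 2`` (e.g. 3 and 5, 11 and 13).

    Returns
    -------
    SMatrix
        Matrix of order ``n = p*q`` whose rows are left circular shifts of
        the quadratic-residue first row; every row carries (n+1)/2 ones.

    Raises
    ------
    ValueError
        If either argument is not prime or ``q != p + 2``.
    """
    if not sympy.isprime(p):
        raise ValueError(f"p={p} is not prime")
    if not sympy.isprime(q):
        raise ValueError(f"q={q} is not prime")
    if q != p + 2:
        raise ValueError(f"(p, q)=({p}, {q}) are not twin primes: q must equal p + 2")

    n = p * q
    qr_p = quadratic_residues(p)
    qr_q = quadratic_residues(q)

    first_row = np.empty(n, dtype=np.int64)
    for j in range(n):
        f = _residue_sign(j, p, qr_p)
        g = _residue_sign(j, q, qr_q)
        first_row[j] = 0 if (f - g) * g == 0 else 1

    # row i is the left circular shift of row 0 by i: S[i, j] = S[0, i+j mod n]
    idx = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
    matrix = first_row[idx]
    return SMatrix(p=p, q=q, first_row=first_row, matrix=matrix)


def smatrix_inverse(S: SMatrix | np.ndarray) -> np.ndarray:
    """Closed-form inverse ``2/(n+1) * (2 S^T - J)``.

    The entries take exactly two values, ``2/(n+1)`` and ``-2/(n+1)``;
    the product with ``S`` is the identity (exactly so in rational
    arithmetic, to rounding in floating point).
    """
    M = S.matrix if isinstance(S, SMatrix) else np.asarray(S)
    n = M.shape[0]
    if M.shape != (n, n):
        raise ValueError(f"S must be square, got shape {M.shape}")
    return (2.0 / (n + 1)) * (2 * M.T - 1)


def smatrix_inverse_exact(S: SMatrix | np.ndarray) -> tuple[np.ndarray, int]:
    """Inverse as an exact integer matrix plus denominator.

    Returns ``(2*S^T - J, (n+1)//2)`` so that ``S @ num == den * I`` holds in
    integer arithmetic — the rational identity ``S @ S^{-1} = I`` without
    floating point.
    """
    M = S.matrix if isinstance(S, SMatrix) else np.asarray(S)
    n = M.shape[0]
    num = (2 * M.T - 1).astype(np.int64)
    return num, (n + 1) // 2


def validate_smatrix(S: SMatrix | np.ndarray) -> dict[str, bool]:
    """Check the defining invariants of a cyclic S-matrix.

    Returns a pass/fail report (failures are reported, never raised):

    - ``cyclic``      : every row is the left circular shift of row 0
    - ``row_weight``  : every row has exactly (n+1)/2 ones
    - ``col_weight``  : every column has exactly (n+1)/2 ones
    - ``gram``        : S S^T = ((n+1)/4) (I + J) entrywise
    - ``binary``      : all entries in {0, 1}
    - ``all_pass``    : conjunction of the above
    """
    M = np.asarray(S.matrix if isinstance(S, SMatrix) else S, dtype=np.int64)
    n = M.shape[0]
    report: dict[str, bool] = {}

    report["binary"] = bool(np.isin(M, (0, 1)).all())

    idx = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
    report["cyclic"] = bool(np.array_equal(M, M[0][idx]))

    w = (n + 1) // 2
    report["row_weight"] = bool((M.sum(axis=1) == w).all())
    report["col_weight"] = bool((M.sum(axis=0) == w).all())

    # S S^T = ((n+1)/4)(I + J): off-diagonal (n+1)/4, diagonal (n+1)/2.
    # n = 3 (mod 4) so (n+1)/4 is integral; 4*Gram avoids any division.
    gram4 = 4 * (M @ M.T)
    expected = (n + 1) * (np.eye(n, dtype=np.int64) + 1)
    report["gram"] = bool(np.array_equal(gram4, expected))

    report["all_pass"] = all(report.values())
    return report
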