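"""Vec-permutation and block-construction utilities.

Everything downstream of this module manipulates block-structured matrices
built from stage-level and group-level pieces.  The three primitives here are

* the vec-permutation matrix ``K_{m,n}`` with ``K_{m,n} vec(X) = vec(X')``
  for every m-by-n matrix ``X``,
* the placement/selection pair ``(L_i, Q_i)`` that embeds a group-specific
  s-by-s matrix into block ``i`` of a gs-by-gs block-diagonal matrix, and
* structural constants of the absorbing chain: the "cleaving" matrix
  ``Z = [I | 0]`` that drops absorbing states, and the pair ``(C1, C2)``
  mapping the transient block and the death row into the full transition
  matrix.

Permutations are stored as index maps and applied by fancy indexing; dense
materialization is reserved for small matrices (test paths).  All matrices
follow the column-oriented convention: column = departing state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VecPermutation",
    "PlacementPair",
    "vec_perm",
    "placement",
    "structural_constants",
    "kron_vjp",
]


@dataclass(frozen=True)
class VecPermutation:
    """Permutation sending ``vec(X)`` to ``vec(X')`` for m-by-n ``X``.

    ``perm`` holds the row index map: ``(K @ v)[i] == v[perm[i]]``.
    """

    m: int
    n: int
    perm: np.ndarray

    @property
    def size(self) -> int:
        return self.m * self.n

    def apply(self, v: np.ndarray) -> np.ndarray:
        """K @ v (also works on matrices: permutes rows)."""
        return np.asarray(v)[self.perm]

    def apply_t(self, v: np.ndarray) -> np.ndarray:
        """K' @ v; since K is orthogonal this inverts :meth:`apply`."""
        out = np.empty_like(np.asarray(v))
        out[self.perm] = v
        return out

    def permute_cols(self, a: np.ndarray) -> np.ndarray:
        """A @ K — permutes columns of ``a``."""
        inv = np.empty_like(self.perm)
        inv[self.perm] = np.arange(self.perm.size)
        return np.asarray(a)[:, inv]

    def permute_cols_t(self, a: np.ndarray) -> np.ndarray:
        """A @ K'."""
        return np.asarray(a)[:, self.perm]

    @property
    def T(self) -> "VecPermutation":
        return vec_perm(self.n, self.m)

    def matrix(self) -> np.ndarray:
        """Dense materialization (small dimensions only)."""
        return np.eye(self.size)[self.perm]


def vec_perm(m: int, n: int) -> VecPermutation:
    """Vec-permutation matrix ``K_{m,n}``.

    For an m-by-n matrix X, ``vec(X')[j] = vec(X)[perm[j]]``.  Entry (i, j)
    of X sits at position j*m + i of vec(X) and at i*n + j of vec(X').
    """
    if m < 1 or n < 1:
        raise ValueError(f"vec_perm dimensions must be positive, got ({m}, {n})")
    j, i = np.meshgrid(np.arange(n), np.arange(m))  # i varies down rows
    # position i*n + j of the output takes input position j*m + i
    perm = (j * m + i).ravel(order="C")  # output ordered i-major: vec(X') order
    return VecPermutation(m=m, n=n, perm=perm)


@dataclass(frozen=True)
class PlacementPair:
    """Block-construction matrices for group ``i`` of ``g`` (s stages).

    ``L`` stacks I_s into block row i of a gs-by-s matrix; ``Q = L'`` selects
    block column i.  ``sum_i L_i U_i Q_i`` is block-diagonal with U_i in
    block i.
    """

    i: int
    s: int
    g: int

    @property
    def rows(self) -> slice:
        return slice((self.i - 1) * self.s, self.i * self.s)

    @property
    def L(self) -> np.ndarray:
        out = np.zeros((self.g * self.s, self.s))
        out[self.rows, :] = np.eye(self.s)
        return out

    @property
    def Q(self) -> np.ndarray:
        return self.L.T

    def embed(self, block: np.ndarray) -> np.ndarray:
        """L_i @ block @ Q_i without forming L, Q."""
        block = np.asarray(block)
        out = np.zeros((self.g * self.s, self.g * self.s))
        out[self.rows, self.rows] = block
        return out


def placement(i: int, s: int, g: int) -> PlacementPair:
    """Placement/selection pair ``(L_i, Q_i)`` for group ``i``."""
    if not 1 <= i <= g:
        raise ValueError(f"group index {i} out of range 1..{g}")
    return PlacementPair(i=i, s=s, g=g)


def block_diagonal(blocks: list[np.ndarray]) -> np.ndarray:
    """Block diagonal of square blocks (sum of L_i B_i Q_i)."""
    sizes = [np.asarray(b).shape[0] for b in blocks]
    n = sum(sizes)
    out = np.zeros((n, n))
    pos = 0
    for b, k in zip(blocks, sizes):
        out[pos : pos + k, pos : pos + k] = b
        pos += k
    return out


def structural_constants(gs: int, alpha: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Absorbing-chain structural matrices ``(Z, C1, C2)``.

    Z is gs x (gs+alpha), ``[I | 0]``: it cleaves absorbing states off a
    vector/matrix over the full chain; Z' glues them back on (as zeros).

    C1 and C2 (built for one absorbing state) relate the full transition
    matrix P = [[U, 0], [d, 1]] to its pieces:
    ``vec(P) = C1 vec(U) + C2 d + const`` with
    C1 = ([I; 0] kron [I; 0]) and C2 = ([I; 0] kron [0; 1]), so that
    ``d(vec P)/d(vec U) = C1 - C2 (I kron 1')``.
    """
    if gs < 1 or alpha < 1:
        raise ValueError("gs and alpha must be >= 1")
    Z = np.hstack([np.eye(gs), np.zeros((gs, alpha))])
    pad = np.vstack([np.eye(gs), np.zeros((alpha, gs))])  # [I; 0]
    tail = np.vstack([np.zeros((gs, 1)), np.ones((1, 1))])  # [0; 1]
    C1 = np.kron(pad, pad)
    C2 = np.kron(pad, tail)
    return Z, C1, C2


def kron_vjp(y: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-vector pullback ``y @ (A kron B)`` without forming the product.

    Uses the identity y (A kron B) = vec(B' Y A)' with Y the
    rows(B)-by-rows(A) column-major unvec of y.  This is the workhorse for
    chaining Jacobians whose Kronecker factors are model-sized while the
    product itself would be (gs)^2-by-(gs)^2.
    """
    y = np.asarray(y).ravel()
    A = np.asarray(A)
    B = np.asarray(B)
    if y.size != A.shape[0] * B.shape[0]:
        raise ValueError(
            f"dim(y)={y.size} not conformable with (A kron B) rows "
            f"{A.shape[0]}x{B.shape[0]}"
        )
    Y = y.reshape(A.shape[0], B.shape[0]).T  # column-major unvec
    return (B.T @ Y @ A).ravel(order="F")
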