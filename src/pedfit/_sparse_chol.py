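"""Fixed-pattern sparse Cholesky for the animal-model equations.

The Gibbs sampler draws all breeding values jointly each iteration from a
Gaussian whose precision is ``Q / s2 + diag(d)`` with ``Q`` the sparse
inverse relationship matrix — the sparsity pattern never changes, only the
values.  We therefore run the symbolic analysis (fill-reducing ordering via
reverse Cuthill-McKee, elimination pattern) once in Python, and per
iteration only the numeric factorisation and triangular solves, in numba.

The joint draw itself uses "perturb-and-solve": with prior ``a ~ N(0, s2 A)``
and Gaussian pseudo-observations, ``a = a0 + C^-1 rhs`` has exactly the
conditional posterior distribution when ``a0`` is a prior (gene-dropping)
draw and ``rhs`` includes appropriately perturbed data — only solves with
``C`` are needed, never a matrix square root of the posterior covariance.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.csgraph import reverse_cuthill_mckee


class CholeskyPattern:
    """Symbolic factorisation of a fixed SPD sparsity pattern.

    Parameters
    ----------
    Q
        Sparse symmetric matrix whose pattern (plus the diagonal) is the
        pattern of every matrix to be factorised.
    """

    def __init__(self, Q: sparse.csr_matrix) -> None:
        n = Q.shape[0]
        self.n = n
        perm = np.asarray(reverse_cuthill_mckee(Q.tocsr(), symmetric_mode=True))
        self.perm = perm
        self.iperm = np.empty(n, dtype=np.int64)
        self.iperm[perm] = np.arange(n)
        # permuted pattern, lower triangle, CSC (= CSR of upper)
        P = sparse.coo_matrix(
            (np.ones(Q.nnz), (self.iperm[Q.tocoo().row], self.iperm[Q.tocoo().col])),
            shape=(n, n),
        ).tocsc()
        A = sparse.tril(P, format="csc")
        A = (A + sparse.eye(n, format="csc")).tocsc()  # ensure diagonal

        # symbolic left-looking elimination
        cols: list[list[int]] = []
        rowlists: list[list[int]] = [[] for _ in range(n)]
        indptr, indices = A.indptr, A.indices
        for j in range(n):
            s = set(indices[indptr[j]:indptr[j + 1]])
            for k in rowlists[j]:
                s.update(i for i in cols[k] if i > j)
            s.discard(j)
            col = sorted(s)
            cols.append(col)
            for i in col:
                rowlists[i].append(j)

        # CSC arrays of L (diagonal stored first in each column)
        colptr = np.zeros(n + 1, dtype=np.int64)
        for j in range(n):
            colptr[j + 1] = colptr[j] + 1 + len(cols[j])
        rowidx = np.empty(colptr[n], dtype=np.int64)
        for j in range(n):
            rowidx[colptr[j]] = j
            rowidx[colptr[j] + 1 : colptr[j + 1]] = cols[j]
        self.colptr = colptr
        self.rowidx = rowidx
        self.nnz = int(colptr[n])

        # per-column update lists (the k < j with L[j,k] != 0), flattened
        upptr = np.zeros(n + 1, dtype=np.int64)
        for j in range(n):
            upptr[j + 1] = upptr[j] + len(rowlists[j])
        upidx = np.empty(upptr[n], dtype=np.int64)
        for j in range(n):
            upidx[upptr[j] : upptr[j + 1]] = rowlists[j]
        self.upptr = upptr
        self.upidx = upidx

        # map the entries of the permuted input pattern into L storage
        Acoo = A.tocoo()
        lookup = {}
        for j in range(n):
            for p in range(colptr[j], colptr[j + 1]):
                lookup[(int(rowidx[p]), j)] = p
        self._lookup = lookup
        self.lx = np.empty(self.nnz)

    def map_matrix(self, M: sparse.spmatrix) -> tuple[np.ndarray, np.ndarray]:
        """Positions in L storage for the lower-triangle entries of *M*.

        Returns (entry_positions, values_selector) such that the numeric
        factorisation can scatter ``M.data[values_selector]`` into
        ``positions`` of the work array.  *M* must share the symbolic
        pattern (after permutation).
        """
        C = M.tocoo()
        ri = self.iperm[C.row]
        ci = self.iperm[C.col]
        keep = ri >= ci
        pos = np.array(
            [self._lookup[(int(r), int(c))] for r, c in zip(ri[keep], ci[keep])],
            dtype=np.int64,
        )
        sel = np.flatnonzero(keep)
        return pos, sel


@njit(cache=True)
def _numeric_chol(n, colptr, rowidx, upptr, upidx, cx, lx, work, pattern_flag):
    """Left-looking numeric Cholesky on the fixed pattern.

    cx holds the (permuted, lower-triangle) values of C scattered into L
    positions; lx receives the factor.  Returns 0 on success, j+1 if the
    leading minor at column j is not positive definite.
    """
    for j in range(n):
        # scatter column j of C
        for p in range(colptr[j], colptr[j + 1]):
            work[rowidx[p]] = cx[p]
        # updates from earlier columns
        for t in range(upptr[j], upptr[j + 1]):
            k = upidx[t]
            ljk = 0.0
            # find L[j,k]
            for p in range(colptr[k], colptr[k + 1]):
                if rowidx[p] == j:
                    ljk = lx[p]
                    break
            if ljk == 0.0:
                continue
            for p in range(colptr[k], colptr[k + 1]):
                i = rowidx[p]
                if i >= j:
                    work[i] -= lx[p] * ljk
        d = work[j]
        if d <= 0.0:
            return j + 1
        d = np.sqrt(d)
        lx[colptr[j]] = d
        work[j] = 0.0
        for p in range(colptr[j] + 1, colptr[j + 1]):
            i = rowidx[p]
            lx[p] = work[i] / d
            work[i] = 0.0
    return 0


@njit(cache=True)
def _solve_chol(n, colptr, rowidx, lx, b):
    """Solve L L' x = b in place (b permuted)."""
    for j in range(n):
        b[j] /= lx[colptr[j]]
        xj = b[j]
        for p in range(colptr[j] + 1, colptr[j + 1]):
            b[rowidx[p]] -= lx[p] * xj
    for j in range(n - 1, -1, -1):
        s = b[j]
        for p in range(colptr[j] + 1, colptr[j + 1]):
            s -= lx[p] * b[rowidx[p]]
        b[j] = s / lx[colptr[j]]
    return b


class PedigreePrecisionSolver:
    """Solver for ``C = Q / s2 + diag(d)`` with fixed pattern ``Q``.

    ``factor(s2, d)`` recomputes the Cholesky; ``solve(b)`` then solves
    ``C x = b``.  Raises ``np.linalg.LinAlgError`` if C is not positive
    definite (a corrupt pedigree or non-finite variance).
    """

    def __init__(self, Q: sparse.csr_matrix) -> None:
        self.Q = Q.tocoo()
        self.pattern = CholeskyPattern(Q)
        self.pos, sel = self.pattern.map_matrix(Q)
        self.qvals = np.asarray(self.Q.data)[sel]
        n = self.pattern.n
        self.diag_pos = np.array(
            [self.pattern.colptr[j] for j in range(n)], dtype=np.int64
        )
        # diagonal position for original index i is colptr[iperm[i]]
        self.diag_for_orig = self.pattern.colptr[self.pattern.iperm]
        self.cx = np.zeros(self.pattern.nnz)
        self.work = np.zeros(n)

    def factor(self, s2: float, d: np.ndarray) -> None:
        p = self.pattern
        self.cx[:] = 0.0
        np.add.at(self.cx, self.pos, self.qvals / s2)
        np.add.at(self.cx, self.diag_for_orig, d)
        status = _numeric_chol(
            p.n, p.colptr, p.rowidx, p.upptr, p.upidx,
            self.cx, p.lx, self.work, 0,
        )
        if status:
            raise np.linalg.LinAlgError(
                f"precision matrix not positive definite at column {status - 1}"
            )

    def solve(self, b: np.ndarray) -> np.ndarray:
        p = self.pattern
        x = np.asarray(b, dtype=float)[p.perm].copy()
        _solve_chol(p.n, p.colptr, p.rowidx, p.lx, x)
        return x[p.iperm]
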