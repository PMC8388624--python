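"""Sparse LDL' factorization with a reusable symbolic analysis.

The Gibbs location update factorizes matrices that share one sparsity
pattern across tens of thousands of iterations (only two scalars change).
SuperLU redoes its ordering and symbolic analysis on every call, which
dominates the run time, so this module provides the classic up-looking
LDL' factorization (elimination-tree based, no pivoting — valid because
the systems are symmetric positive definite): the symbolic step runs once,
the numeric step and the triangular solves run per iteration. Kernels are
numba-compiled when numba is importable and fall back to pure Python
otherwise.

Input is the upper triangle of the (permuted) matrix in CSC form.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap

__all__ = ["LDLFactorization"]


@njit(cache=True)
def _symbolic(n, Ap, Ai):
    parent = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i < k:
                while flag[i] != k:
                    if parent[i] == -1:
                        parent[i] = k
                    lnz[i] += 1
                    flag[i] = k
                    i = parent[i]
    lp = np.zeros(n + 1, dtype=np.int64)
    for k in range(n):
        lp[k + 1] = lp[k] + lnz[k]
    return parent, lp


@njit(cache=True)
def _numeric(n, Ap, Ai, Ax, parent, Lp):
    li = np.zeros(Lp[n], dtype=np.int64)
    lx = np.zeros(Lp[n])
    d = np.zeros(n)
    y = np.zeros(n)
    pattern = np.zeros(n, dtype=np.int64)
    stack = np.zeros(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        top = n
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i <= k:
                y[i] += Ax[p]
                length = 0
                while flag[i] != k:
                    pattern[length] = i
                    length += 1
                    flag[i] = k
                    i = parent[i]
                while length > 0:
                    top -= 1
                    length -= 1
                    stack[top] = pattern[length]
        d[k] = y[k]
        y[k] = 0.0
        while top < n:
            i = stack[top]
            yi = y[i]
            y[i] = 0.0
            p2 = Lp[i] + lnz[i]
            for p in range(Lp[i], p2):
                y[li[p]] -= lx[p] * yi
            l_ki = yi / d[i]
            d[k] -= l_ki * yi
            li[p2] = k
            lx[p2] = l_ki
            lnz[i] += 1
            top += 1
        if d[k] <= 0.0:
            return li, lx, d, k + 1  # not positive definite at column k
    return li, lx, d, 0


@njit(cache=True)
def _solve(n, Lp, Li, Lx, d, b):
    x = b.copy()
    for j in range(n):
        xj = x[j]
        for p in range(Lp[j], Lp[j + 1]):
            x[Li[p]] -= Lx[p] * xj
    for j in range(n):
        x[j] /= d[j]
    for j in range(n - 1, -1, -1):
        acc = x[j]
        for p in range(Lp[j], Lp[j + 1]):
            acc -= Lx[p] * x[Li[p]]
        x[j] = acc
    return x


class LDLFactorization:
    """Reusable LDL' of SPD matrices sharing one upper-triangular pattern.

    Parameters
    ----------
    indptr, indices : int arrays
        CSC structure of the upper triangle (diagonal included) of the
        permuted matrix. The pattern is analysed once at construction.
    """

    def __init__(self, indptr: np.ndarray, indices: np.ndarray) -> None:
        self.n = len(indptr) - 1
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.indices = np.asarray(indices, dtype=np.int64)
        self.parent, self.lp = _symbolic(self.n, self.indptr, self.indices)
        self._li = None
        self._lx = None
        self._d = None

    def factorize(self, data: np.ndarray) -> None:
        li, lx, d, bad = _numeric(
            self.n, self.indptr, self.indices, np.asarray(data, dtype=float),
            self.parent, self.lp,
        )
        if bad:
            raise np.linalg.LinAlgError(
                f"matrix not positive definite at column {bad - 1}"
            )
        self._li, self._lx, self._d = li, lx, d

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self._d is None:
            raise RuntimeError("factorize() must run before solve()")
        return _solve(self.n, self.lp, self._li, self._lx, self._d, np.asarray(b, dtype=float))
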