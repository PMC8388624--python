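"""Relationship kernels: pedigree A, genomic G, and single-step H inverse.

The animal model needs the inverse of a relationship kernel. Three kernels
are supported:

* ``A`` — the pedigree numerator relationship matrix (tabular recursion);
  its inverse is assembled directly and sparsely from Henderson's rules
  with inbreeding.
* ``G`` — the genomic relationship matrix from centred SNP dosages,
  G = MM' / (2 sum_k p_k (1 - p_k)) with M = dosages - 2 p (VanRaden
  method 1, observed allele frequencies).
* ``H^{-1}`` — the single-step matrix combining both:
  H^{-1} = A^{-1} + [[0, 0], [0, Gw^{-1} - A22^{-1}]] on the genotyped
  block, where A22 is the pedigree relationship among genotyped animals and
  Gw = blend*G + (1-blend)*A22 guards invertibility.

Every kernel carries its animal index map; inverses also carry a factor L
with L L' = K^{-1}, used by the blocked Gibbs location update to perturb
the right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cholesky as dense_cholesky
from scipy.sparse.linalg import splu

from .pedigree import Pedigree

__all__ = [
    "GenotypeMatrix",
    "RelationshipKernel",
    "maf_filter",
    "a_matrix",
    "a_inverse",
    "g_matrix",
    "h_inverse",
    "spd_factor",
]


class RelationshipError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix (animals x SNPs, entries 0/1/2) with frequencies."""

    ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # (n_animals, n_snps) int8
    freqs: np.ndarray = field(default=None)  # ALT-allele frequency per SNP

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise RelationshipError("dosage shape does not match id lists")
        if self.dosages.size and not np.isin(self.dosages, [0, 1, 2]).all():
            raise RelationshipError("dosages must be complete 0/1/2 codes")
        if self.freqs is None:
            self.freqs = self.compute_freqs()
        else:
            self.freqs = np.asarray(self.freqs, dtype=float)

    def compute_freqs(self) -> np.ndarray:
        if len(self.ids) == 0:
            return np.zeros(len(self.snp_ids))
        return self.dosages.mean(axis=0) / 2.0

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def is_empty(self) -> bool:
        return self.n_animals == 0 or self.n_snps == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.ids, columns=self.snp_ids)


@dataclass
class RelationshipKernel:
    """A labelled symmetric kernel (A, G) or precision (A_inverse, H_inverse)."""

    kind: str  # {"A", "A_inverse", "G", "H_inverse"}
    ids: list[str]
    matrix: "np.ndarray | sp.spmatrix"
    factor: "sp.spmatrix | None" = None  # L with L L' = matrix (inverses only)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        if self.kind not in ("A", "A_inverse", "G", "H_inverse"):
            raise RelationshipError(f"unknown kernel kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def dense(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sp.issparse(m) else np.asarray(m)

    def index_of(self, animal: str) -> int:
        return self.ids.index(str(animal))


# ----------------------------------------------------------------------
# genotype preparation


def maf_filter(g: GenotypeMatrix, threshold: float = 0.001) -> GenotypeMatrix:
    """Drop SNPs with minor-allele frequency <= ``threshold``.

    Frequencies are recomputed on the retained set. Raises if nothing
    survives, since G cannot be built from an empty marker panel.
    """
    p = g.compute_freqs()
    maf = np.minimum(p, 1.0 - p)
    keep = maf > threshold
    if not keep.any():
        raise RelationshipError(
            f"MAF filter at threshold {threshold} removed every SNP"
        )
    return GenotypeMatrix(
        ids=list(g.ids),
        snp_ids=[s for s, k in zip(g.snp_ids, keep) if k],
        dosages=g.dosages[:, keep],
    )


# ----------------------------------------------------------------------
# pedigree kernels


def a_matrix(p: Pedigree, subset: Sequence[str] | None = None) -> RelationshipKernel:
    """Numerator relationship matrix by the tabular recursion.

    ``subset`` restricts the output to the listed animals (relationships are
    still propagated through the full pedigree).
    """
    if subset is None:
        idx = list(range(len(p)))
        ids = list(p.animals)
    else:
        ids = [str(a) for a in subset]
        idx = [p.index_of(a) for a in ids]
    n = len(idx)
    a = np.empty((n, n))
    for r in range(n):
        for c in range(r, n):
            a[r, c] = a[c, r] = p.kinship_pair(idx[r], idx[c])
    return RelationshipKernel("A", ids, a)


def a_inverse(p: Pedigree) -> RelationshipKernel:
    """Sparse A^{-1} from Henderson's rules with inbreeding.

    With T^{-1} = I - P (P holding 0.5 at parent positions) and D the
    diagonal of Mendelian-sampling variances, A^{-1} = (I-P)' D^{-1} (I-P).
    The returned kernel also carries the analytic factor
    L = (I-P)' D^{-1/2}, so L L' = A^{-1} exactly.
    """
    n = len(p)
    s, d = p.parent_indices()
    dvar = p.mendelian_variances()

    rows, cols, vals = [], [], []
    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(np.ones(n))
    for i in range(n):
        for par in (s[i], d[i]):
            if par >= 0:
                rows.append(i)
                cols.append(int(par))
                vals.append(-0.5)
    t_inv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    d_half_inv = sp.diags(1.0 / np.sqrt(dvar))
    factor = (t_inv.T @ d_half_inv).tocsr()
    ainv = (factor @ factor.T).tocsr()
    return RelationshipKernel("A_inverse", list(p.animals), ainv, factor=factor)


# ----------------------------------------------------------------------
# genomic kernels


def g_matrix(g: GenotypeMatrix) -> RelationshipKernel:
    """VanRaden method-1 genomic relationship matrix with observed frequencies."""
    if g.is_empty():
        raise RelationshipError("cannot build G from an empty genotype matrix")
    p = g.compute_freqs()
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise RelationshipError(
            "zero heterozygosity denominator; run maf_filter first"
        )
    m = g.dosages.astype(float) - 2.0 * p
    gmat = (m @ m.T) / denom
    return RelationshipKernel("G", list(g.ids), gmat)


def spd_factor(matrix: "np.ndarray | sp.spmatrix") -> sp.csr_matrix:
    """A (lower-triangular up to permutation) factor L with L L' = matrix.

    Dense Cholesky below a size cutoff; above it, a no-pivot symmetric
    SuperLU factorization whose L*sqrt(diag(U)) is the permuted Cholesky
    factor. The factor is verified on random probe vectors and falls back
    to dense Cholesky if verification fails.
    """
    n = matrix.shape[0]
    dense = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix)
    if n <= 4000:
        return sp.csr_matrix(dense_cholesky(dense, lower=True))
    msp = sp.csc_matrix(matrix)
    lu = splu(
        msp,
        diag_pivot_thresh=0.0,
        permc_spec="MMD_AT_PLUS_A",
        options=dict(SymmetricMode=True),
    )
    du = lu.U.diagonal()
    if (du <= 0).any():
        return sp.csr_matrix(dense_cholesky(dense, lower=True))
    lfac = (lu.L @ sp.diags(np.sqrt(du))).tocsr()
    perm = np.argsort(lu.perm_r)
    cand = lfac[perm, :] if (lu.perm_r == lu.perm_c).all() else None
    if cand is not None:
        rng = np.random.default_rng(0)
        z = rng.standard_normal((n, 3))
        err = np.abs(cand @ (cand.T @ z) - msp @ z).max()
        scale = max(1.0, np.abs(msp.data).max())
        if err < 1e-8 * scale * n:
            return cand
    return sp.csr_matrix(dense_cholesky(dense, lower=True))


def h_inverse(
    a_inv: RelationshipKernel,
    g: RelationshipKernel,
    pedigree: Pedigree,
    blend: float = 0.95,
) -> RelationshipKernel:
    """Single-step H^{-1} combining pedigree and genomic relationships.

    H^{-1} = A^{-1} + [[0, 0], [0, Gw^{-1} - A22^{-1}]] on the genotyped
    block, with Gw = blend*G + (1-blend)*A22. With no genotyped animals the
    result is exactly A^{-1} (same sparsity, same factor).
    """
    if a_inv.kind != "A_inverse":
        raise RelationshipError("first argument must be an A_inverse kernel")
    if g is None or g.n == 0:
        return RelationshipKernel(
            "H_inverse", list(a_inv.ids), a_inv.matrix.copy(), factor=a_inv.factor
        )
    if g.kind != "G":
        raise RelationshipError("second argument must be a G kernel")
    missing = [i for i in g.ids if i not in pedigree]
    if missing:
        raise RelationshipError(f"genotyped animals absent from pedigree: {missing[:5]}")
    if not 0.0 < blend <= 1.0:
        raise RelationshipError("blend must be in (0, 1]")

    a22 = a_matrix(pedigree, subset=g.ids).dense()
    gw = blend * g.dense() + (1.0 - blend) * a22
    try:
        gw_inv = np.linalg.inv(gw)
        a22_inv = np.linalg.inv(a22)
    except np.linalg.LinAlgError as exc:
        raise RelationshipError(
            "singular blended genomic matrix; lower the blend proportion"
        ) from exc

    n = a_inv.n
    pos = [a_inv.index_of(i) for i in g.ids]
    delta = gw_inv - a22_inv
    rows = np.repeat(pos, len(pos))
    cols = np.tile(pos, len(pos))
    corr = sp.csr_matrix((delta.ravel(), (rows, cols)), shape=(n, n))
    hinv = (sp.csr_matrix(a_inv.matrix) + corr).tocsr()
    kernel = RelationshipKernel("H_inverse", list(a_inv.ids), hinv)
    kernel.factor = spd_factor(hinv)
    return kernel
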