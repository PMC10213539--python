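"""Assembly of the single-step H^{-1} in its four flavors.

All flavors share the pattern "pedigree inverse + genomic correction on the
genotyped block":

* standard:  H^-1 = A^-1 + [0, 0; 0, G^-1 - A22^-1]
* UPG1:      A* (QP-transformed, animals+groups) with the genomic correction
             propagated into the group equations through Q:
             [D, -D Q2; -Q2' D, Q2' D Q2] with D = G^-1 - A22^-1
* UPG2:      A* with the group coupling through the pedigree only:
             [D, -A22^-1 Q2; -Q2' A22^-1, Q2' A22^-1 Q2]
* MF:        A(Gamma)^-1 (metafounders kept as pseudo-animals) plus
             G05^-1 - A22(Gamma)^-1 on the genotyped block; group blocks
             are zero because the metafounders live inside A(Gamma).

Unknown ordering is always (animals, groups).  The dense corrections are
kept as indexed blocks so solvers can apply H^-1 without materialising an
n x n dense matrix; ``to_sparse`` materialises when a direct solve wants it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .genomic import APYInverse, GRM

FLAVORS = ("standard", "upg1", "upg2", "mf")


class HMatrixError(ValueError):
    pass


@dataclass
class HInverse:
    """H^{-1} as sparse part + dense indexed correction blocks."""

    flavor: str
    n_animals: int
    n_groups: int
    sparse_part: sparse.csr_matrix
    blocks: list = field(default_factory=list)   # (row_idx, col_idx, matrix)
    Q: np.ndarray | None = None
    genotyped: np.ndarray | None = None          # animal codes

    @property
    def dim(self) -> int:
        return self.sparse_part.shape[0]

    def to_sparse(self) -> sparse.csr_matrix:
        out = self.sparse_part.tolil(copy=True)
        for r, c, M in self.blocks:
            out[np.ix_(r, c)] = out[np.ix_(r, c)].toarray() + M
        return out.tocsr()

    def to_dense(self) -> np.ndarray:
        out = self.sparse_part.toarray()
        for r, c, M in self.blocks:
            out[np.ix_(r, c)] += M
        return out

    def matvec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.sparse_part @ x
        for r, c, M in self.blocks:
            y[r] += M @ x[c]
        return y

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.sparse_part.diagonal()).copy()
        for r, c, M in self.blocks:
            common = np.intersect1d(r, c)
            if len(common):
                ri = np.searchsorted(r, common)
                ci = np.searchsorted(c, common)
                d[common] += M[ri, ci]
        return d


def _genomic_dense(ginv) -> np.ndarray:
    if isinstance(ginv, APYInverse):
        return ginv.dense()
    if isinstance(ginv, GRM):
        raise HMatrixError("pass the *inverse* of G, not G itself")
    return np.asarray(ginv)


def build_hinv(flavor: str, n_animals: int, genotyped: np.ndarray,
               ainv=None, ginv=None, a22inv=None, astar=None,
               Q: np.ndarray | None = None, agamma_inv=None,
               n_groups: int = 0, g_freq_mode: str | None = None) -> HInverse:
    """Assemble one of the four H^{-1} flavors from its constituents.

    ``genotyped`` holds animal codes (0-based, ordered like the rows of the
    genomic operators).  ``g_freq_mode`` is validated against the flavor:
    the MF flavor requires the 0.5-centred G, the others the
    observed-frequency G.
    """
    if flavor not in FLAVORS:
        raise HMatrixError(f"unknown H^-1 flavor {flavor!r}")
    genotyped = np.asarray(genotyped, dtype=np.int64)
    if flavor == "mf":
        if g_freq_mode not in (None, "half"):
            raise HMatrixError(
                "MF flavor requires the 0.5-centred G (freq_mode='half')")
        if agamma_inv is None or ginv is None or a22inv is None:
            raise HMatrixError("MF flavor needs agamma_inv, ginv and a22inv")
        dim = agamma_inv.shape[0]
        n_groups_mf = dim - n_animals
        D = _genomic_dense(ginv) - np.asarray(a22inv)
        return HInverse(flavor="mf", n_animals=n_animals,
                        n_groups=n_groups_mf,
                        sparse_part=sparse.csr_matrix(agamma_inv),
                        blocks=[(genotyped, genotyped, D)],
                        Q=None, genotyped=genotyped)

    if g_freq_mode not in (None, "observed"):
        raise HMatrixError(
            f"{flavor} flavor requires the observed-frequency G")
    if ginv is None or a22inv is None:
        raise HMatrixError(f"{flavor} flavor needs ginv and a22inv")
    a22inv = np.asarray(a22inv)
    D = _genomic_dense(ginv) - a22inv

    if flavor == "standard":
        if ainv is None:
            raise HMatrixError("standard flavor needs ainv")
        return HInverse(flavor="standard", n_animals=n_animals, n_groups=0,
                        sparse_part=sparse.csr_matrix(ainv),
                        blocks=[(genotyped, genotyped, D)],
                        Q=None, genotyped=genotyped)

    if astar is None or Q is None:
        raise HMatrixError(f"{flavor} flavor needs astar and Q")
    Q = np.asarray(Q)
    if n_groups <= 0:
        n_groups = astar.shape[0] - n_animals
    Q2 = Q[genotyped]
    grp = np.arange(n_animals, n_animals + n_groups)
    if flavor == "upg1":
        coup = D
    else:
        coup = a22inv
    blocks = [
        (genotyped, genotyped, D),
        (genotyped, grp, -coup @ Q2),
        (grp, genotyped, -(coup @ Q2).T),
        (grp, grp, Q2.T @ coup @ Q2),
    ]
    return HInverse(flavor=flavor, n_animals=n_animals, n_groups=n_groups,
                    sparse_part=sparse.csr_matrix(astar), blocks=blocks,
                    Q=Q, genotyped=genotyped)
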