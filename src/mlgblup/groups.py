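"""Unknown-parent groups and metafounders.

Two ways to model heterogeneous genetic bases across lines:

* Unknown-parent groups (UPG): every missing parent slot is routed to a
  group effect.  Q holds expected base-group contributions per animal and
  A* is the QP-transformed inverse of A over animals + groups.
* Metafounders (MF): groups become pseudo-founders that are mutually related
  and "inbred" through the Gamma matrix (diagonal gamma_jj is the
  self-relationship; gamma_jj - 1 the metafounder inbreeding).  A(Gamma) is
  the ordinary relationship recursion over the MF-augmented pedigree, and
  pairs with the 0.5-centred genomic matrix G05.

Gamma is estimated from markers: per group, the base allele frequency is the
GLS mean of half-dosages under the within-group pedigree covariance, and
Gamma = 8 x the covariance across markers of those estimates around 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import (MISSING, Pedigree, PedigreeError, build_A22,
                       compute_inbreeding, mendelian_variances)

__all__ = [
    "GroupAssignment", "PedigreeWithGroups", "GammaMatrix", "assign_groups",
    "build_Q", "build_Astar", "estimate_gamma", "build_AGamma",
    "build_AGamma_inverse",
]


@dataclass
class GroupAssignment:
    """Ordered group labels and the line -> group rule for missing parents."""

    groups: list
    line_to_group: dict

    def group_index(self, line) -> int:
        try:
            return self.groups.index(self.line_to_group[line])
        except KeyError:
            raise PedigreeError(f"no group rule for line {line!r}") from None

    @classmethod
    def per_line(cls, lines) -> "GroupAssignment":
        """One group per line, named after the line (the default rule)."""
        uniq = list(dict.fromkeys(lines))
        return cls(groups=uniq, line_to_group={ln: ln for ln in uniq})


@dataclass
class PedigreeWithGroups:
    """A pedigree whose missing parent slots carry group references."""

    ped: Pedigree
    assignment: GroupAssignment
    sire_group: np.ndarray   # group index where sire missing, else -1
    dam_group: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.assignment.groups)


def assign_groups(ped: Pedigree, rule: GroupAssignment) -> PedigreeWithGroups:
    """Route every missing parent slot to the group of the animal's line."""
    missing_lines = sorted({ln for ln in set(ped.line)
                            if ln not in rule.line_to_group})
    if missing_lines:
        bad = [str(a) for a, ln in zip(ped.animal_id, ped.line)
               if ln in set(missing_lines)][:5]
        raise PedigreeError(
            f"no group rule for line(s) {missing_lines}; e.g. animals {bad}")
    gidx = np.array([rule.group_index(ln) for ln in ped.line], dtype=np.int32)
    sire_group = np.where(ped.sire == MISSING, gidx, -1).astype(np.int32)
    dam_group = np.where(ped.dam == MISSING, gidx, -1).astype(np.int32)
    return PedigreeWithGroups(ped=ped, assignment=rule,
                              sire_group=sire_group, dam_group=dam_group)


def build_Q(pwg: PedigreeWithGroups) -> np.ndarray:
    """Expected base-group contributions: q_i = (q_sire + q_dam)/2 with a
    group reference contributing its unit row."""
    ped = pwg.ped
    n, g = ped.n, pwg.n_groups
    Q = np.zeros((n, g))
    eye = np.eye(g)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        qs = Q[s] if s >= 0 else eye[pwg.sire_group[i]]
        qd = Q[d] if d >= 0 else eye[pwg.dam_group[i]]
        Q[i] = 0.5 * (qs + qd)
    return Q


def build_Astar(pwg: PedigreeWithGroups,
                F: np.ndarray | None = None) -> sparse.csr_matrix:
    """QP-transformed inverse of A over animals + groups, (n+g) x (n+g).

    Henderson-rule assembly in which each missing parent's -1/2 coefficient
    is routed to its group column; Mendelian variances keep the plain
    unknown-parent convention, so the animal block equals A^{-1} plus the
    group corrections of the QP transformation.
    """
    ped = pwg.ped
    n, g = ped.n, pwg.n_groups
    dvec = mendelian_variances(ped, F)
    rows, cols, vals = [], [], []
    for i in range(n):
        alpha = 1.0 / dvec[i]
        slots = []
        for p, grp in ((ped.sire[i], pwg.sire_group[i]),
                       (ped.dam[i], pwg.dam_group[i])):
            slots.append(p if p >= 0 else n + grp)
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in slots:
            rows.append(i); cols.append(p); vals.append(-0.5 * alpha)
            rows.append(p); cols.append(i); vals.append(-0.5 * alpha)
        for p in slots:
            for q in slots:
                rows.append(p); cols.append(q); vals.append(0.25 * alpha)
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(n + g, n + g))
    return A.tocsr()


@dataclass
class GammaMatrix:
    """Relationships within (diagonal) and across (off-diagonal) metafounders."""

    values: np.ndarray
    groups: list

    @property
    def g(self) -> int:
        return self.values.shape[0]

    def check_psd(self, tol: float = 1e-8) -> None:
        ev = np.linalg.eigvalsh(self.values)
        if ev[0] < -tol:
            raise PedigreeError(
                f"Gamma is not PSD: smallest eigenvalue {ev[0]:.3e}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.groups, columns=self.groups)

    @classmethod
    def read_csv(cls, path) -> "GammaMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(float), groups=list(df.columns))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def estimate_gamma(ped: Pedigree, geno, rule: GroupAssignment,
                   center: str = "half") -> GammaMatrix:
    """Estimate Gamma from SNP markers by per-group GLS base frequencies.

    For group k with genotyped member codes G_k and dosage matrix M_k, the
    base frequency per marker is the GLS mean

        p_hat = (1' A22k^{-1} 1)^{-1} 1' A22k^{-1} M_k / 2,

    where A22k is the pedigree relationship among the group's genotyped
    animals.  Gamma = 8 x covariance across markers of the estimates, taken
    around 0.5 (``center='half'``, the metafounder reference) or around the
    per-marker mean across groups (``center='mean'``).
    """
    if center not in ("half", "mean"):
        raise PedigreeError(f"unknown centering {center!r}")
    group_lines = {}
    for ln, grp in rule.line_to_group.items():
        group_lines.setdefault(grp, []).append(ln)
    geno_idx = {a: i for i, a in enumerate(geno.animal_ids)}
    m = geno.n_markers
    p = np.nanmean(geno.dosages, axis=0) / 2.0
    if np.all((p <= 0) | (p >= 1)):
        raise PedigreeError("all markers monomorphic: cannot estimate Gamma")
    F = compute_inbreeding(ped).F
    phat = np.zeros((len(rule.groups), m))
    for k, grp in enumerate(rule.groups):
        lines = set(group_lines.get(grp, []))
        members = [a for a, ln in zip(ped.animal_id, ped.line)
                   if ln in lines and a in geno_idx]
        if len(members) < 2:
            raise PedigreeError(
                f"group {grp!r} has {len(members)} genotyped descendants (<2)")
        A22k = build_A22(ped, members, F)
        rows = np.array([geno_idx[a] for a in members])
        M = geno.dosages[rows].astype(float)
        M = np.where(np.isnan(M), (2 * p)[None, :], M)
        w = np.linalg.solve(A22k, np.ones(len(members)))
        w /= w.sum()
        phat[k] = w @ (M / 2.0)
    if center == "half":
        dev = phat - 0.5
    else:
        dev = phat - phat.mean(axis=0, keepdims=True)
    gamma = 8.0 * (dev @ dev.T) / m
    return GammaMatrix(values=gamma, groups=list(rule.groups))


# ---------------------------------------------------------------------------
# metafounder relationship algebra

def _augmented_parents(pwg: PedigreeWithGroups):
    """Parent codes over the MF-augmented ordering (g metafounders first)."""
    ped, g = pwg.ped, pwg.n_groups
    sire = np.where(ped.sire >= 0, ped.sire + g, pwg.sire_group)
    dam = np.where(ped.dam >= 0, ped.dam + g, pwg.dam_group)
    return sire.astype(np.int64), dam.astype(np.int64)


def build_AGamma(pwg: PedigreeWithGroups, gamma: GammaMatrix) -> np.ndarray:
    """Dense A(Gamma) over (metafounders, animals), by the tabular recursion
    on the MF-augmented pedigree with founder block Gamma."""
    ped, g = pwg.ped, pwg.n_groups
    if gamma.g != g:
        raise PedigreeError("Gamma dimension does not match group count")
    n = ped.n
    N = n + g
    A = np.zeros((N, N))
    A[:g, :g] = gamma.values
    sire, dam = _augmented_parents(pwg)
    for i in range(n):
        k = g + i
        s, d = sire[i], dam[i]
        row = 0.5 * (A[s, :k] + A[d, :k])
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + 0.5 * A[s, d]
    return A


def build_AGamma_inverse(pwg: PedigreeWithGroups, gamma: GammaMatrix,
                         absorb: bool = False):
    """Sparse inverse of A(Gamma), ordered (animals, metafounders).

    Assembled as M' D^{-1} M with M = I - P over the augmented pedigree,
    where D is block-diagonal: the Gamma block for metafounders and the
    Mendelian variances d_i = a_ii - (a_ss + 2 a_sd + a_dd)/4 for animals
    (a from the augmented recursion).  Requires Gamma positive definite.
    With ``absorb=True`` the metafounder rows are absorbed by Schur
    complement and an n x n operator over animals is returned.
    """
    gamma.check_psd()
    ev = np.linalg.eigvalsh(gamma.values)
    if ev[0] <= 1e-10:
        raise PedigreeError(
            f"Gamma is singular (smallest eigenvalue {ev[0]:.3e}); "
            "A(Gamma) has no inverse")
    ped, g = pwg.ped, pwg.n_groups
    n = ped.n
    A = build_AGamma(pwg, gamma)
    sire, dam = _augmented_parents(pwg)
    dvec = np.empty(n)
    for i in range(n):
        k = g + i
        s, d = sire[i], dam[i]
        dvec[i] = A[k, k] - 0.25 * (A[s, s] + 2.0 * A[s, d] + A[d, d])
    if np.any(dvec <= 0):
        raise PedigreeError("non-positive Mendelian variance under Gamma")

    # M = I - P over (MF, animals); MF rows are identity.
    rows, cols, vals = [], [], []
    for j in range(g):
        rows.append(j); cols.append(j); vals.append(1.0)
    for i in range(n):
        k = g + i
        rows += [k, k, k]
        cols += [k, sire[i], dam[i]]
        vals += [1.0, -0.5, -0.5]
    M = sparse.coo_matrix((vals, (rows, cols)), shape=(n + g, n + g)).tocsr()
    Dinv = sparse.block_diag(
        [np.linalg.inv(gamma.values), sparse.diags(1.0 / dvec)]).tocsr()
    Ainv = (M.T @ Dinv @ M).tocsr()
    # reorder to (animals, metafounders)
    perm = np.concatenate([np.arange(g, n + g), np.arange(g)])
    Ainv = Ainv[perm][:, perm].tocsr()
    if absorb:
        Aaa = Ainv[:n, :n].toarray()
        Aag = Ainv[:n, n:].toarray()
        Agg = Ainv[n:, n:].toarray()
        return sparse.csr_matrix(Aaa - Aag @ np.linalg.solve(Agg, Aag.T))
    return Ainv


def build_A22Gamma(pwg: PedigreeWithGroups, gamma: GammaMatrix,
                   genotyped=None) -> np.ndarray:
    """Dense A22(Gamma): principal submatrix of A(Gamma) for genotyped animals."""
    ped, g = pwg.ped, pwg.n_groups
    codes = ped.genotyped_codes if genotyped is None else np.asarray(
        ped.codes(genotyped))
    A = build_AGamma(pwg, gamma)
    idx = codes + g
    return A[np.ix_(idx, idx)]
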