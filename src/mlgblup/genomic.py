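"""Genotype QC, genomic relationship matrices, APY inversion, PCA.

The genomic relationship matrix follows VanRaden's method 1,

    G = (M - 2P) D (M - 2P)' / (2 * sum_i p_i (1 - p_i)),

with dosages M in {0,1,2}, allele frequencies P taken across the entire
genotyped population, and an optional diagonal SNP-weight matrix D
(D = I for plain ssGBLUP).  A half-frequency mode centres at p = 0.5 with
denominator m/2, the parameterisation the metafounder theory pairs with.

APY (algorithm for proven and young) builds a sparse-structured inverse of G
from a core subset sized by the eigenvalue spectrum of G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeSet", "QCThresholds", "QCReport", "GRM", "APYPartition",
    "APYInverse", "qc_genotypes", "allele_frequencies", "build_G",
    "blend_G", "select_core", "apy_inverse", "genotype_pca",
]


class GenomicError(ValueError):
    pass


@dataclass
class GenotypeSet:
    """Animals x markers dosage matrix plus marker map.

    ``dosages`` is float (0/1/2, NaN = missing).  ``marker_map`` has columns
    marker, chrom, bp (1-based), sorted by (chrom, bp) with strictly
    increasing positions within chromosome.
    """

    dosages: np.ndarray
    animal_ids: np.ndarray
    marker_map: pd.DataFrame
    panel: str = "chip"

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        if self.dosages.shape != (len(self.animal_ids), len(self.marker_map)):
            raise GenomicError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.marker_map)} markers")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise GenomicError("marker positions not strictly increasing "
                                   "within chromosome")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def markers(self) -> np.ndarray:
        return self.marker_map["marker"].to_numpy()

    def subset_markers(self, keep) -> "GenotypeSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif np.issubdtype(keep.dtype, np.integer):
            idx = keep
        else:
            pos = pd.Index(self.marker_map["marker"])
            idx = np.sort(pos.get_indexer(keep))
            if np.any(idx < 0):
                raise GenomicError("unknown marker in subset")
        return GenotypeSet(self.dosages[:, idx], self.animal_ids,
                           self.marker_map.iloc[idx].reset_index(drop=True),
                           self.panel)

    def subset_animals(self, keep) -> "GenotypeSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif np.issubdtype(keep.dtype, np.integer):
            idx = keep
        else:
            pos = pd.Index(self.animal_ids)
            idx = pos.get_indexer(keep)
            if np.any(idx < 0):
                raise GenomicError("unknown animal in subset")
        return GenotypeSet(self.dosages[idx], self.animal_ids[idx],
                           self.marker_map, self.panel)


@dataclass
class QCThresholds:
    """Marker/animal quality-control thresholds (defaults: chip panels)."""

    min_call_rate: float = 0.90
    min_maf: float = 0.01
    max_het_deviation: float = 0.15   # |observed - expected| heterozygosity
    max_animal_missing: float = 0.10
    parent_conflict_rate: float = 0.01  # opposite-homozygote fraction

    @classmethod
    def wgs(cls) -> "QCThresholds":
        """Thresholds for (imputed) sequence panels: MAF floor 0.023."""
        return cls(min_maf=0.023)


@dataclass
class QCReport:
    n_markers_in: int = 0
    n_animals_in: int = 0
    removed_call_rate: int = 0
    removed_monomorphic: int = 0
    removed_maf: int = 0
    removed_het_deviation: int = 0
    removed_animals_missing: int = 0
    removed_parent_conflict: int = 0
    n_markers_out: int = 0
    n_animals_out: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def qc_genotypes(geno: GenotypeSet, thresholds: QCThresholds | None = None,
                 ped=None) -> tuple[GenotypeSet, QCReport]:
    """Apply marker and animal filters; returns the filtered set and a report.

    Marker filters: call rate, monomorphism, minor allele frequency,
    heterozygote-frequency deviation from Hardy-Weinberg expectation.
    Animal filters: fraction missing; with a pedigree supplied, animals whose
    opposite-homozygote rate against a genotyped parent exceeds the conflict
    threshold are removed (parent-progeny conflicts).
    """
    th = thresholds or QCThresholds()
    rep = QCReport(n_markers_in=geno.n_markers, n_animals_in=geno.n_animals)
    X = geno.dosages.astype(float)
    obs = ~np.isnan(X)

    call_rate = obs.mean(axis=0)
    keep = call_rate >= th.min_call_rate
    rep.removed_call_rate = int(np.sum(~keep))

    with np.errstate(invalid="ignore"):
        p = np.nansum(X, axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))
    mono = (p <= 0.0) | (p >= 1.0)
    rep.removed_monomorphic = int(np.sum(mono & keep))
    keep &= ~mono

    maf = np.minimum(p, 1.0 - p)
    low = maf < th.min_maf
    rep.removed_maf = int(np.sum(low & keep))
    keep &= ~low

    het_obs = np.nansum(X == 1, axis=0) / np.maximum(obs.sum(axis=0), 1)
    het_exp = 2.0 * p * (1.0 - p)
    dev = np.abs(het_obs - het_exp) > th.max_het_deviation
    rep.removed_het_deviation = int(np.sum(dev & keep))
    keep &= ~dev

    if not keep.any():
        raise GenomicError("quality control removed all markers or animals")
    out = geno.subset_markers(keep)

    miss = np.isnan(out.dosages).mean(axis=1)
    akeep = miss <= th.max_animal_missing
    rep.removed_animals_missing = int(np.sum(~akeep))
    out = out.subset_animals(akeep)

    if ped is not None and out.n_animals:
        conflict = _parent_conflicts(out, ped, th.parent_conflict_rate)
        rep.removed_parent_conflict = int(conflict.sum())
        out = out.subset_animals(~conflict)

    rep.n_markers_out, rep.n_animals_out = out.n_markers, out.n_animals
    if rep.n_markers_out == 0 or rep.n_animals_out == 0:
        raise GenomicError("quality control removed all markers or animals")
    return out, rep


def _parent_conflicts(geno: GenotypeSet, ped, rate: float) -> np.ndarray:
    """Flag animals with opposite-homozygote rate > ``rate`` vs any parent."""
    idx = {a: i for i, a in enumerate(geno.animal_ids)}
    X = geno.dosages
    flag = np.zeros(geno.n_animals, dtype=bool)
    for i, aid in enumerate(geno.animal_ids):
        code = ped._code.get(aid)
        if code is None:
            continue
        for par in (ped.sire[code], ped.dam[code]):
            if par < 0:
                continue
            j = idx.get(ped.animal_id[par])
            if j is None:
                continue
            a, b = X[i], X[j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            hom = ok & (a != 1) & (b != 1)
            if hom.sum() == 0:
                continue
            opp = np.sum(hom & (a != b))
            if opp / hom.sum() > rate:
                flag[i] = True
    return flag


def allele_frequencies(geno: GenotypeSet) -> np.ndarray:
    """Second-allele frequency per marker, pooled over all genotyped animals."""
    X = geno.dosages.astype(float)
    obs = ~np.isnan(X)
    return np.nansum(X, axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))


@dataclass
class GRM:
    """A genomic relationship matrix plus the bookkeeping H-assembly needs."""

    values: np.ndarray
    animal_ids: np.ndarray
    freq_mode: str = "observed"     # "observed" | "half"
    blended: bool = False

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_G(geno: GenotypeSet, freq_mode: str = "observed",
            weights: np.ndarray | None = None,
            freqs: np.ndarray | None = None) -> GRM:
    """VanRaden method-1 G, optionally SNP-weighted and/or 0.5-centred.

    ``freq_mode='observed'`` centres at 2p and scales by 2*sum(p(1-p));
    ``freq_mode='half'`` centres at 1 and scales by m/2 (metafounder pairing).
    Residual missing dosages are mean-imputed to 2p before centring, so they
    contribute nothing to relationships.
    """
    if freq_mode not in ("observed", "half"):
        raise GenomicError(f"unknown freq_mode {freq_mode!r}")
    X = geno.dosages.astype(float)
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs, float)
    miss = np.isnan(X)
    if miss.any():
        X = np.where(miss, (2.0 * p)[None, :], X)
    if freq_mode == "observed":
        denom = 2.0 * float(np.sum(p * (1.0 - p)))
        if denom <= 0:
            raise GenomicError("all markers fixed: zero VanRaden denominator")
        Z = X - 2.0 * p[None, :]
    else:
        denom = geno.n_markers / 2.0
        Z = X - 1.0
    if weights is not None:
        w = np.asarray(weights, float)
        if w.shape != (geno.n_markers,):
            raise GenomicError("weight vector length != marker count")
        if np.any(w < 0):
            raise GenomicError("negative SNP weights")
    else:
        w = None
    if w is None or np.all(w == 1.0):
        # keep the unweighted path bitwise-identical for D = I
        G = Z @ Z.T / denom
    else:
        G = (Z * w[None, :]) @ Z.T / denom
    return GRM(values=0.5 * (G + G.T), animal_ids=geno.animal_ids,
               freq_mode=freq_mode)


def tune_G_to_A22(G: GRM, A22: np.ndarray) -> GRM:
    """Rescale G so its mean diagonal and mean off-diagonal match A22.

    The affine adjustment a + b*G with b = (diag(A22)bar - offd(A22)bar) /
    (diag(G)bar - offd(G)bar) puts the genomic and pedigree relationships on
    the same base, the standard compatibility step of single-step
    evaluations with an observed-frequency G.  (The metafounder/0.5-centred
    pairing achieves compatibility through Gamma instead and is not tuned.)
    """
    A22 = np.asarray(A22)
    if A22.shape != G.values.shape:
        raise GenomicError("A22 shape does not match G")
    n = G.n
    if n < 2:
        return G
    dG = float(G.values.diagonal().mean())
    dA = float(A22.diagonal().mean())
    oG = float((G.values.sum() - G.values.diagonal().sum()) / (n * n - n))
    oA = float((A22.sum() - A22.diagonal().sum()) / (n * n - n))
    if abs(dG - oG) < 1e-12:
        raise GenomicError("degenerate G: no diagonal/off-diagonal contrast")
    b = (dA - oA) / (dG - oG)
    a = dA - b * dG
    return GRM(values=a + b * G.values, animal_ids=G.animal_ids,
               freq_mode=G.freq_mode, blended=G.blended)


def blend_G(G: GRM, A22: np.ndarray, beta: float = 0.05) -> GRM:
    """(1-beta) G + beta A22; the default 5% guards against singular G."""
    if not 0.0 <= beta < 1.0:
        raise GenomicError("blend fraction must be in [0, 1)")
    A22 = np.asarray(A22)
    if A22.shape != G.values.shape:
        raise GenomicError(
            f"A22 shape {A22.shape} does not match G shape {G.values.shape}")
    return GRM(values=(1.0 - beta) * G.values + beta * A22,
               animal_ids=G.animal_ids, freq_mode=G.freq_mode,
               blended=beta > 0)


@dataclass
class APYPartition:
    core: np.ndarray       # animal ids
    noncore: np.ndarray    # animal ids

    @property
    def n_core(self) -> int:
        return len(self.core)


def select_core(G: GRM, lines: np.ndarray, var_threshold: float = 0.98,
                proportions: dict | None = None, seed: int = 0) -> APYPartition:
    """Size the APY core by the eigenvalue spectrum of G, sample it by line.

    n_core is the smallest number of leading eigenvalues explaining
    ``var_threshold`` of the total variation in G; the core is then sampled
    uniformly at random within line with per-line counts
    round(n_core * proportion).  Default proportions are the line shares of
    the genotyped population.
    """
    if not 0.0 < var_threshold <= 1.0:
        raise GenomicError("var_threshold must be in (0, 1]")
    lines = np.asarray(lines, dtype=object)
    if len(lines) != G.n:
        raise GenomicError("line labels do not match G dimension")
    ev = np.linalg.eigvalsh(G.values)[::-1]
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    if total <= 0:
        raise GenomicError("G has no variation")
    share = np.cumsum(ev) / total
    n_core = int(np.searchsorted(share, var_threshold - 1e-12) + 1)
    n_core = min(n_core, G.n)

    uniq = list(dict.fromkeys(lines))
    if proportions is None:
        proportions = {ln: np.mean(lines == ln) for ln in uniq}
    if abs(sum(proportions.values()) - 1.0) > 1e-8:
        raise GenomicError("line proportions must sum to 1")
    rng = np.random.default_rng(seed)
    core_ids = []
    for ln in uniq:
        pool = np.flatnonzero(lines == ln)
        want = int(round(n_core * proportions.get(ln, 0.0)))
        want = min(want, len(pool))
        if want:
            core_ids.append(rng.choice(pool, size=want, replace=False))
    core_idx = np.sort(np.concatenate(core_ids)) if core_ids else np.array([], int)
    mask = np.zeros(G.n, dtype=bool)
    mask[core_idx] = True
    return APYPartition(core=G.animal_ids[mask], noncore=G.animal_ids[~mask])


@dataclass
class APYInverse:
    """APY inverse of G: exact core inverse, diagonal noncore block.

    With core block Gcc and noncore g_i, the noncore Mendelian-like variance
    is m_ii = g_ii - g_i,core Gcc^{-1} g_core,i and the inverse is the
    standard bordered assembly.  ``order`` maps rows back onto the original
    animal order of G.
    """

    Gcc_inv: np.ndarray
    P_cn: np.ndarray          # Gcc^{-1} G_cn
    m_inv: np.ndarray         # 1 / m_ii for noncore
    core_idx: np.ndarray      # positions of core animals in original order
    noncore_idx: np.ndarray
    animal_ids: np.ndarray
    freq_mode: str = "observed"

    @property
    def n(self) -> int:
        return len(self.core_idx) + len(self.noncore_idx)

    def dense(self) -> np.ndarray:
        k = len(self.core_idx)
        n = self.n
        out = np.zeros((n, n))
        PM = self.P_cn * self.m_inv[None, :]
        cc = self.Gcc_inv + PM @ self.P_cn.T
        perm = np.concatenate([self.core_idx, self.noncore_idx])
        block = np.zeros((n, n))
        block[:k, :k] = cc
        block[:k, k:] = -PM
        block[k:, :k] = -PM.T
        block[k:, k:] = np.diag(self.m_inv)
        out[np.ix_(perm, perm)] = block
        return out

    def matvec(self, x: np.ndarray) -> np.ndarray:
        xc = x[self.core_idx]
        xn = x[self.noncore_idx]
        t = self.m_inv * (xn - self.P_cn.T @ xc)
        out = np.zeros_like(x)
        out[self.core_idx] = self.Gcc_inv @ xc - self.P_cn @ t
        out[self.noncore_idx] = t
        return out


def apy_inverse(G: GRM, part: APYPartition) -> APYInverse:
    """Invert G by the algorithm for proven and young."""
    pos = {a: i for i, a in enumerate(G.animal_ids)}
    try:
        core_idx = np.array(sorted(pos[a] for a in part.core), dtype=np.int64)
        noncore_idx = np.array(sorted(pos[a] for a in part.noncore),
                               dtype=np.int64)
    except KeyError as e:
        raise GenomicError(f"partition animal {e.args[0]!r} not in G") from None
    if len(core_idx) == 0:
        raise GenomicError("empty APY core")
    Gcc = G.values[np.ix_(core_idx, core_idx)]
    try:
        c, low = _cho_factor(Gcc)
    except np.linalg.LinAlgError:
        raise GenomicError(
            "singular APY core block; consider blending G with A22") from None
    Gcc_inv = _cho_inverse(c)
    if len(noncore_idx):
        Gcn = G.values[np.ix_(core_idx, noncore_idx)]
        P_cn = Gcc_inv @ Gcn
        m = G.values[noncore_idx, noncore_idx] - np.sum(Gcn * P_cn, axis=0)
        if np.any(m <= 0):
            raise GenomicError(
                "non-positive noncore variance in APY; consider blending")
        m_inv = 1.0 / m
    else:
        P_cn = np.zeros((len(core_idx), 0))
        m_inv = np.zeros(0)
    return APYInverse(Gcc_inv=Gcc_inv, P_cn=P_cn, m_inv=m_inv,
                      core_idx=core_idx, noncore_idx=noncore_idx,
                      animal_ids=G.animal_ids, freq_mode=G.freq_mode)


def _cho_factor(M):
    L = np.linalg.cholesky(M)
    return L, True


def _cho_inverse(L):
    n = L.shape[0]
    Linv = np.linalg.solve(L, np.eye(n))
    return Linv.T @ Linv


def genotype_pca(geno: GenotypeSet, k: int = 10):
    """PCA on centred dosages; returns (scores, explained-variance shares)."""
    X = geno.dosages.astype(float)
    p = allele_frequencies(geno)
    X = np.where(np.isnan(X), (2 * p)[None, :], X)
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    if var.sum() > 0:
        rank = int(np.sum(s > s[0] * 1e-12))
        if k > rank:
            raise GenomicError(f"k={k} exceeds genotype matrix rank {rank}")
        shares = var[:k] / var.sum()
    else:
        if k > s.size:
            raise GenomicError(f"k={k} exceeds genotype matrix rank 0")
        shares = np.zeros(k)
    return U[:, :k] * s[:k], shares
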