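"""Pedigree ingestion, recoding, inbreeding and numerator-relationship algebra.

The numerator relationship matrix A of a pedigree admits the factorisation
A = T D T' where T = (I - P)^{-1} traces gene flow from parents to offspring
(P carries 0.5 on each known parent) and D is the diagonal of Mendelian
sampling variances.  Everything in this module works off that factorisation:

* inbreeding F (diag(A) - 1) by the Meuwissen & Luo recursion,
* the sparse A^{-1} by Henderson's rules (at most 9 contributions/animal),
* A22, the dense relationship block among a subset (typically the genotyped
  animals), by Colleau's indirect method (repeated triangular solves, never
  forming the full A).

Internal animal codes are 0-based and topologically sorted (parents precede
offspring); reports use 1-based codes.  Unknown parents contribute as
unrelated, non-inbred base animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

MISSING = -1
DEFAULT_MISSING_SENTINELS = ("0", "")


class PedigreeError(ValueError):
    """Malformed pedigree: cycles, duplicates, unknown references."""


@dataclass
class Pedigree:
    """Recoded, topologically sorted pedigree.

    ``sire`` / ``dam`` hold 0-based internal codes, ``MISSING`` (-1) for an
    unknown parent.  Row order is the internal code order, so parents always
    appear before their offspring.
    """

    animal_id: np.ndarray          # object array of opaque id strings
    sire: np.ndarray               # int32 codes, MISSING if unknown
    dam: np.ndarray                # int32 codes, MISSING if unknown
    line: np.ndarray               # object array of line labels
    birth_year: np.ndarray         # int32
    genotyped: np.ndarray          # bool
    litter: np.ndarray | None = None   # object array of litter codes, optional
    _code: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._code:
            self._code = {a: i for i, a in enumerate(self.animal_id)}

    @property
    def n(self) -> int:
        return len(self.animal_id)

    def code(self, animal) -> int:
        return self._code[animal]

    def codes(self, animals) -> np.ndarray:
        try:
            return np.array([self._code[a] for a in animals], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"unknown animal {e.args[0]!r}") from None

    @property
    def genotyped_codes(self) -> np.ndarray:
        return np.flatnonzero(self.genotyped)

    def to_frame(self) -> pd.DataFrame:
        sid = np.where(self.sire >= 0, self.animal_id[np.maximum(self.sire, 0)], "0")
        did = np.where(self.dam >= 0, self.animal_id[np.maximum(self.dam, 0)], "0")
        df = pd.DataFrame({
            "animal": self.animal_id, "sire": sid, "dam": did,
            "line": self.line, "birth_year": self.birth_year,
            "genotyped": self.genotyped.astype(int),
        })
        if self.litter is not None:
            df["litter"] = self.litter
        return df


@dataclass
class InbreedingVector:
    """Per-animal inbreeding coefficients, aligned with pedigree codes."""

    F: np.ndarray

    def mean_over(self, codes) -> float:
        return float(np.mean(self.F[np.asarray(codes)]))


DEFAULT_COLUMNS = {
    "animal": "animal", "sire": "sire", "dam": "dam",
    "line": "line", "birth_year": "birth_year", "genotyped": "genotyped",
    "litter": "litter",
}


def read_pedigree(path, column_map: dict | None = None,
                  missing=DEFAULT_MISSING_SENTINELS, sep=",") -> Pedigree:
    """Read a delimited pedigree file, recode and topologically sort it.

    The file must have a header; ``column_map`` renames file columns onto the
    canonical names (animal, sire, dam, line, birth_year, genotyped, litter).
    Records listed before their parents are handled; cycles and duplicate ids
    raise :class:`PedigreeError`.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    ren = {v: k for k, v in cols.items() if v in df.columns}
    df = df.rename(columns=ren)
    for need in ("animal", "sire", "dam"):
        if need not in df.columns:
            raise PedigreeError(f"pedigree file lacks column {need!r}")
    return pedigree_from_frame(df, missing=missing)


def pedigree_from_frame(df: pd.DataFrame,
                        missing=DEFAULT_MISSING_SENTINELS) -> Pedigree:
    """Build a recoded :class:`Pedigree` from a raw dataframe of id strings."""
    animals = df["animal"].astype(str).to_numpy()
    if len(set(animals)) != len(animals):
        s = pd.Series(animals)
        dup = s[s.duplicated()].iloc[0]
        raise PedigreeError(f"duplicate animal_id {dup!r}")
    miss = set(missing)
    sire_raw = df["sire"].astype(str).to_numpy()
    dam_raw = df["dam"].astype(str).to_numpy()
    idx = {a: i for i, a in enumerate(animals)}
    n = len(animals)

    def parent_row(raw):
        out = np.full(n, MISSING, dtype=np.int64)
        for i, p in enumerate(raw):
            if p in miss:
                continue
            j = idx.get(p)
            if j is None:
                raise PedigreeError(
                    f"parent {p!r} of animal {animals[i]!r} has no own record")
            out[i] = j
        return out

    s0, d0 = parent_row(sire_raw), parent_row(dam_raw)
    order = _toposort(s0, d0, animals)
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    def remap(p):
        q = np.full(n, MISSING, dtype=np.int32)
        known = p[order] >= 0
        q[known] = rank[p[order][known]]
        return q

    def col(name, default, dtype=None):
        if name in df.columns:
            v = df[name].to_numpy()[order]
        else:
            v = np.full(n, default)
        return v if dtype is None else v.astype(dtype)

    return Pedigree(
        animal_id=animals[order].astype(object),
        sire=remap(s0), dam=remap(d0),
        line=col("line", "L1").astype(object),
        birth_year=pd.to_numeric(pd.Series(col("birth_year", 0)), errors="coerce")
                     .fillna(0).to_numpy().astype(np.int32),
        genotyped=pd.to_numeric(pd.Series(col("genotyped", 0)), errors="coerce")
                    .fillna(0).to_numpy().astype(bool),
        litter=(col("litter", None).astype(object)
                if "litter" in df.columns else None),
    )


def _toposort(sire, dam, animals) -> np.ndarray:
    """Kahn topological order (parents first); raises on cycles."""
    n = len(sire)
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    # stable: keep file order among ties
    queue.sort()
    order = []
    head = 0
    while head < len(queue):
        i = queue[head]; head += 1
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) < n:
        stuck = next(i for i in range(n) if indeg[i] > 0)
        raise PedigreeError(
            f"pedigree cycle detected involving animal {animals[stuck]!r}")
    return np.array(order, dtype=np.int64)


# ---------------------------------------------------------------------------
# inbreeding and Mendelian sampling variances

@njit(cache=True)
def _meuwissen_luo(sire, dam):
    n = sire.shape[0]
    F = np.zeros(n)
    v = np.zeros(n)
    for i in range(n):
        if sire[i] < 0 or dam[i] < 0:
            continue  # unknown parent => unrelated base => F = 0
        v[: i + 1] = 0.0
        v[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            vj = v[j]
            if vj == 0.0:
                continue
            s, d = sire[j], dam[j]
            if s >= 0 and d >= 0:
                dj = 0.5 - 0.25 * (F[s] + F[d])
            elif s >= 0 or d >= 0:
                p = s if s >= 0 else d
                dj = 0.75 - 0.25 * F[p]
            else:
                dj = 1.0
            aii += vj * vj * dj
            if s >= 0:
                v[s] += 0.5 * vj
            if d >= 0:
                v[d] += 0.5 * vj
        F[i] = aii - 1.0
    return F


def compute_inbreeding(ped: Pedigree) -> InbreedingVector:
    """Inbreeding coefficients by the Meuwissen-Luo recursion.

    F_i is half the numerator relationship between i's parents; animals with
    any unknown parent have F = 0 (unrelated base convention).
    """
    return InbreedingVector(F=_meuwissen_luo(ped.sire, ped.dam))


def mendelian_variances(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Diagonal of D in A = T D T' (within-family segregation variances)."""
    if F is None:
        F = compute_inbreeding(ped).F
    s, d = ped.sire, ped.dam
    Fs = np.where(s >= 0, F[np.maximum(s, 0)], 0.0)
    Fd = np.where(d >= 0, F[np.maximum(d, 0)], 0.0)
    ks = (s >= 0).astype(float)
    kd = (d >= 0).astype(float)
    return 1.0 - 0.25 * (ks * (1.0 + Fs) + kd * (1.0 + Fd))


# ---------------------------------------------------------------------------
# A^{-1} by Henderson's rules

def build_A_inverse(ped: Pedigree,
                    F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse A^{-1} assembled by Henderson's rules with inbreeding.

    For each animal i with parent set p the inverse receives
    alpha_i = 1/d_i at (i,i), -alpha/2 at (i,p) and alpha/4 at (p,p'), so at
    most nine nonzero contributions per animal.
    """
    dvec = mendelian_variances(ped, F)
    rows, cols, vals = _ainv_triplets(ped.sire, ped.dam, dvec)
    n = ped.n
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return A.tocsr()


@njit(cache=True)
def _ainv_triplets(sire, dam, dvec):
    n = sire.shape[0]
    cap = 9 * n
    rows = np.empty(cap, dtype=np.int64)
    cols = np.empty(cap, dtype=np.int64)
    vals = np.empty(cap)
    k = 0
    for i in range(n):
        alpha = 1.0 / dvec[i]
        rows[k] = i; cols[k] = i; vals[k] = alpha; k += 1
        for p in (sire[i], dam[i]):
            if p >= 0:
                rows[k] = i; cols[k] = p; vals[k] = -0.5 * alpha; k += 1
                rows[k] = p; cols[k] = i; vals[k] = -0.5 * alpha; k += 1
        for p in (sire[i], dam[i]):
            if p < 0:
                continue
            for q in (sire[i], dam[i]):
                if q < 0:
                    continue
                rows[k] = p; cols[k] = q; vals[k] = 0.25 * alpha; k += 1
    return rows[:k], cols[:k], vals[:k]


# ---------------------------------------------------------------------------
# A22 by Colleau's indirect method

@njit(cache=True)
def _A_matvec(sire, dam, dvec, q):
    """w = A q through the T D T' factorisation (two triangular sweeps)."""
    n = sire.shape[0]
    x = q.copy()
    for i in range(n - 1, -1, -1):
        xi = x[i]
        if xi != 0.0:
            if sire[i] >= 0:
                x[sire[i]] += 0.5 * xi
            if dam[i] >= 0:
                x[dam[i]] += 0.5 * xi
    x *= dvec
    for i in range(n):
        acc = x[i]
        if sire[i] >= 0:
            acc += 0.5 * x[sire[i]]
        if dam[i] >= 0:
            acc += 0.5 * x[dam[i]]
        x[i] = acc
    return x


@njit(cache=True)
def _A_columns(sire, dam, dvec, targets):
    n = sire.shape[0]
    out = np.empty((targets.shape[0], n))
    for t in range(targets.shape[0]):
        e = np.zeros(n)
        e[targets[t]] = 1.0
        out[t] = _A_matvec(sire, dam, dvec, e)
    return out


def relationship_columns(ped: Pedigree, animals,
                         F: np.ndarray | None = None) -> np.ndarray:
    """Rows of A for the given animals against the whole pedigree.

    Uses Colleau's indirect method: each row costs one backward and one
    forward sweep over the pedigree, O(n) per animal.
    """
    codes = np.asarray(ped.codes(animals) if not np.issubdtype(
        np.asarray(animals).dtype, np.integer) else animals, dtype=np.int64)
    dvec = mendelian_variances(ped, F)
    return _A_columns(ped.sire, ped.dam, dvec, codes)


def build_A22(ped: Pedigree, genotyped=None,
              F: np.ndarray | None = None) -> np.ndarray:
    """Dense numerator relationships among a subset (default: genotyped).

    Exact principal submatrix of A, computed indirectly (never forming A).
    """
    if genotyped is None:
        codes = ped.genotyped_codes
    else:
        arr = np.asarray(genotyped)
        codes = (arr.astype(np.int64) if np.issubdtype(arr.dtype, np.integer)
                 else ped.codes(genotyped))
    if len(codes) == 0:
        raise PedigreeError("empty genotyped subset")
    cols = relationship_columns(ped, codes, F)
    A22 = cols[:, codes]
    return 0.5 * (A22 + A22.T)   # symmetrise away roundoff


# ---------------------------------------------------------------------------
# truncation utility

def truncate_pedigree(ped: Pedigree, min_birth_year: int) -> Pedigree:
    """Drop animals born before ``min_birth_year``; orphans are re-founded.

    Animals whose parents are removed keep their own record with the parent
    slot set to MISSING, i.e. they become base animals of their line.
    """
    keep = ped.birth_year >= min_birth_year
    keep_codes = np.flatnonzero(keep)
    rank = np.full(ped.n, MISSING, dtype=np.int32)
    rank[keep_codes] = np.arange(len(keep_codes))

    def remap(p):
        out = np.full(len(keep_codes), MISSING, dtype=np.int32)
        pp = p[keep_codes]
        known = pp >= 0
        out[known] = rank[pp[known]]
        return out

    return Pedigree(
        animal_id=ped.animal_id[keep_codes],
        sire=remap(ped.sire), dam=remap(ped.dam),
        line=ped.line[keep_codes],
        birth_year=ped.birth_year[keep_codes],
        genotyped=ped.genotyped[keep_codes],
        litter=None if ped.litter is None else ped.litter[keep_codes],
    )
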