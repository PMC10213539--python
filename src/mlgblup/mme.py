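"""Multi-trait mixed-model equations: assembly, solving, GEBV extraction.

The model per trait is y = Xb + Wc + Zu (+ ZQg) + e with fixed effects b
(categorical contemporary groups and optional covariates), random litter
effects c, additive effects u with covariance structure given by an
:class:`~mlgblup.hmatrix.HInverse` flavor, and group effects g carried
inside the coefficient matrix for the UPG flavors.

Unknown ordering: all fixed effects (trait-major), then litters and then
additive levels, both level-major with traits fastest, so the variance
penalties are Kronecker products C0^{-1} (x) I and H^{-1} (x) G0^{-1}.
Missing trait records are handled per missing-value pattern: each record
contributes through the inverse of the residual covariance restricted to
its observed traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import linalg as spla

from .hmatrix import HInverse


class MMEError(ValueError):
    pass


@dataclass
class TraitModel:
    """Fixed-effect layout for one trait."""

    name: str
    fixed: tuple = ("cg",)
    covariates: tuple = ()


@dataclass
class ModelSpec:
    """Traits, their fixed effects, and the (co)variance components."""

    traits: list
    additive_cov: np.ndarray          # G0, T x T
    resid_cov: np.ndarray             # R0, T x T
    litter_var: np.ndarray            # T (independent across traits) or T x T
    litter_col: str = "litter"
    animal_col: str = "animal"

    def __post_init__(self):
        self.additive_cov = np.atleast_2d(np.asarray(self.additive_cov, float))
        self.resid_cov = np.atleast_2d(np.asarray(self.resid_cov, float))
        lv = np.asarray(self.litter_var, float)
        self.litter_cov = np.diag(np.atleast_1d(lv)) if lv.ndim <= 1 else lv
        T = len(self.traits)
        for name, M in (("additive", self.additive_cov),
                        ("residual", self.resid_cov),
                        ("litter", self.litter_cov)):
            if M.shape != (T, T):
                raise MMEError(f"{name} covariance is not {T}x{T}")
            if np.linalg.eigvalsh(M)[0] <= 0:
                raise MMEError(f"{name} covariance is not positive definite")

    @property
    def T(self) -> int:
        return len(self.traits)


@dataclass
class MMESystem:
    """Assembled symmetric system: sparse part + dense additive corrections."""

    lhs_sparse: sparse.csr_matrix     # data part + litter + sparse additive
    rhs: np.ndarray
    hinv: HInverse
    spec: ModelSpec
    g0_inv: np.ndarray
    offsets: dict                     # name -> (start, stop)
    fixed_labels: dict                # trait -> list of unknown labels
    litter_levels: np.ndarray
    animal_ids: np.ndarray

    @property
    def dim(self) -> int:
        return self.lhs_sparse.shape[0]

    @property
    def add_start(self) -> int:
        return self.offsets["additive"][0]

    def matvec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.lhs_sparse @ x
        T = self.spec.T
        a0 = self.add_start
        U = x[a0:].reshape(-1, T)
        Y = np.zeros_like(U)
        for r, c, M in self.hinv.blocks:
            Y[r] += M @ (U[c] @ self.g0_inv)
        y[a0:] += Y.ravel()
        return y

    def materialise(self) -> sparse.csr_matrix:
        """Full sparse LHS including the dense genomic correction blocks."""
        T = self.spec.T
        a0 = self.add_start
        parts = [self.lhs_sparse]
        for r, c, M in self.hinv.blocks:
            Ms = sparse.coo_matrix(M)
            # expand over trait pairs through G0^{-1}
            blk_rows, blk_cols, blk_data = [], [], []
            for t in range(T):
                for u in range(T):
                    g = self.g0_inv[t, u]
                    if g == 0.0:
                        continue
                    blk_rows.append(a0 + np.asarray(r)[Ms.row] * T + t)
                    blk_cols.append(a0 + np.asarray(c)[Ms.col] * T + u)
                    blk_data.append(Ms.data * g)
            parts.append(sparse.coo_matrix(
                (np.concatenate(blk_data),
                 (np.concatenate(blk_rows), np.concatenate(blk_cols))),
                shape=self.lhs_sparse.shape))
        total = parts[0]
        for p in parts[1:]:
            total = total + p.tocsr()
        return total.tocsr()


def assemble_mme(spec: ModelSpec, data: pd.DataFrame, hinv: HInverse,
                 ped) -> MMESystem:
    """Assemble the symmetric MME for phenotype table ``data``.

    ``data`` has one row per animal with trait columns (NaN = missing),
    categorical fixed-effect columns, covariate columns and a litter column.
    Every phenotyped animal must be in the pedigree underlying ``hinv``.
    """
    T = spec.T
    n_levels = hinv.dim                 # animals (+ groups / metafounders)
    animals = data[spec.animal_col].to_numpy()
    codes = ped.codes(animals)

    trait_y = []
    for tm in spec.traits:
        if tm.name not in data.columns:
            raise MMEError(f"trait column {tm.name!r} missing from data")
        trait_y.append(pd.to_numeric(data[tm.name], errors="coerce")
                       .to_numpy(float))
    Y = np.column_stack(trait_y)
    observed = ~np.isnan(Y)
    if not observed.any():
        raise MMEError("no phenotype records")

    # ---- unknown layout -------------------------------------------------
    offsets, fixed_labels = {}, {}
    pos = 0
    fixed_maps = []                    # per trait: list of (col, level->idx)
    for t, tm in enumerate(spec.traits):
        labels = []
        maps = []
        rows_t = observed[:, t]
        for colname in tm.fixed:
            if colname not in data.columns:
                raise MMEError(f"fixed-effect column {colname!r} missing")
            levels = pd.unique(data.loc[rows_t, colname])
            lmap = {lv: pos + len(labels) + i for i, lv in enumerate(levels)}
            labels += [f"{colname}={lv}" for lv in levels]
            maps.append(("cat", colname, lmap))
        for colname in tm.covariates:
            if colname not in data.columns:
                raise MMEError(f"covariate column {colname!r} missing")
            maps.append(("cov", colname, pos + len(labels)))
            labels.append(f"cov:{colname}")
        fixed_maps.append(maps)
        offsets[f"fixed:{tm.name}"] = (pos, pos + len(labels))
        fixed_labels[tm.name] = labels
        pos += len(labels)
    n_fixed = pos

    litter_levels = pd.unique(data[spec.litter_col]) \
        if spec.litter_col in data.columns else np.array([])
    lit_map = {lv: i for i, lv in enumerate(litter_levels)}
    offsets["litter"] = (pos, pos + len(litter_levels) * T)
    pos += len(litter_levels) * T
    offsets["additive"] = (pos, pos + n_levels * T)
    dim = pos + n_levels * T

    # ---- per-trait design matrices -------------------------------------
    n_rec = len(data)
    designs = []
    for t, tm in enumerate(spec.traits):
        rows, cols, vals = [], [], []
        rows_t = np.flatnonzero(observed[:, t])
        for i in rows_t:
            for kind, colname, ref in fixed_maps[t]:
                if kind == "cat":
                    cols.append(ref[data[colname].iloc[i]])
                    vals.append(1.0)
                else:
                    cols.append(ref)
                    vals.append(float(data[colname].iloc[i]))
                rows.append(i)
            if litter_levels.size:
                rows.append(i)
                cols.append(offsets["litter"][0]
                            + lit_map[data[spec.litter_col].iloc[i]] * T + t)
                vals.append(1.0)
            rows.append(i)
            cols.append(offsets["additive"][0] + codes[i] * T + t)
            vals.append(1.0)
        designs.append(sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n_rec, dim)))

    # ---- data part by missing-value pattern ----------------------------
    R0 = spec.resid_cov
    lhs = sparse.csr_matrix((dim, dim))
    rhs = np.zeros(dim)
    patt = observed @ (1 << np.arange(T))
    for code in np.unique(patt):
        rows = np.flatnonzero(patt == code)
        obs_t = [t for t in range(T) if code >> t & 1]
        if not obs_t:
            continue
        rinv = np.zeros((T, T))
        sub = np.linalg.inv(R0[np.ix_(obs_t, obs_t)])
        rinv[np.ix_(obs_t, obs_t)] = sub
        sel = sparse.csr_matrix(
            (np.ones(len(rows)), (np.arange(len(rows)), rows)),
            shape=(len(rows), n_rec))
        Zs = [sel @ designs[t] for t in range(T)]
        for t in obs_t:
            for u in obs_t:
                w = rinv[t, u]
                lhs = lhs + w * (Zs[t].T @ Zs[u])
                rhs += w * (Zs[t].T @ Y[rows, u])

    # ---- variance penalties --------------------------------------------
    if litter_levels.size:
        c0_inv = np.linalg.inv(spec.litter_cov)
        lstart = offsets["litter"][0]
        pen = sparse.kron(sparse.eye(len(litter_levels)),
                          sparse.csr_matrix(c0_inv), format="coo")
        pen = sparse.coo_matrix((pen.data, (pen.row + lstart,
                                            pen.col + lstart)),
                                shape=(dim, dim))
        lhs = lhs + pen.tocsr()
    g0_inv = np.linalg.inv(spec.additive_cov)
    astart = offsets["additive"][0]
    pen = sparse.kron(hinv.sparse_part, sparse.csr_matrix(g0_inv),
                      format="coo")
    pen = sparse.coo_matrix((pen.data, (pen.row + astart, pen.col + astart)),
                            shape=(dim, dim))
    lhs = (lhs + pen.tocsr()).tocsr()

    return MMESystem(lhs_sparse=lhs, rhs=rhs, hinv=hinv, spec=spec,
                     g0_inv=g0_inv, offsets=offsets, fixed_labels=fixed_labels,
                     litter_levels=litter_levels,
                     animal_ids=np.asarray(ped.animal_id))


@dataclass
class EvaluationResult:
    """Solutions of the MME plus the bookkeeping to read them."""

    solutions: np.ndarray
    system: MMESystem
    method: str
    iterations: int
    residual: float

    def _add_part(self) -> np.ndarray:
        a0 = self.system.add_start
        return self.solutions[a0:].reshape(-1, self.system.spec.T)

    def u(self) -> np.ndarray:
        """Additive solutions for real animals (levels x traits)."""
        n = self.system.hinv.n_animals
        return self._add_part()[:n]

    def g(self) -> np.ndarray:
        """Group (or metafounder) solutions, empty for the standard flavor."""
        n = self.system.hinv.n_animals
        return self._add_part()[n:]

    def fixed(self, trait: str) -> pd.Series:
        lo, hi = self.system.offsets[f"fixed:{trait}"]
        return pd.Series(self.solutions[lo:hi],
                         index=self.system.fixed_labels[trait])

    def litter(self) -> np.ndarray:
        lo, hi = self.system.offsets["litter"]
        return self.solutions[lo:hi].reshape(-1, self.system.spec.T)

    def gebv(self) -> pd.DataFrame:
        """GEBV table: u for standard/MF flavors, Qg + u for UPG flavors."""
        sysm = self.system
        vals = extract_gebv(self, sysm.hinv.flavor, sysm.hinv.Q)
        n = sysm.hinv.n_animals
        out = pd.DataFrame(vals, columns=[t.name for t in sysm.spec.traits])
        out.insert(0, "animal", sysm.animal_ids[:n])
        return out


def extract_gebv(result: EvaluationResult, flavor: str,
                 Q: np.ndarray | None = None) -> np.ndarray:
    """GEBV per animal x trait: u, plus Qg for the UPG flavors."""
    u = result.u()
    if flavor in ("standard", "mf"):
        return u
    if Q is None:
        raise MMEError(f"flavor {flavor!r} needs Q to reconstruct GEBV")
    return u + np.asarray(Q) @ result.g()


def solve_mme(system: MMESystem, method: str = "direct", tol: float = 1e-10,
              maxiter: int = 20000) -> EvaluationResult:
    """Solve the assembled MME.

    ``direct`` materialises and factorises the sparse LHS (falling back to a
    dense least-squares solve when the system is singular, as with UPG
    confounding); ``pcg`` runs Jacobi-preconditioned conjugate gradients
    against the matrix-free operator and never materialises the dense
    genomic blocks.  Both are deterministic.
    """
    rhs = system.rhs
    if method == "direct":
        full = system.materialise()
        sol = None
        try:
            with np.errstate(all="ignore"):
                cand = spla.spsolve(full.tocsc(), rhs)
            if np.all(np.isfinite(cand)):
                res = _rel_residual(system, cand)
                if res < 1e-6:
                    sol = cand
                    resid = res
        except Exception:
            sol = None
        if sol is None:
            if system.dim > 20000:
                raise MMEError("direct solve failed on a large system; "
                               "use method='pcg'")
            dense = full.toarray()
            sol, *_ = np.linalg.lstsq(dense, rhs, rcond=None)
            resid = _rel_residual(system, sol)
        return EvaluationResult(solutions=sol, system=system, method="direct",
                                iterations=0, residual=resid)
    if method != "pcg":
        raise MMEError(f"unknown solve method {method!r}")

    diag = _full_diagonal(system)
    diag = np.where(diag > 0, diag, 1.0)
    M = spla.LinearOperator((system.dim,) * 2, matvec=lambda x: x / diag)
    A = spla.LinearOperator((system.dim,) * 2, matvec=system.matvec)
    sol, info = spla.cg(A, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
    resid = _rel_residual(system, sol)
    if info > 0 and resid > 1e-6:
        raise MMEError(
            f"PCG did not converge in {maxiter} iterations "
            f"(relative residual {resid:.3e})")
    return EvaluationResult(solutions=sol, system=system, method="pcg",
                            iterations=int(info) if info else maxiter,
                            residual=resid)


def _rel_residual(system: MMESystem, sol: np.ndarray) -> float:
    r = system.matvec(sol) - system.rhs
    denom = np.linalg.norm(system.rhs)
    return float(np.linalg.norm(r) / denom) if denom > 0 else float(
        np.linalg.norm(r))


def _full_diagonal(system: MMESystem) -> np.ndarray:
    d = np.asarray(system.lhs_sparse.diagonal()).copy()
    T = system.spec.T
    a0 = system.add_start
    for r, c, M in system.hinv.blocks:
        r = np.asarray(r); c = np.asarray(c)
        common, ri, ci = np.intersect1d(r, c, return_indices=True)
        if len(common):
            for t in range(T):
                d[a0 + common * T + t] += M[ri, ci] * system.g0_inv[t, t]
    return d
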