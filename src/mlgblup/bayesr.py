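"""BayesR Gibbs sampler and conversion of posterior SNP variances to weights.

SNP effects are drawn from a four-component normal mixture with mean zero
and variances (0, 1e-4, 1e-3, 1e-2) x the genetic variance.  The Gibbs chain
samples, per iteration: the intercept, every SNP effect and its mixture
class, the mixture proportions (Dirichlet), the genetic variance and the
residual variance (scaled inverse chi-square).  Each iteration records the
per-SNP variance (the squared sampled effect); the posterior SNP variance is
the average over post-burn-in iterations and, rescaled so that trace(D)
equals the number of SNP, becomes the diagonal weight matrix of weighted
ssGBLUP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genomic import GenotypeSet, allele_frequencies


class BayesRError(ValueError):
    pass


@dataclass
class BayesRConfig:
    """Chain settings; mixture fractions are the canonical BayesR classes."""

    variance_fractions: tuple = (0.0, 1e-4, 1e-3, 1e-2)
    n_iter: int = 25_000
    burn_in: int = 5_000
    thin: int = 10
    dirichlet_prior: float = 1.0
    h2_init: float = 0.3
    seed: int = 0

    def __post_init__(self):
        fr = np.asarray(self.variance_fractions, float)
        if fr[0] != 0.0 or np.any(np.diff(fr) < 0):
            raise BayesRError(
                "variance fractions must be nondecreasing with first = 0")
        if self.n_iter <= self.burn_in:
            raise BayesRError("chain length must exceed burn-in")


@dataclass
class BayesRPosterior:
    snp_variance: np.ndarray        # posterior mean variance per SNP
    class_probs: np.ndarray         # SNP x class membership probabilities
    mixture_proportions: np.ndarray
    residual_variance: float
    genetic_variance: float
    markers: np.ndarray = field(default=None)

    def __post_init__(self):
        if np.any(self.snp_variance < 0):
            raise BayesRError("negative posterior SNP variance")


@njit(cache=True)
def _gibbs(Xt, y, fractions, n_iter, burn_in, alpha0, h2_init, seed):
    np.random.seed(seed)
    m, n = Xt.shape
    K = fractions.shape[0]
    xx = np.empty(m)
    for j in range(m):
        xx[j] = Xt[j] @ Xt[j]
    vary = y.var()
    sigma_e = vary * (1.0 - h2_init) + 1e-12
    sigma_g = vary * h2_init + 1e-12
    mu = y.mean()
    e = y - mu
    beta = np.zeros(m)
    klass = np.zeros(m, dtype=np.int64)
    pi = np.full(K, 1.0 / K)

    var_sum = np.zeros(m)
    class_cnt = np.zeros((m, K))
    pi_sum = np.zeros(K)
    se_sum = 0.0
    sg_sum = 0.0
    kept = 0
    logl = np.empty(K)
    nu0 = 4.0
    s0_g = sigma_g * (nu0 + 2.0) / nu0     # prior mode at the initial value
    s0_e = sigma_e * (nu0 + 2.0) / nu0

    for it in range(n_iter):
        # intercept
        e += mu
        mu = e.sum() / n + np.sqrt(sigma_e / n) * np.random.randn()
        e -= mu
        counts = np.zeros(K)
        ssq_scaled = 0.0
        m_nz = 0
        for j in range(m):
            if beta[j] != 0.0:
                for i in range(n):
                    e[i] += Xt[j, i] * beta[j]
            rhs = Xt[j] @ e
            mx = -1e300
            for k in range(K):
                vk = fractions[k] * sigma_g
                if vk <= 0.0:
                    logl[k] = np.log(pi[k] + 1e-300)
                else:
                    lam = xx[j] * vk + sigma_e
                    logl[k] = (np.log(pi[k] + 1e-300)
                               - 0.5 * np.log(lam / sigma_e)
                               + 0.5 * rhs * rhs * vk / (sigma_e * lam))
                if logl[k] > mx:
                    mx = logl[k]
            tot = 0.0
            for k in range(K):
                logl[k] = np.exp(logl[k] - mx)
                tot += logl[k]
            u = np.random.random() * tot
            acc = 0.0
            kk = K - 1
            for k in range(K):
                acc += logl[k]
                if u <= acc:
                    kk = k
                    break
            klass[j] = kk
            counts[kk] += 1.0
            vk = fractions[kk] * sigma_g
            if vk <= 0.0:
                beta[j] = 0.0
            else:
                prec = xx[j] + sigma_e / vk
                mean = rhs / prec
                beta[j] = mean + np.sqrt(sigma_e / prec) * np.random.randn()
                for i in range(n):
                    e[i] -= Xt[j, i] * beta[j]
                ssq_scaled += beta[j] * beta[j] / fractions[kk]
                m_nz += 1
        # mixture proportions ~ Dirichlet(counts + alpha0)
        tot = 0.0
        for k in range(K):
            pi[k] = np.random.gamma(counts[k] + alpha0, 1.0)
            tot += pi[k]
        for k in range(K):
            pi[k] /= tot
        # genetic variance ~ scaled inverse chi-square
        df_g = nu0 + m_nz
        sc_g = nu0 * s0_g + ssq_scaled
        sigma_g = sc_g / (2.0 * np.random.gamma(df_g / 2.0, 1.0))
        # residual variance
        sse = e @ e
        df_e = nu0 + n
        sc_e = nu0 * s0_e + sse
        sigma_e = sc_e / (2.0 * np.random.gamma(df_e / 2.0, 1.0))
        if not np.isfinite(sigma_e) or sigma_e <= 0.0:
            return (var_sum, class_cnt, pi_sum, se_sum, sg_sum, -1)
        if it >= burn_in:
            kept += 1
            for j in range(m):
                var_sum[j] += beta[j] * beta[j]
                class_cnt[j, klass[j]] += 1.0
            for k in range(K):
                pi_sum[k] += pi[k]
            se_sum += sigma_e
            sg_sum += sigma_g
    return (var_sum, class_cnt, pi_sum, se_sum, sg_sum, kept)


def run_bayesr(geno: GenotypeSet, phenotype: np.ndarray,
               config: BayesRConfig | None = None) -> BayesRPosterior:
    """Run the BayesR chain on pre-adjusted phenotypes of genotyped animals.

    One record per genotyped animal, in the row order of ``geno``.  Dosages
    are centred at 2p before entering the sampler.  Fully reproducible for a
    given seed.
    """
    cfg = config or BayesRConfig()
    y = np.asarray(phenotype, float)
    if len(y) != geno.n_animals:
        raise BayesRError("one phenotype record per genotyped animal required")
    X = geno.dosages.astype(float)
    p = allele_frequencies(geno)
    X = np.where(np.isnan(X), (2 * p)[None, :], X)
    Xt = np.ascontiguousarray((X - 2.0 * p[None, :]).T)
    out = _gibbs(Xt, y, np.asarray(cfg.variance_fractions, float),
                 cfg.n_iter, cfg.burn_in, cfg.dirichlet_prior,
                 cfg.h2_init, cfg.seed % (2**31 - 1))
    var_sum, class_cnt, pi_sum, se_sum, sg_sum, kept = out
    if kept < 0:
        raise BayesRError("divergent residual variance in the Gibbs chain")
    return BayesRPosterior(
        snp_variance=var_sum / kept,
        class_probs=class_cnt / kept,
        mixture_proportions=pi_sum / kept,
        residual_variance=se_sum / kept,
        genetic_variance=sg_sum / kept,
        markers=geno.markers,
    )


def variances_to_weights(post: BayesRPosterior,
                         floor: float = 1e-8) -> np.ndarray:
    """Posterior SNP variances rescaled so trace(D) = number of SNP.

    A small floor keeps zero-variance SNP strictly positive before the
    rescaling.
    """
    v = np.asarray(post.snp_variance, float)
    if np.all(v <= 0):
        raise BayesRError("all posterior SNP variances are zero")
    v = np.maximum(v, floor)
    m = len(v)
    return v * (m / v.sum())
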