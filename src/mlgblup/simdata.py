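"""Synthetic multi-line pig population generator.

Emulates the data structure a multi-line single-step evaluation consumes:
several purebred lines diverged from a shared ancestral population, an
optional crossbred line, multi-generation litters with some unknown parents,
chip- and sequence-density marker panels, and phenotypes generated under

    y = contemporary group + litter + additive (QTL sum) + residual.

Line divergence follows the Balding-Nichols model: per marker, the ancestral
frequency p is drawn uniformly and each line's base frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F) with drift parameter F, which makes the implied
metafounder Gamma (8 x covariance of base frequencies around 0.5) an
analytic quantity the truth container reports.

Genotypes are gene-dropped through the pedigree with recombination
(crossovers Poisson per Morgan along each chromosome); founder haplotypes
are drawn in linkage equilibrium at the line base frequencies.  Unknown
parents contribute immigrant gametes drawn from the line base, consistent
with their unknown-parent-group semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .genomic import GenotypeSet
from .pedigree import MISSING, Pedigree

__all__ = ["TraitDef", "SimConfig", "SimTruth", "SimResult",
           "simulate_population", "emit_fixtures"]


@dataclass(frozen=True)
class TraitDef:
    name: str
    recorded_on: str = "purebred"     # "purebred" | "crossbred"


@dataclass
class SimConfig:
    """Study conditions for the simulated multi-line population.

    Defaults give three purebred lines of 2,000 animals each (80 founders +
    8 generations of 48 litters of 5), one crossbred line, 5,000 sequence
    markers thinned to a 1,000-marker chip, 100 QTL kept off the chip, and a
    growth-like trait pair with h^2 = 0.3 and purebred-crossbred genetic
    correlation 0.7.
    """

    n_lines: int = 3
    founders_per_line: int = 80
    generations: int = 8
    sires_per_generation: int = 12
    dams_per_generation: int = 48
    litter_size: int = 5
    missing_parent_rate: float = 0.02
    genotyped_generations: int = 2
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    cm_per_mb: float = 1.0
    n_wgs: int = 5000
    n_chip: int = 1000
    n_qtl: int = 100
    qtl_on_chip: bool = False   # True: chip drawn from all markers incl. QTL
    drift: float = 0.10
    founder_pool_haplotypes: int = 40   # ancestral haplotypes per line base
    founder_pool_mixing: float = 4.0    # mosaic switch rate, per Morgan
    ancestral_freq_low: float = 0.05
    ancestral_freq_high: float = 0.95
    traits: tuple = (TraitDef("ADG", "purebred"), TraitDef("ADGX", "crossbred"))
    additive_cov: np.ndarray | None = None   # G0; default 0.3 diag, corr 0.7
    litter_var: np.ndarray | None = None     # per trait; default 0.1
    resid_var: np.ndarray | None = None      # per trait; default 0.6
    cg_sd: float = 0.5
    crossbred_sire_line: str | None = "TL1"
    crossbred_dam_line: str | None = "TL2"
    crossbred_litters_per_generation: int = 24
    crossbred_generations: int = 2
    genotype_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        t = len(self.traits)
        if self.additive_cov is None:
            G0 = np.full((t, t), 0.7 * 0.3)
            np.fill_diagonal(G0, 0.3)
            self.additive_cov = G0
        else:
            self.additive_cov = np.asarray(self.additive_cov, float)
        if self.litter_var is None:
            self.litter_var = np.full(t, 0.1)
        else:
            self.litter_var = np.asarray(self.litter_var, float)
        if self.resid_var is None:
            self.resid_var = np.full(t, 0.6)
        else:
            self.resid_var = np.asarray(self.resid_var, float)
        if not 0.0 <= self.drift < 1.0:
            raise ValueError("drift must be in [0, 1)")
        if self.n_chip + self.n_qtl > self.n_wgs:
            raise ValueError("chip + QTL markers exceed WGS marker count")

    @property
    def lines(self) -> list:
        return [f"TL{i+1}" for i in range(self.n_lines)]

    @property
    def has_crossbred(self) -> bool:
        return (self.crossbred_sire_line is not None
                and self.crossbred_dam_line is not None
                and self.crossbred_litters_per_generation > 0)


@dataclass
class SimTruth:
    """Ground truth: breeding values, QTL, base frequencies, implied Gamma."""

    tbv: pd.DataFrame                 # animal x trait true breeding values
    qtl_markers: np.ndarray
    qtl_effects: np.ndarray           # n_qtl x n_traits
    base_freq: pd.DataFrame           # line x marker base frequencies
    ancestral_freq: np.ndarray
    gamma_true: pd.DataFrame          # purebred lines
    additive_cov: np.ndarray
    litter_var: np.ndarray
    resid_var: np.ndarray


@dataclass
class SimResult:
    ped: Pedigree
    chip: GenotypeSet
    wgs: GenotypeSet
    phenotypes: pd.DataFrame
    truth: SimTruth
    config: SimConfig
    generation: np.ndarray = field(default=None)


@njit(cache=True)
def _base_gamete(pool_line, gpos, chrom_off, chrom_morgan, mixing, out):
    """A base-population gamete: recombinant mosaic of the line's ancestral
    haplotype pool (switch points Poisson(mixing) per Morgan)."""
    K = pool_line.shape[0]
    nc = chrom_off.shape[0] - 1
    for c in range(nc):
        a, b = chrom_off[c], chrom_off[c + 1]
        L = chrom_morgan[c] * mixing
        ncx = np.random.poisson(L)
        cxs = np.sort(np.random.random(ncx) * chrom_morgan[c])
        h = np.random.randint(0, K)
        ci = 0
        for mk in range(a, b):
            while ci < ncx and cxs[ci] < gpos[mk]:
                h = np.random.randint(0, K)
                ci += 1
            out[mk] = pool_line[h, mk]


@njit(cache=True)
def _gene_drop(seed, sire, dam, line_idx, pools, gpos, chrom_off,
               chrom_morgan, mixing):
    np.random.seed(seed)
    n = sire.shape[0]
    m = gpos.shape[0]
    nc = chrom_off.shape[0] - 1
    H = np.zeros((n, 2, m), dtype=np.int8)
    cx = np.empty(64)
    for i in range(n):
        for k in range(2):
            par = sire[i] if k == 0 else dam[i]
            if par < 0:
                _base_gamete(pools[line_idx[i]], gpos, chrom_off,
                             chrom_morgan, mixing, H[i, k])
            else:
                for c in range(nc):
                    a, b = chrom_off[c], chrom_off[c + 1]
                    L = chrom_morgan[c]
                    ncx = np.random.poisson(L)
                    if ncx > cx.shape[0]:
                        cx = np.empty(ncx)
                    for t in range(ncx):
                        cx[t] = np.random.random() * L
                    cxs = np.sort(cx[:ncx])
                    phase = np.random.randint(0, 2)
                    ci = 0
                    for mk in range(a, b):
                        while ci < ncx and cxs[ci] < gpos[mk]:
                            phase = 1 - phase
                            ci += 1
                        H[i, k, mk] = H[par, phase, mk]
    return H


def _build_pedigree(cfg: SimConfig, rng) -> tuple:
    """Mating design: per line per generation, random sires x dam litters."""
    animal, sire, dam = [], [], []
    line, year, litter, sex, generation = [], [], [], [], []
    by_line_gen = {}     # (line, gen) -> (codes, sexes)

    def add(aid, s, d, ln, gen, lit):
        animal.append(aid)
        sire.append(s)
        dam.append(d)
        line.append(ln)
        year.append(2000 + gen)
        litter.append(lit)
        generation.append(gen)
        sx = int(rng.integers(0, 2))
        sex.append(sx)
        by_line_gen.setdefault((ln, gen), []).append((len(animal) - 1, sx))
        return len(animal) - 1

    for ln in cfg.lines:
        for f in range(cfg.founders_per_line):
            add(f"{ln}_G0_{f}", MISSING, MISSING, ln, 0, f"{ln}_G0_L{f}")
    for gen in range(1, cfg.generations + 1):
        for ln in cfg.lines:
            prev = by_line_gen[(ln, gen - 1)]
            males = [c for c, sx in prev if sx == 1]
            females = [c for c, sx in prev if sx == 0]
            if len(males) < 2 or len(females) < 2:
                raise ValueError(
                    f"infeasible mating design: line {ln} generation {gen - 1} "
                    f"has {len(males)} males / {len(females)} females")
            sires = rng.choice(males, size=min(cfg.sires_per_generation,
                                               len(males)), replace=False)
        # one litter per selected dam, sire drawn among selected sires
            dams = rng.choice(females, size=min(cfg.dams_per_generation,
                                                len(females)), replace=False)
            for li, dcode in enumerate(dams):
                scode = int(rng.choice(sires))
                lit = f"{ln}_G{gen}_L{li}"
                for off in range(cfg.litter_size):
                    s_rec, d_rec = scode, int(dcode)
                    if rng.random() < cfg.missing_parent_rate:
                        s_rec = MISSING
                    if rng.random() < cfg.missing_parent_rate:
                        d_rec = MISSING
                    add(f"{ln}_G{gen}_{li}_{off}", s_rec, d_rec, ln, gen, lit)
        if (cfg.has_crossbred
                and gen > cfg.generations - cfg.crossbred_generations):
            sm = [c for c, sx in by_line_gen[(cfg.crossbred_sire_line, gen - 1)]
                  if sx == 1]
            df = [c for c, sx in by_line_gen[(cfg.crossbred_dam_line, gen - 1)]
                  if sx == 0]
            dams = rng.choice(df, size=min(cfg.crossbred_litters_per_generation,
                                           len(df)), replace=False)
            for li, dcode in enumerate(dams):
                scode = int(rng.choice(sm))
                lit = f"CL_G{gen}_L{li}"
                for off in range(cfg.litter_size):
                    add(f"CL_G{gen}_{li}_{off}", scode, int(dcode), "CL",
                        gen, lit)
    generation = np.array(generation)
    genotyped = generation > cfg.generations - cfg.genotyped_generations
    ped = Pedigree(
        animal_id=np.array(animal, dtype=object),
        sire=np.array(sire, dtype=np.int32),
        dam=np.array(dam, dtype=np.int32),
        line=np.array(line, dtype=object),
        birth_year=np.array(year, dtype=np.int32),
        genotyped=genotyped,
        litter=np.array(litter, dtype=object),
    )
    return ped, generation


def _marker_map(cfg: SimConfig, rng) -> pd.DataFrame:
    per = np.full(cfg.n_chromosomes, cfg.n_wgs // cfg.n_chromosomes)
    per[: cfg.n_wgs % cfg.n_chromosomes] += 1
    rows = []
    for c in range(cfg.n_chromosomes):
        bp = np.sort(rng.integers(1, cfg.chrom_length_bp, size=per[c]))
        while len(np.unique(bp)) < per[c]:      # resolve rare collisions
            bp = np.unique(np.concatenate(
                [bp, rng.integers(1, cfg.chrom_length_bp,
                                  size=per[c] - len(np.unique(bp)))]))
        bp = np.sort(np.unique(bp))[: per[c]]
        for j, pos in enumerate(bp):
            rows.append((f"snp{c+1}_{pos}", c + 1, int(pos)))
    return pd.DataFrame(rows, columns=["marker", "chrom", "bp"])


def simulate_population(cfg: SimConfig | None = None) -> SimResult:
    """Simulate pedigree, genotypes, phenotypes and truth; fully seeded."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    ped, generation = _build_pedigree(cfg, rng)
    mmap = _marker_map(cfg, rng)
    m = len(mmap)

    panc = rng.uniform(cfg.ancestral_freq_low, cfg.ancestral_freq_high, size=m)
    if cfg.drift > 0:
        F = cfg.drift
        a, b = panc * (1 - F) / F, (1 - panc) * (1 - F) / F
        base = rng.beta(np.tile(a, (cfg.n_lines, 1)),
                        np.tile(b, (cfg.n_lines, 1)))
        base = np.clip(base, 1e-4, 1 - 1e-4)
    else:
        base = np.tile(panc, (cfg.n_lines, 1))
    line_names = list(cfg.lines)
    if cfg.has_crossbred:
        si = line_names.index(cfg.crossbred_sire_line)
        di = line_names.index(cfg.crossbred_dam_line)
        base_all = np.vstack([base, 0.5 * (base[si] + base[di])])
        line_names_all = line_names + ["CL"]
    else:
        base_all, line_names_all = base, line_names
    line_idx = np.array([line_names_all.index(ln) for ln in ped.line],
                        dtype=np.int32)

    gpos = (mmap["bp"].to_numpy() * cfg.cm_per_mb * 1e-8).astype(float)
    counts = mmap.groupby("chrom", sort=True).size().to_numpy()
    chrom_off = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    chrom_morgan = np.full(cfg.n_chromosomes,
                           cfg.chrom_length_bp * cfg.cm_per_mb * 1e-8)
    # ancestral haplotype pool per base population: founder gametes are
    # recombinant mosaics of these, giving each line base the LD of a
    # finite ancestral population
    K = max(cfg.founder_pool_haplotypes, 2)
    if cfg.drift > 0:
        pools = (rng.random((base_all.shape[0], K, m))
                 < base_all[:, None, :]).astype(np.int8)
    else:
        # no divergence: every line base is literally the same population
        shared = (rng.random((K, m)) < panc[None, :]).astype(np.int8)
        pools = np.repeat(shared[None, :, :], base_all.shape[0], axis=0)
    base_realised = pools.mean(axis=1)
    drop_seed = int(rng.integers(0, 2**31 - 1))
    H = _gene_drop(drop_seed, ped.sire.astype(np.int64),
                   ped.dam.astype(np.int64), line_idx, pools, gpos,
                   chrom_off, chrom_morgan, cfg.founder_pool_mixing)
    dosage = (H[:, 0, :] + H[:, 1, :]).astype(np.int8)

    # QTL / chip marker partition; by default QTL stay off the chip so
    # chip-vs-sequence panel comparisons are meaningful
    qtl = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    pool = np.arange(m) if cfg.qtl_on_chip else np.setdiff1d(np.arange(m), qtl)
    chip_idx = np.sort(rng.choice(pool, size=cfg.n_chip, replace=False))

    # trait architecture: correlated QTL effects, scaled so the mean
    # within-line base additive variance (the variance among a line's
    # founders, which is what the pedigree model calls sigma2_u) equals the
    # configured component
    T = len(cfg.traits)
    G0 = cfg.additive_cov
    sd = np.sqrt(np.diag(G0))
    corr = G0 / np.outer(sd, sd)
    Lc = np.linalg.cholesky(corr)
    eff = rng.standard_normal((cfg.n_qtl, T)) @ Lc.T
    base_pb = base_realised[: cfg.n_lines]
    wq = np.mean(2.0 * base_pb[:, qtl] * (1.0 - base_pb[:, qtl]), axis=0)
    for t in range(T):
        scale = np.sqrt(G0[t, t] / np.sum(wq * eff[:, t] ** 2))
        eff[:, t] *= scale
    centred = dosage[:, qtl].astype(float) - 2.0 * panc[qtl][None, :]
    tbv = centred @ eff

    phen = _phenotypes(cfg, ped, generation, tbv, rng)

    gmask = ped.genotyped
    gids = ped.animal_id[gmask]
    dos_g = dosage[gmask].astype(float)
    if cfg.genotype_missing_rate > 0:
        miss = rng.random(dos_g.shape) < cfg.genotype_missing_rate
        dos_g = np.where(miss, np.nan, dos_g)
    wgs = GenotypeSet(dos_g, gids, mmap, panel="wgs")
    chip = GenotypeSet(dos_g[:, chip_idx], gids,
                       mmap.iloc[chip_idx].reset_index(drop=True),
                       panel="chip")

    # implied Gamma from the realised base (founder-pool) frequencies
    dev = base_pb - 0.5
    gamma_true = 8.0 * (dev @ dev.T) / m
    truth = SimTruth(
        tbv=pd.DataFrame(tbv, index=ped.animal_id,
                         columns=[t.name for t in cfg.traits]),
        qtl_markers=mmap["marker"].to_numpy()[qtl],
        qtl_effects=eff,
        base_freq=pd.DataFrame(base_realised, index=line_names_all),
        ancestral_freq=panc,
        gamma_true=pd.DataFrame(gamma_true, index=line_names,
                                columns=line_names),
        additive_cov=G0, litter_var=cfg.litter_var, resid_var=cfg.resid_var,
    )
    return SimResult(ped=ped, chip=chip, wgs=wgs, phenotypes=phen,
                     truth=truth, config=cfg, generation=generation)


def _phenotypes(cfg, ped, generation, tbv, rng) -> pd.DataFrame:
    T = len(cfg.traits)
    n = ped.n
    cg = np.array([f"{ln}_G{g}" for ln, g in zip(ped.line, generation)],
                  dtype=object)
    cg_levels = pd.unique(cg)
    cg_eff = {c: rng.normal(0.0, cfg.cg_sd, size=T) for c in cg_levels}
    lit_levels = pd.unique(ped.litter)
    lit_eff = {c: rng.normal(0.0, np.sqrt(cfg.litter_var)) for c in lit_levels}
    resid = rng.normal(0.0, 1.0, size=(n, T)) * np.sqrt(cfg.resid_var)[None, :]

    is_cross = ped.line == "CL"
    recorded = np.zeros((n, T), dtype=bool)
    for t, tr in enumerate(cfg.traits):
        if tr.recorded_on == "crossbred":
            recorded[:, t] = is_cross
        else:
            recorded[:, t] = (~is_cross) & (generation >= 1)
    y = np.full((n, T), np.nan)
    for i in range(n):
        for t in range(T):
            if recorded[i, t]:
                y[i, t] = (cg_eff[cg[i]][t] + lit_eff[ped.litter[i]][t]
                           + tbv[i, t] + resid[i, t])
    df = pd.DataFrame({
        "animal": ped.animal_id, "line": ped.line,
        "generation": generation, "litter": ped.litter, "cg": cg,
    })
    for t, tr in enumerate(cfg.traits):
        df[tr.name] = y[:, t]
    return df[recorded.any(axis=1)].reset_index(drop=True)


def emit_fixtures(cfg: SimConfig, outdir) -> dict:
    """Write the simulated dataset as plain-text fixture files.

    Emits pedigree.csv, chip/wgs dosage TSVs with .bim-like maps,
    phenotypes.csv, a model config with the true variance components, and a
    truth.json.  Byte-identical across runs with the same config and seed.
    """
    from pathlib import Path

    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    res = simulate_population(cfg)
    paths = {}

    ped_df = res.ped.to_frame()
    paths["pedigree"] = out / "pedigree.csv"
    ped_df.to_csv(paths["pedigree"], index=False)

    for tag, geno in (("chip", res.chip), ("wgs", res.wgs)):
        raw = pd.DataFrame(geno.dosages, columns=geno.markers)
        raw.insert(0, "animal", geno.animal_ids)
        paths[f"{tag}_raw"] = out / f"{tag}.raw.tsv"
        raw.to_csv(paths[f"{tag}_raw"], sep="\t", index=False,
                   float_format="%.0f")
        paths[f"{tag}_map"] = out / f"{tag}.bim.tsv"
        geno.marker_map.to_csv(paths[f"{tag}_map"], sep="\t", index=False)

    paths["phenotypes"] = out / "phenotypes.csv"
    res.phenotypes.to_csv(paths["phenotypes"], index=False)

    model = {
        "traits": [t.name for t in cfg.traits],
        "additive_cov": np.asarray(cfg.additive_cov).tolist(),
        "litter_var": np.asarray(cfg.litter_var).tolist(),
        "resid_var": np.asarray(cfg.resid_var).tolist(),
        "fixed": ["cg"], "litter": "litter", "seed": cfg.seed,
    }
    paths["model"] = out / "model.yaml"
    with open(paths["model"], "w") as fh:
        yaml.safe_dump(model, fh, sort_keys=True)

    truth = {
        "qtl_markers": list(map(str, res.truth.qtl_markers)),
        "qtl_effects": res.truth.qtl_effects.tolist(),
        "gamma_true": res.truth.gamma_true.to_numpy().tolist(),
        "lines": list(res.truth.gamma_true.columns),
    }
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def read_genotypes(raw_path, map_path, panel="chip") -> GenotypeSet:
    """Read a dosage TSV (animal + one column per marker) and a .bim-like map."""
    raw = pd.read_csv(raw_path, sep="\t")
    mmap = pd.read_csv(map_path, sep="\t")
    animals = raw["animal"].astype(str).to_numpy()
    dos = raw.drop(columns=["animal"]).to_numpy(float)
    return GenotypeSet(dos, animals, mmap, panel=panel)
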