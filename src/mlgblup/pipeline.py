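"""End-to-end orchestration: from data to GEBV and LR reports.

`evaluate` wires one single-step evaluation: genotype panel selection,
relationship operators for the requested H^{-1} flavor, MME assembly and
solve.  `lr_run` performs the whole/reduced pair of evaluations behind the
LR validation method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import groups as grp
from .genomic import (GenotypeSet, apy_inverse, blend_G, build_G,
                      select_core, tune_G_to_A22)
from .hmatrix import HInverse, build_hinv
from .lr_validation import Split, SplitSpec, lr_statistics, make_split
from .mme import EvaluationResult, ModelSpec, TraitModel, assemble_mme, solve_mme
from .pedigree import Pedigree, build_A22, build_A_inverse, compute_inbreeding


@dataclass
class APYSettings:
    """Core sizing/sampling for the APY inverse of G."""

    var_threshold: float = 0.98
    proportions: dict | None = None
    seed: int = 0


def model_spec_from_sim(sim, fixed=("cg",), covariates=()) -> ModelSpec:
    """ModelSpec using the simulator's true variance components."""
    cfg = sim.config
    return ModelSpec(
        traits=[TraitModel(t.name, fixed=tuple(fixed),
                           covariates=tuple(covariates))
                for t in cfg.traits],
        additive_cov=cfg.additive_cov,
        resid_cov=np.diag(cfg.resid_var),
        litter_var=cfg.litter_var,
    )


def build_relationships(ped: Pedigree, geno: GenotypeSet, flavor: str,
                        blend_beta: float = 0.05,
                        apy: APYSettings | None = None,
                        weights: np.ndarray | None = None,
                        gamma: grp.GammaMatrix | None = None,
                        rule: grp.GroupAssignment | None = None,
                        tune: bool | None = None) -> HInverse:
    """Assemble the H^{-1} flavor for the genotyped animals in ``geno``.

    ``tune`` applies the G-to-A22 compatibility rescaling before blending;
    the default is on for the observed-frequency flavors and off for MF,
    whose 0.5-centred G is made compatible through Gamma instead.
    """
    g_ids = [a for a in ped.animal_id[ped.genotyped] if a in set(geno.animal_ids)]
    geno = geno.subset_animals(np.array(g_ids, dtype=object))
    codes = ped.codes(g_ids)
    order = np.argsort(codes)
    geno = geno.subset_animals(order)
    codes = codes[order]

    F = compute_inbreeding(ped).F
    mode = "half" if flavor == "mf" else "observed"
    G = build_G(geno, freq_mode=mode, weights=weights)

    if flavor == "mf":
        if rule is None:
            rule = grp.GroupAssignment.per_line(list(ped.line))
        pwg = grp.assign_groups(ped, rule)
        if gamma is None:
            gamma = grp.estimate_gamma(ped, geno, rule)
        a22 = grp.build_A22Gamma(pwg, gamma, genotyped=ped.animal_id[codes])
        Gb = blend_G(G, a22, blend_beta)
        ginv = _invert_G(Gb, ped.line[codes], apy)
        aginv = grp.build_AGamma_inverse(pwg, gamma)
        return build_hinv("mf", ped.n, codes, ginv=ginv,
                          a22inv=np.linalg.inv(a22), agamma_inv=aginv,
                          g_freq_mode="half")

    a22 = build_A22(ped, codes, F)
    if tune is None or tune:
        G = tune_G_to_A22(G, a22)
    Gb = blend_G(G, a22, blend_beta)
    ginv = _invert_G(Gb, ped.line[codes], apy)
    a22inv = np.linalg.inv(a22)
    if flavor == "standard":
        ainv = build_A_inverse(ped, F)
        return build_hinv("standard", ped.n, codes, ainv=ainv, ginv=ginv,
                          a22inv=a22inv, g_freq_mode="observed")
    if rule is None:
        rule = grp.GroupAssignment.per_line(list(ped.line))
    pwg = grp.assign_groups(ped, rule)
    Q = grp.build_Q(pwg)
    astar = grp.build_Astar(pwg, F)
    return build_hinv(flavor, ped.n, codes, astar=astar, Q=Q, ginv=ginv,
                      a22inv=a22inv, n_groups=pwg.n_groups,
                      g_freq_mode="observed")


def _invert_G(Gb, lines, apy: APYSettings | None):
    if apy is None:
        return np.linalg.inv(Gb.values)
    part = select_core(Gb, lines, var_threshold=apy.var_threshold,
                       proportions=apy.proportions, seed=apy.seed)
    return apy_inverse(Gb, part)


def evaluate(ped: Pedigree, geno: GenotypeSet, phenotypes: pd.DataFrame,
             spec: ModelSpec, flavor: str = "standard",
             panel_markers=None, weights: np.ndarray | None = None,
             blend_beta: float = 0.05, apy: APYSettings | None = None,
             gamma=None, rule=None, exclude_phenotypes=None,
             method: str = "direct", hinv: HInverse | None = None
             ) -> EvaluationResult:
    """One single-step evaluation; returns the solved system.

    ``exclude_phenotypes`` blanks all trait records of the given animals
    (the reduced run of LR validation).  A prebuilt ``hinv`` skips the
    relationship assembly (used to share it between whole/reduced runs).
    """
    if panel_markers is not None:
        geno = geno.subset_markers(np.asarray(panel_markers, dtype=object))
    if hinv is None:
        hinv = build_relationships(ped, geno, flavor, blend_beta=blend_beta,
                                   apy=apy, weights=weights, gamma=gamma,
                                   rule=rule)
    data = phenotypes
    if exclude_phenotypes is not None:
        excl = set(map(str, exclude_phenotypes))
        data = phenotypes.copy()
        mask = data[spec.animal_col].astype(str).isin(excl)
        for tm in spec.traits:
            data.loc[mask, tm.name] = np.nan
    system = assemble_mme(spec, data, hinv, ped)
    return solve_mme(system, method=method)


def calibration_scenario(seed: int):
    """SimConfig for the LR calibration study: three purebred lines of
    ~2,000 animals, a 1,000-marker chip thinned from 1,100 sequence markers,
    100 off-chip QTL, h^2 = 0.3, random mating (no selection)."""
    from .simdata import SimConfig, TraitDef
    return SimConfig(n_wgs=1100, n_chip=1000, n_qtl=100,
                     traits=(TraitDef("ADG"),),
                     crossbred_sire_line=None, crossbred_dam_line=None,
                     seed=seed)


def lr_calibration_study(seed: int = 1, n_replicates: int = 20,
                         flavor: str = "standard") -> dict:
    """Replicated LR calibration under a correctly specified simulation.

    Runs ``n_replicates`` independent populations from
    :func:`calibration_scenario`, evaluates each with whole and reduced
    (validation phenotypes removed) data, and averages the LR statistics.
    Replicate seeds derive deterministically from ``seed``.
    """
    from .simdata import simulate_population
    states = np.random.SeedSequence(seed).generate_state(n_replicates)
    b1, bias, acc, n_val = [], [], [], []
    for s in states:
        cfg = calibration_scenario(int(s % (2**31 - 1)))
        rep = lr_run(simulate_population(cfg), flavor=flavor).reports["ADG"]
        b1.append(rep.dispersion)
        bias.append(rep.bias)
        acc.append(rep.accuracy)
        n_val.append(rep.n_validation)
    return {
        "mean_b1": float(np.mean(b1)), "mean_bias": float(np.mean(bias)),
        "mean_accuracy": float(np.mean(acc)),
        "se_b1": float(np.std(b1) / np.sqrt(len(b1))),
        "se_bias": float(np.std(bias) / np.sqrt(len(bias))),
        "replicates": len(b1),
        "mean_n_validation": float(np.mean(n_val)),
    }


@dataclass
class LROutcome:
    reports: dict                 # trait -> LRReport
    split: Split
    whole: EvaluationResult
    reduced: EvaluationResult


def lr_run(sim, flavor: str = "standard", panel_markers=None,
           weights=None, blend_beta: float = 0.05,
           apy: APYSettings | None = None, split_spec: SplitSpec | None = None,
           method: str = "direct", spec: ModelSpec | None = None) -> LROutcome:
    """Whole/reduced evaluation pair and LR statistics on a simulated set."""
    spec = spec or model_spec_from_sim(sim)
    split = make_split(sim.ped, list(sim.chip.animal_ids), split_spec)
    geno = sim.chip
    hinv = None
    results = {}
    for tag, excl in (("whole", None), ("reduced", split.test)):
        res = evaluate(sim.ped, geno, sim.phenotypes, spec, flavor=flavor,
                       panel_markers=panel_markers, weights=weights,
                       blend_beta=blend_beta, apy=apy,
                       exclude_phenotypes=excl, method=method, hinv=hinv)
        hinv = res.system.hinv
        results[tag] = res
    F = compute_inbreeding(sim.ped)
    val_codes = sim.ped.codes(split.test)
    f_bar = F.mean_over(val_codes)
    reports = {}
    for t, tm in enumerate(spec.traits):
        uw = results["whole"].gebv()[tm.name].to_numpy()[val_codes]
        ur = results["reduced"].gebv()[tm.name].to_numpy()[val_codes]
        reports[tm.name] = lr_statistics(
            uw, ur, f_bar, float(spec.additive_cov[t, t]))
    return LROutcome(reports=reports, split=split,
                     whole=results["whole"], reduced=results["reduced"])
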