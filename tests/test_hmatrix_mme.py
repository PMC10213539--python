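import numpy as np
import pandas as pd
import pytest

from conftest import make_pedigree
from mlgblup.genomic import GRM, build_G, blend_G
from mlgblup.groups import GroupAssignment, assign_groups, build_Astar, build_Q
from mlgblup.hmatrix import HMatrixError, build_hinv
from mlgblup.mme import (MMEError, ModelSpec, TraitModel, assemble_mme,
                         solve_mme)
from mlgblup.pedigree import (MISSING, build_A22, build_A_inverse,
                              compute_inbreeding)
from mlgblup.pipeline import evaluate, model_spec_from_sim
from oracles import random_pedigree


def standard_hinv(ped, codes=None, G=None):
    F = compute_inbreeding(ped).F
    codes = (ped.genotyped_codes if codes is None
             else np.asarray(codes, dtype=np.int64))
    ainv = build_A_inverse(ped, F)
    if len(codes) == 0:
        return build_hinv("standard", ped.n, codes, ainv=ainv,
                          ginv=np.zeros((0, 0)), a22inv=np.zeros((0, 0)))
    a22 = build_A22(ped, codes, F)
    a22i = np.linalg.inv(a22)
    gi = a22i if G is None else np.linalg.inv(G)
    return build_hinv("standard", ped.n, codes, ainv=ainv, ginv=gi,
                      a22inv=a22i)


class TestHInverseAssembly:
    def test_no_genotyped_standard_equals_ainv(self):
        rng = np.random.default_rng(0)
        sire, dam, _ = random_pedigree(40, rng)
        ped = make_pedigree(sire, dam)
        F = compute_inbreeding(ped).F
        ainv = build_A_inverse(ped, F)
        h = build_hinv("standard", ped.n, np.array([], dtype=np.int64),
                       ainv=ainv, ginv=np.zeros((0, 0)),
                       a22inv=np.zeros((0, 0)))
        np.testing.assert_allclose(h.to_dense(), ainv.toarray())

    @pytest.mark.parametrize("flavor", ["standard", "upg1", "upg2", "mf"])
    def test_symmetry_of_every_flavor(self, flavor, small_sim_single_trait):
        from mlgblup.pipeline import build_relationships
        sim = small_sim_single_trait
        h = build_relationships(sim.ped, sim.chip, flavor)
        M = h.to_dense()
        np.testing.assert_allclose(M, M.T, atol=1e-9)

    def test_upg1_group_block_is_Q_correction(self):
        rng = np.random.default_rng(1)
        sire, dam, lines = random_pedigree(60, rng, n_lines=2)
        ped = make_pedigree(sire, dam, lines,
                            genotyped=(np.arange(60) >= 40))
        codes = ped.genotyped_codes
        F = compute_inbreeding(ped).F
        a22 = build_A22(ped, codes, F)
        rng2 = np.random.default_rng(2)
        dos = rng2.integers(0, 3, size=(len(codes), 120)).astype(float)
        mm = pd.DataFrame({"marker": [f"m{i}" for i in range(120)],
                           "chrom": 1, "bp": np.arange(1, 121)})
        from mlgblup.genomic import GenotypeSet
        G = blend_G(build_G(GenotypeSet(dos, ped.animal_id[codes], mm)),
                    a22, 0.05)
        ginv = np.linalg.inv(G.values)
        a22i = np.linalg.inv(a22)
        pwg = assign_groups(ped, GroupAssignment.per_line(lines))
        Q = build_Q(pwg)
        astar = build_Astar(pwg, F)
        h = build_hinv("upg1", ped.n, codes, astar=astar, Q=Q, ginv=ginv,
                       a22inv=a22i, n_groups=pwg.n_groups)
        dense = h.to_dense()
        D = ginv - a22i
        Q2 = Q[codes]
        expected_gg = astar.toarray()[60:, 60:] + Q2.T @ D @ Q2
        np.testing.assert_allclose(dense[60:, 60:], expected_gg, atol=1e-10)
        expected_ag = astar.toarray()[codes, 60:] - D @ Q2
        np.testing.assert_allclose(dense[np.ix_(codes, range(60, 62))],
                                   expected_ag, atol=1e-10)

    def test_mf_flavor_rejects_observed_frequency_G(self):
        with pytest.raises(HMatrixError, match="0.5-centred"):
            build_hinv("mf", 5, np.arange(2), ginv=np.eye(2),
                       a22inv=np.eye(2), agamma_inv=np.eye(7),
                       g_freq_mode="observed")

    def test_unknown_flavor_rejected(self):
        with pytest.raises(HMatrixError):
            build_hinv("banana", 5, np.arange(2))


def phenotypes_for(ped, y, extra=None):
    df = pd.DataFrame({"animal": ped.animal_id, "mu": "all",
                       "trait": y})
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


class TestAssembleSolve:
    def test_hand_assembled_five_animal_oracle(self):
        # textbook single-trait animal model: 5 animals, overall mean,
        # animals 2..4 phenotyped, no litter
        ped = make_pedigree([MISSING, MISSING, 0, 0, 2],
                            [MISSING, MISSING, 1, 1, 3])
        y = np.array([np.nan, np.nan, 1.0, 2.0, 3.0])
        spec = ModelSpec(traits=[TraitModel("trait", fixed=("mu",))],
                         additive_cov=[[2.0]], resid_cov=[[4.0]],
                         litter_var=[1.0])
        data = phenotypes_for(ped, y).drop(columns=[])
        data["litter"] = [f"l{i}" for i in range(5)]
        h = standard_hinv(ped, codes=np.array([], dtype=np.int64))
        # with no genotyped animals H^{-1} = A^{-1}
        sysm = assemble_mme(spec, data.iloc[2:], h, ped)
        # oracle: dense normal equations X'X/s2e + litter and A^{-1} penalties
        Ainv = build_A_inverse(ped).toarray()
        X = np.zeros((3, 1 + 3 + 5))       # mu, litters l2..l4, animals
        X[:, 0] = 1.0
        for i in range(3):
            X[i, 1 + i] = 1.0          # litter levels of animals 2, 3, 4
            X[i, 4 + 2 + i] = 1.0      # animals 2, 3, 4
        lhs = X.T @ X / 4.0
        lhs[1:4, 1:4] += np.eye(3) / 1.0
        lhs[4:, 4:] += Ainv / 2.0
        rhs = X.T @ y[2:] / 4.0
        sol_oracle = np.linalg.solve(lhs, rhs)
        res = solve_mme(sysm, method="direct")
        np.testing.assert_allclose(res.u()[:, 0], sol_oracle[4:], atol=1e-8)
        np.testing.assert_allclose(res.fixed("trait").iloc[0], sol_oracle[0],
                                   atol=1e-8)

    def test_unphenotyped_animal_gets_parent_average(self):
        ped = make_pedigree([MISSING, MISSING, 0], [MISSING, MISSING, 1])
        y = np.array([1.0, 2.0, np.nan])
        spec = ModelSpec(traits=[TraitModel("trait", fixed=("mu",))],
                         additive_cov=[[1.0]], resid_cov=[[1.0]],
                         litter_var=[0.5])
        data = phenotypes_for(ped, y, extra={"litter": ["x", "y", "z"]})
        h = standard_hinv(ped, codes=np.array([], dtype=np.int64))
        res = solve_mme(assemble_mme(spec, data, h, ped))
        u = res.u()[:, 0]
        assert u[2] == pytest.approx(0.5 * (u[0] + u[1]), abs=1e-10)

    def test_two_uncorrelated_traits_equal_single_trait_runs(self):
        rng = np.random.default_rng(5)
        sire, dam, _ = random_pedigree(30, rng)
        ped = make_pedigree(sire, dam)
        y1 = rng.normal(size=30)
        y2 = rng.normal(size=30)
        y2[:15] = np.nan          # disjoint-ish recording
        y1[15:] = np.nan
        lit = [f"l{i % 6}" for i in range(30)]
        data = pd.DataFrame({"animal": ped.animal_id, "mu": "all",
                             "t1": y1, "t2": y2, "litter": lit})
        h = standard_hinv(ped, codes=np.array([], dtype=np.int64))
        spec2 = ModelSpec(
            traits=[TraitModel("t1", fixed=("mu",)),
                    TraitModel("t2", fixed=("mu",))],
            additive_cov=np.diag([0.5, 0.8]), resid_cov=np.diag([1.0, 1.2]),
            litter_var=[0.3, 0.4])
        both = solve_mme(assemble_mme(spec2, data, h, ped))
        for t, (name, s2u, s2e, s2c) in enumerate(
                [("t1", 0.5, 1.0, 0.3), ("t2", 0.8, 1.2, 0.4)]):
            spec1 = ModelSpec(traits=[TraitModel(name, fixed=("mu",))],
                              additive_cov=[[s2u]], resid_cov=[[s2e]],
                              litter_var=[s2c])
            single = solve_mme(assemble_mme(
                spec1, data[~data[name].isna()], h, ped))
            np.testing.assert_allclose(both.u()[:, t], single.u()[:, 0],
                                       atol=1e-8)

    def test_direct_and_pcg_agree(self, small_sim_single_trait):
        sim = small_sim_single_trait
        spec = model_spec_from_sim(sim)
        h = standard_hinv(sim.ped)
        sysm = assemble_mme(spec, sim.phenotypes, h, sim.ped)
        direct = solve_mme(sysm, method="direct")
        pcg = solve_mme(sysm, method="pcg", tol=1e-12)
        np.testing.assert_allclose(direct.u(), pcg.u(), atol=1e-6)

    def test_permuting_records_leaves_solutions(self, trio):
        y = np.array([1.0, 2.0, 1.5])
        spec = ModelSpec(traits=[TraitModel("trait", fixed=("mu",))],
                         additive_cov=[[1.0]], resid_cov=[[1.0]],
                         litter_var=[0.5])
        data = phenotypes_for(trio, y, extra={"litter": ["x", "y", "z"]})
        h = standard_hinv(trio, codes=np.array([], dtype=np.int64))
        a = solve_mme(assemble_mme(spec, data, h, trio))
        b = solve_mme(assemble_mme(spec, data.iloc[::-1], h, trio))
        np.testing.assert_allclose(a.u(), b.u(), atol=1e-10)

    def test_constant_shift_of_one_group_leaves_gebv(self):
        rng = np.random.default_rng(8)
        sire, dam, _ = random_pedigree(40, rng)
        ped = make_pedigree(sire, dam)
        y = rng.normal(size=40)
        cg = np.array(["g1"] * 20 + ["g2"] * 20, dtype=object)
        lit = [f"l{i % 8}" for i in range(40)]
        spec = ModelSpec(traits=[TraitModel("trait", fixed=("cg",))],
                         additive_cov=[[1.0]], resid_cov=[[1.0]],
                         litter_var=[0.5])
        h = standard_hinv(ped, codes=np.array([], dtype=np.int64))
        d1 = pd.DataFrame({"animal": ped.animal_id, "cg": cg, "trait": y,
                           "litter": lit})
        d2 = d1.copy()
        d2.loc[d2.cg == "g1", "trait"] += 7.5
        a = solve_mme(assemble_mme(spec, d1, h, ped))
        b = solve_mme(assemble_mme(spec, d2, h, ped))
        np.testing.assert_allclose(a.u(), b.u(), atol=1e-8)

    def test_scaling_equivariance(self, trio):
        y = np.array([1.0, 2.0, 1.5])
        h = standard_hinv(trio, codes=np.array([], dtype=np.int64))
        data = phenotypes_for(trio, y, extra={"litter": ["x", "y", "z"]})
        s1 = ModelSpec(traits=[TraitModel("trait", fixed=("mu",))],
                       additive_cov=[[0.4]], resid_cov=[[1.1]],
                       litter_var=[0.2])
        a = solve_mme(assemble_mme(s1, data, h, trio))
        k = 3.0
        data2 = data.copy(); data2["trait"] *= k
        s2 = ModelSpec(traits=[TraitModel("trait", fixed=("mu",))],
                       additive_cov=[[0.4 * k * k]],
                       resid_cov=[[1.1 * k * k]], litter_var=[0.2 * k * k])
        b = solve_mme(assemble_mme(s2, data2, h, trio))
        np.testing.assert_allclose(b.u(), k * a.u(), atol=1e-9)

    def test_non_pd_components_rejected(self):
        with pytest.raises(MMEError, match="positive definite"):
            ModelSpec(traits=[TraitModel("t")], additive_cov=[[0.0]],
                      resid_cov=[[1.0]], litter_var=[0.1])


class TestFlavorEquivalences:
    def test_ssgblup_with_G_equal_A22_reproduces_pedigree_blup(
            self, small_sim_single_trait):
        sim = small_sim_single_trait
        ped = sim.ped
        spec = model_spec_from_sim(sim)
        F = compute_inbreeding(ped).F
        codes = ped.genotyped_codes
        a22 = build_A22(ped, codes, F)
        h_ss = standard_hinv(ped, codes, G=a22)       # G := A22
        h_blup = standard_hinv(ped, codes=np.array([], dtype=np.int64))
        r_ss = solve_mme(assemble_mme(spec, sim.phenotypes, h_ss, ped))
        r_blup = solve_mme(assemble_mme(spec, sim.phenotypes, h_blup, ped))
        np.testing.assert_allclose(r_ss.gebv()["ADG"], r_blup.gebv()["ADG"],
                                   atol=1e-8)

    def test_upg1_with_G_equal_A22_reduces_to_grouped_pedigree_model(
            self, small_sim_single_trait):
        # with G = A22 the UPG1 correction blocks vanish entirely, so the
        # model is exactly the QP-transformed pedigree model (A* alone)
        sim = small_sim_single_trait
        ped = sim.ped
        spec = model_spec_from_sim(sim)
        F = compute_inbreeding(ped).F
        codes = ped.genotyped_codes
        a22 = build_A22(ped, codes, F)
        a22i = np.linalg.inv(a22)
        pwg = assign_groups(ped, GroupAssignment.per_line(list(ped.line)))
        Q = build_Q(pwg)
        astar = build_Astar(pwg, F)
        h1 = build_hinv("upg1", ped.n, codes, astar=astar, Q=Q,
                        ginv=a22i, a22inv=a22i, n_groups=pwg.n_groups)
        for r, c, M in h1.blocks:
            np.testing.assert_allclose(M, 0.0, atol=1e-10)
        np.testing.assert_allclose(h1.to_dense(), astar.toarray(),
                                   atol=1e-10)

    def test_upg2_group_coupling_present_even_when_G_equals_A22(
            self, small_sim_single_trait):
        # the printed UPG2 equation keeps -A22^{-1} Q couplings regardless
        # of G, so its blocks do not vanish at G = A22
        sim = small_sim_single_trait
        ped = sim.ped
        F = compute_inbreeding(ped).F
        codes = ped.genotyped_codes
        a22 = build_A22(ped, codes, F)
        a22i = np.linalg.inv(a22)
        pwg = assign_groups(ped, GroupAssignment.per_line(list(ped.line)))
        Q = build_Q(pwg)
        astar = build_Astar(pwg, F)
        h2 = build_hinv("upg2", ped.n, codes, astar=astar, Q=Q,
                        ginv=a22i, a22inv=a22i, n_groups=pwg.n_groups)
        dense = h2.to_dense()
        Q2 = Q[codes]
        grp = np.arange(ped.n, ped.n + pwg.n_groups)
        np.testing.assert_allclose(
            dense[np.ix_(codes, grp)],
            astar.toarray()[np.ix_(codes, grp)] - a22i @ Q2, atol=1e-10)
        np.testing.assert_allclose(
            dense[np.ix_(grp, grp)],
            astar.toarray()[np.ix_(grp, grp)] + Q2.T @ a22i @ Q2, atol=1e-10)

    def test_apy_duplicate_of_core_animal_gets_same_gebv(
            self, small_sim_single_trait):
        # a noncore animal genotypically identical to a core animal (and
        # otherwise symmetric) receives the same genomic information
        from mlgblup.genomic import APYPartition, GenotypeSet, apy_inverse
        sim = small_sim_single_trait
        ped = sim.ped
        codes = ped.genotyped_codes
        F = compute_inbreeding(ped).F
        a22 = build_A22(ped, codes, F)
        geno = sim.chip.subset_animals(
            [a for a in ped.animal_id[codes]])
        dup_pos = 0
        dos = geno.dosages.copy()
        dos[1] = dos[0]                       # duplicate animal 0 into 1
        G = blend_G(build_G(GenotypeSet(dos, geno.animal_ids,
                                        geno.marker_map)), a22, 0.05)
        core = np.array([geno.animal_ids[0]], dtype=object)
        rest = geno.animal_ids[1:]
        apy = apy_inverse(G, APYPartition(core=core, noncore=rest))
        # duplicate's noncore conditional mean weight is entirely on its twin
        assert apy.P_cn[0, 0] == pytest.approx(
            G.values[0, 1] / G.values[0, 0])
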