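import numpy as np
import pandas as pd
import pytest

from conftest import make_pedigree
from mlgblup.genomic import (APYPartition, GenomicError, GenotypeSet, GRM,
                             QCThresholds, allele_frequencies, apy_inverse,
                             blend_G, build_G, genotype_pca, qc_genotypes,
                             select_core, tune_G_to_A22)
from mlgblup.pedigree import MISSING, build_A22, compute_inbreeding


def gset(dosages, chrom=None, bp=None, ids=None):
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    mm = pd.DataFrame({
        "marker": [f"m{i}" for i in range(m)],
        "chrom": chrom if chrom is not None else np.ones(m, int),
        "bp": bp if bp is not None else np.arange(1, m + 1),
    })
    ids = ids if ids is not None else [f"a{i}" for i in range(n)]
    return GenotypeSet(dosages, np.array(ids, dtype=object), mm)


class TestQC:
    def test_low_maf_marker_removed_at_default_threshold(self):
        rng = np.random.default_rng(42)
        dos = rng.binomial(2, 0.4, size=(100, 2)).astype(float)
        dos[:, 0] = 0
        dos[0, 0] = 1        # MAF 0.005 < 0.01
        out, rep = qc_genotypes(gset(dos))
        assert rep.removed_maf == 1
        assert list(out.markers) == ["m1"]

    def test_all_heterozygote_marker_fails_het_deviation(self):
        dos = np.column_stack([np.ones(40), np.tile([0, 1, 2, 1], 10)])
        out, rep = qc_genotypes(gset(dos))
        # p = 0.5 but observed het 1.0 vs expected 0.5 => removed
        assert rep.removed_het_deviation == 1
        assert list(out.markers) == ["m1"]

    def test_constructed_failures_leave_survivors(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.4, size=(60, 10)).astype(float)
        dos[:, 1] = 2.0                      # monomorphic
        dos[: 50, 2] = np.nan                # call rate 10/60 < 0.9
        dos[:, 3] = 0.0
        dos[0, 3] = 1.0                      # MAF 1/120 < 0.01
        out, rep = qc_genotypes(gset(dos))
        assert rep.removed_monomorphic == 1
        assert rep.removed_call_rate == 1
        assert rep.removed_maf == 1
        assert out.n_markers == 7

    def test_animal_with_excess_missingness_removed(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(30, 20)).astype(float)
        dos[0, :5] = np.nan                  # 25% missing
        out, rep = qc_genotypes(gset(dos))
        assert rep.removed_animals_missing == 1
        assert "a0" not in out.animal_ids

    def test_parent_progeny_conflict_removed(self):
        rng = np.random.default_rng(2)
        n_bg = 40
        dos = rng.binomial(2, 0.5, size=(n_bg + 2, 50)).astype(float)
        parent = dos[0]
        # animal 1 is recorded as offspring of animal 0 but carries the
        # opposite homozygote wherever the parent is homozygous
        dos[1] = np.where(parent == 1, 1.0, 2.0 - parent)
        ped = make_pedigree(
            [MISSING, 0] + [MISSING] * n_bg,
            [MISSING] * (n_bg + 2),
            genotyped=[True] * (n_bg + 2))
        out, rep = qc_genotypes(gset(dos), ped=ped)
        assert rep.removed_parent_conflict == 1
        assert "a1" not in out.animal_ids

    def test_wgs_thresholds_use_sequence_maf_floor(self):
        assert QCThresholds.wgs().min_maf == pytest.approx(0.023)

    def test_empty_output_is_error(self):
        with pytest.raises(GenomicError):
            qc_genotypes(gset(np.full((5, 2), 2.0)))


class TestAlleleFrequencies:
    def test_simple_mean_dosage(self):
        g = gset([[0.0], [1.0], [2.0]])
        assert allele_frequencies(g)[0] == pytest.approx(0.5)

    def test_fixed_marker_boundary(self):
        g = gset([[2.0], [2.0]])
        assert allele_frequencies(g)[0] == pytest.approx(1.0)

    def test_matches_counting_with_missing(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(50, 8)).astype(float)
        dos[rng.random(dos.shape) < 0.1] = np.nan
        p = allele_frequencies(gset(dos))
        for j in range(8):
            col = dos[:, j]
            obs = col[~np.isnan(col)]
            assert p[j] == pytest.approx(obs.sum() / (2 * len(obs)))


class TestBuildG:
    def test_two_animal_direct_evaluation(self):
        G = build_G(gset([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_identical_animals_have_equal_rows(self):
        rng = np.random.default_rng(4)
        row = rng.integers(0, 3, size=12).astype(float)
        dos = np.vstack([row, row, rng.integers(0, 3, size=12)])
        G = build_G(gset(dos)).values
        np.testing.assert_allclose(G[0], G[1])
        assert G[0, 0] == pytest.approx(G[1, 1])

    def test_identity_weights_match_unweighted(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, size=(20, 30)).astype(float)
        g = gset(dos)
        np.testing.assert_allclose(build_G(g).values,
                                   build_G(g, weights=np.ones(30)).values)

    def test_half_mode_invariant_to_allele_swap(self):
        rng = np.random.default_rng(6)
        dos = rng.integers(0, 3, size=(15, 25)).astype(float)
        g1 = build_G(gset(dos), freq_mode="half").values
        g2 = build_G(gset(2.0 - dos), freq_mode="half").values
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_mean_diagonal_tracks_inbreeding(self, small_sim):
        sim = small_sim
        G = build_G(sim.chip).values
        F = compute_inbreeding(sim.ped).F
        codes = sim.ped.genotyped_codes
        assert abs(G.diagonal().mean() - (1.0 + F[codes].mean())) < 0.05

    def test_all_fixed_markers_error(self):
        with pytest.raises(GenomicError, match="denominator"):
            build_G(gset(np.full((4, 3), 2.0)))


class TestBlendAndTune:
    def test_beta_zero_leaves_G(self):
        rng = np.random.default_rng(7)
        dos = rng.integers(0, 3, size=(10, 40)).astype(float)
        G = build_G(gset(dos))
        np.testing.assert_allclose(blend_G(G, np.eye(10), 0.0).values,
                                   G.values)

    def test_blending_G_equal_A22_is_fixed_point(self):
        A22 = np.eye(6) + 0.1
        G = GRM(values=A22.copy(), animal_ids=np.arange(6))
        np.testing.assert_allclose(blend_G(G, A22, 0.05).values, A22)

    def test_blending_raises_smallest_eigenvalue(self, small_sim):
        sim = small_sim
        sub = sim.chip.subset_animals(np.arange(30))
        G = build_G(sub)
        codes = sim.ped.codes(sub.animal_ids)
        A22 = build_A22(sim.ped, codes)
        lo = np.linalg.eigvalsh(G.values)[0]
        hi = np.linalg.eigvalsh(blend_G(G, A22, 0.05).values)[0]
        assert hi > lo
        assert hi > 0

    def test_tuning_matches_means_to_A22(self):
        rng = np.random.default_rng(8)
        dos = rng.integers(0, 3, size=(25, 60)).astype(float)
        G = build_G(gset(dos))
        A22 = np.eye(25) * 1.02 + 0.04
        Gt = tune_G_to_A22(G, A22).values
        n = 25
        assert Gt.diagonal().mean() == pytest.approx(A22.diagonal().mean())
        offd = (Gt.sum() - Gt.diagonal().sum()) / (n * n - n)
        offa = (A22.sum() - A22.diagonal().sum()) / (n * n - n)
        assert offd == pytest.approx(offa)

    def test_dimension_mismatch(self):
        G = GRM(values=np.eye(3), animal_ids=np.arange(3))
        with pytest.raises(GenomicError):
            blend_G(G, np.eye(4))


class TestAPY:
    def make_blended(self, n=60, m=200, seed=9):
        rng = np.random.default_rng(seed)
        dos = rng.integers(0, 3, size=(n, m)).astype(float)
        G = build_G(gset(dos))
        return blend_G(G, np.eye(n), 0.05)

    def test_threshold_one_full_rank_uses_all(self):
        Gb = self.make_blended(30, 100)
        part = select_core(Gb, np.array(["L1"] * 30, dtype=object),
                           var_threshold=1.0)
        assert part.n_core == 30

    def test_rank_forced_core_size(self):
        # three distinct genotype vectors replicated: centred G has rank 2,
        # so 98% of the eigenvalue mass needs exactly two core animals
        base = np.array([[0.0, 2.0, 0.0, 2.0, 1.0, 1.0],
                         [2.0, 2.0, 0.0, 0.0, 0.0, 2.0],
                         [1.0, 0.0, 2.0, 1.0, 2.0, 0.0]])
        dos = np.vstack([base, base])
        G = build_G(gset(dos))
        assert np.linalg.matrix_rank(G.values) == 2
        part = select_core(G, np.array(["L1"] * 6, dtype=object),
                           var_threshold=0.98, seed=1)
        assert part.n_core == 2

    def test_core_counts_follow_line_proportions(self):
        Gb = self.make_blended(100, 300)
        lines = np.array(["L1"] * 30 + ["L2"] * 20 + ["L3"] * 50, dtype=object)
        part = select_core(Gb, lines, var_threshold=0.98,
                           proportions={"L1": 0.3, "L2": 0.2, "L3": 0.5},
                           seed=3)
        n_core = part.n_core
        core_set = set(part.core)
        counts = {ln: 0 for ln in ("L1", "L2", "L3")}
        for i, aid in enumerate([f"a{i}" for i in range(100)]):
            if aid in core_set:
                counts[lines[i]] += 1
        assert counts["L1"] == round(n_core * 0.3)
        assert counts["L2"] == round(n_core * 0.2)
        assert counts["L3"] == round(n_core * 0.5)

    def test_all_core_equals_dense_inverse(self):
        Gb = self.make_blended(40, 150)
        part = APYPartition(core=Gb.animal_ids, noncore=np.array([], object))
        apy = apy_inverse(Gb, part)
        np.testing.assert_allclose(apy.dense(), np.linalg.inv(Gb.values),
                                   atol=1e-10)

    def test_matvec_matches_dense(self):
        Gb = self.make_blended(50, 150, seed=10)
        rng = np.random.default_rng(0)
        core = rng.choice(Gb.animal_ids, 20, replace=False)
        noncore = np.array([a for a in Gb.animal_ids if a not in set(core)],
                           dtype=object)
        apy = apy_inverse(Gb, APYPartition(core=core, noncore=noncore))
        x = rng.standard_normal(50)
        np.testing.assert_allclose(apy.matvec(x), apy.dense() @ x, atol=1e-10)

    def test_agreement_degrades_as_core_shrinks(self):
        Gb = self.make_blended(80, 100, seed=11)
        dense = np.linalg.inv(Gb.values)
        rng = np.random.default_rng(1)
        errs = []
        for k in (70, 40, 15):
            core = rng.choice(Gb.animal_ids, k, replace=False)
            noncore = np.array(
                [a for a in Gb.animal_ids if a not in set(core)], object)
            apy = apy_inverse(Gb, APYPartition(core=core, noncore=noncore))
            errs.append(np.linalg.norm(apy.dense() - dense))
        assert errs[0] < errs[1] < errs[2]

    def test_singular_core_suggests_blending(self):
        dos = np.tile([[0.0, 2.0], [0.0, 2.0], [2.0, 0.0]], (1, 5))
        G = build_G(gset(dos))
        part = APYPartition(core=np.array(["a0", "a1"], object),
                            noncore=np.array(["a2"], object))
        with pytest.raises(GenomicError, match="blend"):
            apy_inverse(G, part)


class TestPCA:
    def test_lines_separate_on_pc1(self, small_sim):
        sim = small_sim
        pure = np.array([ln != "CL" for ln in
                         [sim.ped.line[sim.ped.code(a)]
                          for a in sim.chip.animal_ids]])
        sub = sim.chip.subset_animals(np.flatnonzero(pure))
        scores, shares = genotype_pca(sub, k=2)
        lines = np.array([sim.ped.line[sim.ped.code(a)]
                          for a in sub.animal_ids])
        # PC1+PC2 separate at least one line pair with zero overlap
        separated = 0
        for ln in ("TL1", "TL2", "TL3"):
            inside = scores[lines == ln, 0]
            outside = scores[lines != ln, 0]
            if inside.max() < outside.min() or inside.min() > outside.max():
                separated += 1
        assert separated >= 1
        assert shares.sum() <= 1.0 + 1e-12

    def test_identical_animals_zero_variance(self):
        dos = np.tile(np.array([0.0, 1.0, 2.0, 1.0]), (5, 1))
        scores, shares = genotype_pca(gset(dos), k=2)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)
        np.testing.assert_allclose(shares, 0.0)

    def test_k_beyond_rank_errors(self):
        rng = np.random.default_rng(12)
        dos = rng.integers(0, 3, size=(3, 10)).astype(float)
        with pytest.raises(GenomicError):
            genotype_pca(gset(dos), k=3)   # rank <= 2 after centring
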