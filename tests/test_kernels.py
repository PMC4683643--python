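import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonalgp import (
    GenotypeMatrix,
    build_A_pedigree,
    build_D_pedigree,
    build_Ga,
    build_Gaa,
    build_Gd,
    condition_kernel,
    pca_genotypes,
    relatedness_summary,
)
from clonalgp.datatypes import PedigreeTable, RelationshipMatrix

from conftest import random_genotypes


class TestAdditiveKernel:
    def test_single_snp_hand_computation(self, toy_geno):
        # p = 0.5 so M = (-1, 0, 1)', sum 2pq = 0.5
        G = build_Ga(toy_geno)
        assert np.allclose(G.values, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]])

    def test_all_heterozygous_centred_codings_vanish(self):
        g = GenotypeMatrix(["a", "b"], ["s1", "s2"], np.ones((2, 2)))
        assert np.allclose(build_Ga(g).values, 0.0)

    def test_monomorphic_panel_rejected(self):
        g = GenotypeMatrix(["a", "b"], ["s"], np.array([[2.0], [2.0]]))
        with pytest.raises(ValueError, match="monomorphic"):
            build_Ga(g)

    def test_clone_rows_give_offdiagonal_equal_diagonal(self):
        rng = np.random.default_rng(3)
        g = random_genotypes(rng, 6, 40)
        dos = g.dosages.copy()
        dos[1] = dos[0]  # clone pair
        g2 = GenotypeMatrix(g.individual_ids, g.snp_ids, dos)
        G = build_Ga(g2).values
        assert G[0, 1] == pytest.approx(G[0, 0])
        assert G[0, 1] == pytest.approx(G[1, 1])


class TestDominanceKernel:
    def test_single_snp_hand_computation(self):
        # AA, AB with p fixed at 0.5: H = (-0.5, 0.5)', denominator 0.25
        g = GenotypeMatrix(["a", "b"], ["s"], np.array([[0.0], [1.0]]))
        Gd = build_Gd(g, freqs=np.array([0.5]))
        assert np.allclose(Gd.values, [[1, -1], [-1, 1]])

    def test_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(7)
        g = random_genotypes(rng, 200, 3000)
        Gd = build_Gd(g)
        assert np.mean(np.diag(Gd.values)) == pytest.approx(1.0, abs=0.05)


class TestEpistaticKernel:
    def test_elementwise_square(self, toy_geno):
        Ga = build_Ga(toy_geno)
        Gaa = build_Gaa(Ga)
        assert np.allclose(Gaa.values, Ga.values**2)
        assert np.allclose(np.diag(Gaa.values), np.diag(Ga.values) ** 2)

    def test_kind_mismatch_rejected(self):
        K = RelationshipMatrix(["a"], np.eye(1), "dominance_genomic")
        with pytest.raises(ValueError, match="additive_genomic"):
            build_Gaa(K)

    def test_schur_product_preserves_psd(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            g = random_genotypes(rng, 15, 30)
            Gaa = build_Gaa(build_Ga(g))
            assert np.linalg.eigvalsh(Gaa.values)[0] >= -1e-8


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.95))
def test_allele_labeling_invariance(seed, flip_frac):
    """Flipping which allele is counted at any subset of SNPs leaves every
    genomic kernel unchanged (dosage x -> 2 - x)."""
    rng = np.random.default_rng(seed)
    g = random_genotypes(rng, 8, 25)
    flip = rng.random(g.n_snps) < flip_frac
    dos = g.dosages.copy()
    dos[:, flip] = 2.0 - dos[:, flip]
    g2 = GenotypeMatrix(g.individual_ids, g.snp_ids, dos)
    assert np.allclose(build_Ga(g).values, build_Ga(g2).values, atol=1e-10)
    assert np.allclose(build_Gd(g).values, build_Gd(g2).values, atol=1e-10)
    assert np.allclose(
        build_Gaa(build_Ga(g)).values, build_Gaa(build_Ga(g2)).values, atol=1e-10
    )


class TestPedigreeKernels:
    def test_full_sibs_textbook_values(self):
        ped = PedigreeTable.from_records(
            [("p1", None, None), ("p2", None, None), ("c1", "p1", "p2"), ("c2", "p1", "p2")]
        )
        A = build_A_pedigree(ped)
        i, j = A.ids.index("c1"), A.ids.index("c2")
        assert A.values[i, j] == pytest.approx(0.5)
        D = build_D_pedigree(ped, A)
        assert D.values[i, j] == pytest.approx(0.25)
        assert np.allclose(np.diag(D.values), 1.0)

    def test_founder_only_pedigree_is_identity(self):
        ped = PedigreeTable([f"f{k}" for k in range(4)], [None] * 4, [None] * 4)
        assert np.allclose(build_A_pedigree(ped).values, np.eye(4))

    def test_parent_offspring_half(self):
        ped = PedigreeTable.from_records([("p", None, None), ("q", None, None), ("c", "p", "q")])
        A = build_A_pedigree(ped)
        assert A.values[A.ids.index("p"), A.ids.index("c")] == pytest.approx(0.5)


class TestConditioning:
    def test_psd_input_unchanged(self):
        K = RelationshipMatrix(["a", "b"], np.eye(2), "additive_genomic")
        out = condition_kernel(K)
        assert out is K and not out.bending_applied

    def test_indefinite_input_bent_to_psd(self):
        vals = np.array([[1.0, 0.999, 0.0], [0.999, 1.0, 0.999], [0.0, 0.999, 1.0]])
        vals = vals - 0.6 * np.eye(3)  # force a negative eigenvalue
        K = RelationshipMatrix(["a", "b", "c"], vals, "additive_genomic")
        assert np.linalg.eigvalsh(vals)[0] < 0
        out = condition_kernel(K)
        assert out.bending_applied
        assert np.linalg.eigvalsh(out.values)[0] >= 0


def test_kernel_csv_roundtrip(tmp_path):
    from clonalgp.kernels import read_kernel, write_kernel

    rng = np.random.default_rng(5)
    G = build_Ga(random_genotypes(rng, 5, 30))
    write_kernel(G, tmp_path / "k.csv")
    back = read_kernel(tmp_path / "k.csv")
    assert back.ids == G.ids
    assert back.kind == "additive_genomic"
    assert np.allclose(back.values, G.values)


class TestSummaries:
    def test_identity_kernel_zero_mean_offdiagonal(self):
        K = RelationshipMatrix(["a", "b", "c"], np.eye(3), "additive_genomic")
        s = relatedness_summary(K)
        assert s.mean_off_diagonal == 0.0

    def test_within_family_exceeds_between(self, small_sim, small_sim_kernels):
        s = relatedness_summary(small_sim_kernels["a"], families=small_sim.families)
        within = s.within_family.mean()
        between = np.nanmean(s.between_family.to_numpy())
        assert within > between

    def test_pca_shapes_and_variance_fractions(self, small_sim):
        coords, explained = pca_genotypes(small_sim.offspring, n_components=4)
        assert coords.shape == (small_sim.offspring.n_individuals, 4)
        assert np.all(np.diff(explained) <= 1e-12)
        assert 0 < explained.sum() <= 1.0 + 1e-9


def test_genomic_tracks_pedigree_relatedness(study_sim):
    """Without pedigree errors, realized SNP relationships track the pedigree
    expectation: strongly correlated pair by pair, and within-family means
    agreeing after the sample-frequency scale of G_a is calibrated onto the
    pedigree scale (sample centring makes raw G_a off-diagonals average ~0,
    so location/scale must be matched before comparison)."""
    A = build_A_pedigree(study_sim.pedigree).subset(study_sim.offspring.individual_ids)
    Ga = build_Ga(study_sim.offspring)
    fams = study_sim.families
    off_a, off_p = Ga.off_diagonal(), A.off_diagonal()
    assert np.corrcoef(off_a, off_p)[0, 1] > 0.85
    # full sibs: pedigree expectation >= 0.5 once parents are related
    sp = relatedness_summary(A, families=fams)
    assert (sp.within_family >= 0.5 - 1e-9).all()
    beta, alpha = np.polyfit(off_a, off_p, 1)
    cal = RelationshipMatrix(Ga.ids, alpha + beta * Ga.values, "additive_genomic")
    sa = relatedness_summary(cal, families=fams)
    assert (sa.within_family - sp.within_family).abs().mean() < 0.1
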