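import numpy as np
import pytest

from opgblup.kernels import (
    AlleleFrequencyVector,
    ConfigurationError,
    GenotypeMatrix,
    PedigreeError,
    PedigreeTable,
    RelationshipKernel,
    build_additive_kernel,
    build_dominance_kernel,
    build_numerator_relationship,
    compute_allele_frequencies,
    hadamard,
    relationship_summaries,
    stabilize,
)
from conftest import random_pedigree


def gm(dosages, ids=None, loci=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        ids or [f"s{i}" for i in range(n)],
        loci or [f"l{j}" for j in range(m)],
        dosages,
    )


TOY = gm([[0.0], [1.0], [2.0]])
TOY_F = AlleleFrequencyVector(["l0"], [0.5])


class TestAlleleFrequencies:
    def test_simple_column(self):
        f, kept = compute_allele_frequencies(gm([[0], [1], [2], [1]]))
        assert f.p[0] == pytest.approx(0.5)
        assert list(kept) == [0]

    def test_missing_excluded_from_denominator(self):
        f, _ = compute_allele_frequencies(gm([[2], [2], [np.nan], [0]]))
        assert f.p[0] == pytest.approx(4 / 6)

    def test_monomorphic_dropped(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            f, kept = compute_allele_frequencies(gm([[0, 1], [0, 1], [0, 2], [0, 0]]))
        assert list(kept) == [1]

    def test_all_dropped_is_error(self):
        with pytest.raises(ConfigurationError):
            compute_allele_frequencies(gm([[0], [0], [0]]))

    def test_external_frequencies_used(self):
        f, _ = compute_allele_frequencies(gm([[0], [0], [1]]), external={"l0": 0.3})
        assert f.p[0] == pytest.approx(0.3)


class TestAdditiveKernel:
    def test_hand_evaluated_single_locus(self):
        G = build_additive_kernel(TOY, TOY_F)
        expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        np.testing.assert_allclose(G.matrix, expected, atol=1e-12)

    def test_duplicate_genotypes_give_identical_rows(self):
        g = gm([[0, 2, 1], [0, 2, 1], [2, 0, 1]])
        f, _ = compute_allele_frequencies(g)
        G = build_additive_kernel(g, f)
        np.testing.assert_allclose(G.matrix[0], G.matrix[1])
        assert G.matrix[0, 1] == pytest.approx(G.matrix[0, 0])

    def test_hwe_panel_centering_and_scale(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.5, 800)
        g = gm(rng.binomial(2, p, size=(500, 800)))
        f = AlleleFrequencyVector(g.locus_ids, p)
        G = build_additive_kernel(g, f)
        assert np.mean(np.diag(G.matrix)) == pytest.approx(1.0, abs=0.02)
        # centering: row means near zero
        assert np.abs(G.matrix.mean(axis=1)).max() < 0.05

    def test_missing_mean_imputed(self):
        g = gm([[0.0], [np.nan], [2.0]])
        G = build_additive_kernel(g, TOY_F)
        assert G.matrix[1, 1] == pytest.approx(0.0)


class TestDominanceKernel:
    def test_hand_evaluated_classical(self):
        G = build_dominance_kernel(TOY, TOY_F, "classical")
        expected = np.array([[1.0, -1, 1], [-1, 1, -1], [1, -1, 1]])
        np.testing.assert_allclose(G.matrix, expected, atol=1e-12)

    def test_hand_evaluated_genotypic(self):
        G = build_dominance_kernel(TOY, TOY_F, "genotypic")
        expected = np.array([[1.0, -1, 1], [-1, 1, -1], [1, -1, 1]])
        np.testing.assert_allclose(G.matrix, expected, atol=1e-12)
        assert G.label == "G_dom_geno"

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_classical_coding_zero_mean_under_hwe(self, p):
        q = 1 - p
        expectation = p**2 * (-2 * q**2) + 2 * p * q * (2 * p * q) + q**2 * (-2 * p**2)
        assert expectation == pytest.approx(0.0, abs=1e-15)

    def test_additive_dominance_orthogonality_under_hwe(self):
        # covariance of the Z and W codings at one locus shrinks with n
        rng = np.random.default_rng(3)
        p = 0.3
        covs = []
        for n in (200, 20000):
            m = rng.binomial(2, p, n).astype(float)
            z = m - 2 * p
            w = np.where(m == 0, -2 * p**2, np.where(m == 1, 2 * p * (1 - p), -2 * (1 - p) ** 2))
            covs.append(abs(np.cov(z, w)[0, 1]))
        assert covs[1] < covs[0]
        assert covs[1] < 0.01

    def test_unknown_parameterization(self):
        with pytest.raises(ConfigurationError):
            build_dominance_kernel(TOY, TOY_F, "bogus")


class TestHadamard:
    def test_entrywise_square(self):
        k = RelationshipKernel("G_add", ["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        out = hadamard(k, k)
        np.testing.assert_allclose(out.matrix, [[1.0, 0.25], [0.25, 1.0]])
        assert out.label == "AxA"

    def test_identity_extracts_diagonal(self):
        k = RelationshipKernel("G_add", ["a", "b"], [[1.2, 0.5], [0.5, 0.8]])
        eye = RelationshipKernel("identity", ["a", "b"], np.eye(2))
        out = hadamard(k, eye)
        np.testing.assert_allclose(out.matrix, np.diag([1.2, 0.8]))

    def test_toy_add_times_dom(self):
        ga = build_additive_kernel(TOY, TOY_F)
        gd = build_dominance_kernel(TOY, TOY_F)
        out = hadamard(ga, gd)
        np.testing.assert_allclose(out.matrix, ga.matrix * gd.matrix)
        assert out.label == "AxD"
        assert out.matrix[0, 2] == pytest.approx((-2.0) * 1.0)

    def test_mismatched_samples_rejected(self):
        k1 = RelationshipKernel("G_add", ["a", "b"], np.eye(2))
        k2 = RelationshipKernel("G_add", ["a", "c"], np.eye(2))
        with pytest.raises(ValueError):
            hadamard(k1, k2)

    def test_schur_product_preserves_psd(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            L1 = rng.normal(size=(6, 6))
            L2 = rng.normal(size=(6, 6))
            ids = [f"s{i}" for i in range(6)]
            k1 = RelationshipKernel("G_add", ids, L1 @ L1.T)
            k2 = RelationshipKernel("G_dom", ids, L2 @ L2.T)
            eig = np.linalg.eigvalsh(hadamard(k1, k2).matrix)
            assert eig.min() > -1e-8


class TestStabilize:
    def test_epsilon_zero_is_identity_operation(self):
        k = RelationshipKernel("G_add", ["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(stabilize(k, 0.0).matrix, k.matrix)

    def test_epsilon_one_gives_identity(self):
        k = RelationshipKernel("G_add", ["a", "b"], [[1.0, 0.9], [0.9, 1.0]])
        np.testing.assert_allclose(stabilize(k, 1.0).matrix, np.eye(2))

    def test_rank_one_kernel_becomes_pd(self):
        G = build_additive_kernel(TOY, TOY_F)  # rank 1
        out = stabilize(G, 0.01)
        assert np.linalg.eigvalsh(out.matrix).min() > 0
        assert out.meta["stabilize_epsilon"] == 0.01

    def test_invalid_epsilon(self):
        k = RelationshipKernel("G_add", ["a"], [[1.0]])
        with pytest.raises(ConfigurationError):
            stabilize(k, 1.5)


class TestNumeratorRelationship:
    def test_maternal_half_sibs(self):
        ped = PedigreeTable([("dam", None, None), ("o1", "dam", None), ("o2", "dam", None)])
        A = build_numerator_relationship(ped)
        assert A.matrix[1, 2] == pytest.approx(0.25)
        assert A.matrix[1, 1] == pytest.approx(1.0)  # unknown sire: no inbreeding

    def test_parent_offspring_and_founder_diagonal(self):
        ped = PedigreeTable([("f", None, None), ("o", "f", None)])
        A = build_numerator_relationship(ped)
        assert A.matrix[0, 0] == pytest.approx(1.0)
        assert A.matrix[0, 1] == pytest.approx(0.5)

    def test_full_sibs_and_selfing_inbreeding(self):
        ped = PedigreeTable(
            [("d", None, None), ("s", None, None), ("o1", "d", "s"), ("o2", "d", "s"), ("x", "d", "d")]
        )
        A = build_numerator_relationship(ped)
        assert A.matrix[2, 3] == pytest.approx(0.5)
        # selfed offspring: inbreeding = 0.5
        assert A.matrix[4, 4] == pytest.approx(1.5)

    def test_unordered_pedigree_rejected(self):
        with pytest.raises(PedigreeError, match="not listed earlier"):
            PedigreeTable([("o", "dam", None), ("dam", None, None)])

    def test_self_parent_rejected(self):
        with pytest.raises(PedigreeError):
            PedigreeTable([("a", None, None), ("b", "b", None)])

    def test_tabular_equals_twice_recursive_coancestry(self):
        def kinship(ped, order, a, b, cache):
            if a is None or b is None:
                return 0.0
            key = (a, b) if order[a] >= order[b] else (b, a)
            if key in cache:
                return cache[key]
            x, y = key
            dx, sx = ped[x]
            if x == y:
                val = 0.5 * (1.0 + kinship(ped, order, dx, sx, cache))
            else:
                val = 0.5 * (
                    kinship(ped, order, dx, y, cache) + kinship(ped, order, sx, y, cache)
                )
            cache[key] = val
            return val

        rng = np.random.default_rng(17)
        for _ in range(20):
            rows = random_pedigree(rng, n=12)
            A = build_numerator_relationship(PedigreeTable(rows)).matrix
            ped = {r[0]: (r[1], r[2]) for r in rows}
            order = {r[0]: i for i, r in enumerate(rows)}
            cache = {}
            ids = [r[0] for r in rows]
            expected = np.array(
                [[2.0 * kinship(ped, order, a, b, cache) for b in ids] for a in ids]
            )
            np.testing.assert_allclose(A, expected, atol=1e-12)


class TestSummaries:
    def test_half_sib_families_cluster_at_expectations(self, clean_sim):
        from opgblup.kernels import build_additive_kernel, compute_allele_frequencies

        f, _ = compute_allele_frequencies(
            clean_sim.genotypes, external=clean_sim.founder_frequencies
        )
        G = build_additive_kernel(clean_sim.genotypes, f)
        fam = dict(
            zip(clean_sim.phenotypes["id"], clean_sim.phenotypes["family"])
        )
        s = relationship_summaries(G, fam)
        within = s.within.set_index("scope")
        assert within.loc["within", "mean"] == pytest.approx(0.25, abs=0.03)
        assert within.loc["among", "mean"] == pytest.approx(0.0, abs=0.02)
        assert s.histogram["within_count"].sum() == len(s.within_values)

    def test_single_family_has_no_among_pairs(self):
        k = RelationshipKernel("G_add", ["a", "b"], np.eye(2))
        s = relationship_summaries(k, {"a": "f1", "b": "f1"})
        assert s.among_values.size == 0

    def test_singleton_families_flagged(self):
        k = RelationshipKernel("G_add", ["a", "b"], np.eye(2))
        s = relationship_summaries(k, {"a": "f1", "b": "f2"})
        assert s.within_values.size == 0
        assert s.flags
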