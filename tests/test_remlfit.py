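import numpy as np
import pandas as pd
import pytest

from opgblup.kernels import (
    AlleleFrequencyVector,
    GenotypeMatrix,
    build_additive_kernel,
)
from opgblup.remlfit import (
    FitError,
    FitOptions,
    MixedModelSpec,
    RandomTerm,
    aic,
    fit,
    heritability,
    heritability_from_components,
    model_ladder,
    model_spec,
    sampling_correlation_diagnostic,
    variance_proportions,
    variance_proportions_from_components,
)


def one_way_layout(s=25, n=8, var_f=2.0, var_e=5.0, seed=2):
    rng = np.random.default_rng(seed)
    y = (rng.normal(0, np.sqrt(var_f), s)[:, None] + rng.normal(0, np.sqrt(var_e), (s, n))).ravel()
    phen = pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(s * n)],
            "family": np.repeat([f"f{j:02d}" for j in range(s)], n),
            "block": "B1",
            "y": y,
        }
    )
    return phen, y.reshape(s, n)


class TestFit:
    def test_balanced_one_way_matches_anova_closed_form(self):
        phen, ymat = one_way_layout()
        spec = MixedModelSpec("y", [RandomTerm("family", factor="family")])
        fit_ = fit(spec, phen)
        s, n = ymat.shape
        msb = n * np.var(ymat.mean(axis=1), ddof=1)
        msw = np.mean(np.var(ymat, axis=1, ddof=1))
        assert fit_.converged
        assert fit_.estimates["family"] == pytest.approx((msb - msw) / n, rel=1e-5)
        assert fit_.estimates["residual"] == pytest.approx(msw, rel=1e-5)

    def test_constant_response_pins_nonresidual_components(self):
        phen, _ = one_way_layout(s=6, n=4)
        phen["y"] = 3.0
        spec = MixedModelSpec("y", [RandomTerm("family", factor="family")])
        fit_ = fit(spec, phen)
        assert "family" in fit_.pinned
        assert fit_.estimates["family"] < 1e-8
        assert np.isnan(fit_.se["family"])

    def test_gblup_equals_snp_blup_ridge_on_random_instances(self):
        # GBLUP at a fixed variance ratio must equal ridge regression on
        # the centered markers with penalty (2*sum(pq)) * s2e / s2a
        rng = np.random.default_rng(9)
        for _ in range(5):
            ni, m = rng.integers(8, 15), rng.integers(15, 30)
            M = rng.binomial(2, rng.uniform(0.2, 0.8, m), (ni, m)).astype(float)
            p = M.mean(axis=0) / 2
            keep = (p > 0) & (p < 1)
            M = M[:, keep]
            p = p[keep]
            ids = [f"s{i}" for i in range(ni)]
            loci = [f"l{j}" for j in range(int(keep.sum()))]
            G = build_additive_kernel(
                GenotypeMatrix(ids, loci, M), AlleleFrequencyVector(loci, p)
            )
            y = rng.normal(10, 2, ni)
            phen = pd.DataFrame({"id": ids, "family": "f", "block": "b", "y": y})
            s2a, s2e = 1.4, 2.3
            fit_ = fit(
                MixedModelSpec("y", [RandomTerm("additive", kernel="G_add")]),
                phen,
                {"G_add": G},
                FitOptions(fixed_variances={"additive": s2a, "residual": s2e}),
            )
            V = s2a * G.matrix + s2e * np.eye(ni)
            Vi = np.linalg.inv(V)
            one = np.ones(ni)
            mu = (one @ Vi @ y) / (one @ Vi @ one)
            Z = M - 2 * p
            lam = G.meta["denominator"] * s2e / s2a
            ahat = np.linalg.solve(Z.T @ Z + lam * np.eye(Z.shape[1]), Z.T @ (y - mu))
            np.testing.assert_allclose(fit_.ebv.to_numpy(), Z @ ahat, atol=1e-9)

    def test_likelihood_nondecreasing_with_nested_terms(self, clean_sim, clean_kernels):
        from opgblup.kernels import build_dominance_kernel, compute_allele_frequencies, hadamard

        freqs, _ = compute_allele_frequencies(clean_sim.genotypes)
        G_dom = build_dominance_kernel(clean_sim.genotypes, freqs)
        kernels = dict(clean_kernels, G_dom=G_dom)
        fits = model_ladder(
            clean_sim.phenotypes, "trait", kernels, models=["GBLUP-A", "GBLUP-AD"]
        )
        assert fits["GBLUP-AD"].loglik >= fits["GBLUP-A"].loglik - 1e-3

    def test_sep_bounded_by_prior_sd(self, clean_sim, clean_kernels):
        fit_ = fit(
            model_spec("GBLUP-A", "trait"), clean_sim.phenotypes, clean_kernels
        )
        blup = fit_.blups["additive"]
        prior_sd = np.sqrt(
            fit_.estimates["additive"]
            * np.diag(clean_kernels["G_add"].matrix)
        )
        assert (blup["sep"].to_numpy() >= 0).all()
        assert (blup["sep"].to_numpy() <= prior_sd + 1e-8).all()

    def test_likelihood_monotone_across_iterations(self, clean_sim, clean_kernels):
        fit_ = fit(model_spec("GBLUP-A", "trait"), clean_sim.phenotypes, clean_kernels)
        logls = [t["loglik"] for t in fit_.trace]
        assert all(b >= a - 1e-8 for a, b in zip(logls, logls[1:]))

    def test_log_transform_requires_positive_trait(self):
        phen, _ = one_way_layout(s=4, n=3)
        phen.loc[0, "y"] = -1.0
        spec = MixedModelSpec(
            "y", [RandomTerm("family", factor="family")], transform="log"
        )
        with pytest.raises(FitError, match="positive"):
            fit(spec, phen)

    def test_missing_trait_values_dropped(self):
        phen, _ = one_way_layout(s=10, n=4)
        phen.loc[phen.index[:5], "y"] = np.nan
        spec = MixedModelSpec("y", [RandomTerm("family", factor="family")])
        assert fit(spec, phen).n_obs == len(phen) - 5

    def test_kernel_missing_individuals_rejected(self, clean_sim, clean_kernels):
        phen = clean_sim.phenotypes.copy()
        phen.loc[phen.index[0], "id"] = "stranger"
        with pytest.raises(FitError, match="stranger"):
            fit(model_spec("GBLUP-A", "trait"), phen, clean_kernels)


class TestDerivedStatistics:
    def test_heritability_excludes_design_terms(self):
        comp = {"additive": 2.0, "replication": 1.0, "rep_x_family": 1.0, "residual": 6.0}
        assert heritability_from_components(comp) == pytest.approx(0.25)

    def test_zero_additive_gives_zero_heritability(self):
        assert heritability_from_components({"additive": 0.0, "residual": 3.0}) == 0.0

    def test_proportions_sum_to_hundred(self, clean_sim, clean_kernels):
        fit_ = fit(model_spec("GBLUP-A", "trait"), clean_sim.phenotypes, clean_kernels)
        props = variance_proportions(fit_)
        assert sum(props.values()) == pytest.approx(100.0)
        h2, se = heritability(fit_)
        assert 0.0 <= h2 <= 1.0
        assert se > 0

    def test_proportions_include_design_terms(self):
        props = variance_proportions_from_components(
            {"additive": 1.0, "replication": 1.0, "residual": 2.0}
        )
        assert props["additive"] == pytest.approx(25.0)

    def test_aic_arithmetic(self):
        class Stub:
            loglik = -100.0
            n_parameters = 4

        assert aic(Stub()) == pytest.approx(208.0)
        Stub.n_parameters = 3
        assert aic(Stub()) == pytest.approx(206.0)


class TestEigenDiagnostic:
    @staticmethod
    def _fit_with_cov(cov: pd.DataFrame):
        class Stub:
            pass

        s = Stub()
        s.cov = cov
        return s

    def test_diagonal_covariance_gives_unit_eigenvalues(self):
        cov = pd.DataFrame(np.diag([2.0, 3.0, 4.0]), index=list("abc"), columns=list("abc"))
        eig = sampling_correlation_diagnostic(self._fit_with_cov(cov))
        np.testing.assert_allclose(eig.eigenvalues, [1.0, 1.0, 1.0])
        np.testing.assert_allclose(eig.cumulative_proportion, [1 / 3, 2 / 3, 1.0])

    def test_two_parameter_closed_form(self):
        cov = pd.DataFrame(
            [[1.0, 0.6], [0.6, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        eig = sampling_correlation_diagnostic(self._fit_with_cov(cov))
        np.testing.assert_allclose(eig.eigenvalues, [1.6, 0.4])

    def test_unit_diagonal_and_boundary_exclusion(self):
        cov = pd.DataFrame(
            [[2.0, 0.1, 0.0], [0.1, 3.0, 0.0], [0.0, 0.0, 0.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        with pytest.warns(UserWarning, match="boundary"):
            eig = sampling_correlation_diagnostic(self._fit_with_cov(cov))
        np.testing.assert_allclose(np.diag(eig.F), 1.0)
        assert eig.excluded == ["c"]
        assert eig.cumulative_proportion[-1] == pytest.approx(1.0)
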