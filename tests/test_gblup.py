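import numpy as np
import pandas as pd
import pytest

from clonalgp import (
    SimConfig,
    VarianceComponents,
    assemble_design,
    build_kernel_set,
    compute_blues_all,
    cross_trait_stats,
    genotypic_correlation,
    heritabilities,
    likelihood_ratio_test,
    reml_fit,
    simulate_dataset,
    solve_blups,
    KernelGBLUP,
)
from clonalgp.gblup import _reml_pieces
from clonalgp.kernels import build_Ga
from clonalgp.simulate import TRAIT_PROFILES

from conftest import random_genotypes

#: printed per-trait variance decompositions (percent of phenotypic variance)
#: for the six-trait worked example, with their published derived ratios
TRAIT_ROWS = {
    "WT": (0.52, 0.77, 0.95),
    "GRE": (0.27, 0.73, 0.87),
    "FF": (0.50, 0.79, 0.93),
    "CRI": (0.23, 0.66, 0.95),
    "JUI": (0.18, 0.60, 0.93),
    "FIN": (0.11, 0.34, 0.88),
}


class TestDerivedRatios:
    @pytest.mark.parametrize("trait", list(TRAIT_ROWS))
    def test_heritabilities_and_rb_from_published_decomposition(self, trait):
        vc = VarianceComponents.from_mapping(TRAIT_PROFILES[trait])
        h2, H2 = heritabilities(vc)
        exp_h2, exp_H2, exp_rb = TRAIT_ROWS[trait]
        assert round(h2, 2) == exp_h2
        assert round(H2, 2) == exp_H2
        assert round(genotypic_correlation(vc), 2) == exp_rb

    def test_degenerate_ratios(self):
        all_resid = VarianceComponents({"a": 0.0, "e": 1.0})
        assert heritabilities(all_resid) == (0.0, 0.0)
        additive_only = VarianceComponents({"a": 0.4, "e": 0.6})
        h2, H2 = heritabilities(additive_only)
        assert h2 == H2
        no_int = VarianceComponents({"a": 0.3, "d": 0.1, "aa": 0.1, "a_site": 0.0, "e": 0.5})
        assert genotypic_correlation(no_int) == 1.0

    def test_cross_trait_means_and_nonadditive_ratios(self):
        stats = cross_trait_stats(
            {t: TRAIT_PROFILES[t] for t in TRAIT_ROWS}
        )
        assert stats["mean_additive_pct"] == pytest.approx(30.0, abs=0.5)
        assert stats["mean_dominance_pct"] == pytest.approx(16.1, abs=0.5)
        assert stats["mean_epistatic_pct"] == pytest.approx(18.7, abs=0.5)
        r = stats["nonadditive_additive_ratio"]
        assert round(r["WT"], 2) == 0.48
        assert round(r["JUI"], 2) == 2.35
        assert round(stats["mean_nonadditive_additive_ratio"], 2) == 1.53

    def test_zero_additive_ratio_undefined(self):
        stats = cross_trait_stats({"x": {"a": 0.0, "d": 0.5, "e": 0.5}})
        assert np.isnan(stats["nonadditive_additive_ratio"]["x"])


class TestDesignAssembly:
    def _blues(self, ids, sites, values=None):
        rows = [(i, s) for s in sites for i in ids]
        df = pd.DataFrame(rows, columns=["individual_id", "site"])
        df["blue_value"] = values if values is not None else np.arange(len(df), dtype=float)
        return df

    def test_site_major_kronecker_structure(self):
        rng = np.random.default_rng(0)
        G = build_Ga(random_genotypes(rng, 3, 50))
        blues = self._blues(G.ids, ["S1", "S2"])
        d = assemble_design(blues, {"a": G}, variant="A")
        assert d.n_records == 6
        Km = next(c.K for c in d.components if c.name == "a")
        Gv = G.values
        assert np.allclose(Km, np.block([[Gv, Gv], [Gv, Gv]]))
        Ki = next(c.K for c in d.components if c.name == "a_site")
        zero = np.zeros_like(Gv)
        assert np.allclose(Ki, np.block([[Gv, zero], [zero, Gv]]))
        assert [c.name for c in d.components] == ["a", "a_site", "e"]

    def test_masked_cell_drops_rows_consistently(self):
        rng = np.random.default_rng(1)
        G = build_Ga(random_genotypes(rng, 3, 50))
        blues = self._blues(G.ids, ["S1", "S2"])
        blues = blues.drop(index=4)  # one individual missing at site 2
        d = assemble_design(blues, {"a": G}, variant="A")
        assert d.n_records == 5
        assert all(c.K.shape == (5, 5) for c in d.components)
        assert d.X.shape == (5, 2)

    def test_unknown_individual_rejected(self):
        rng = np.random.default_rng(2)
        G = build_Ga(random_genotypes(rng, 3, 50))
        blues = self._blues(G.ids + ["ghost"], ["S1"])
        with pytest.raises(KeyError, match="ghost"):
            assemble_design(blues, {"a": G}, variant="A")


class TestRemlOracles:
    def test_balanced_anova_closed_form(self):
        """With an identity kernel and a balanced individuals × sites layout
        the REML components equal the classical two-way ANOVA estimators."""
        rng = np.random.default_rng(10)
        n, s = 40, 2
        u = rng.normal(0, np.sqrt(2.0), size=n)
        site_eff = np.array([0.0, 1.5])
        e = rng.normal(0, 1.0, size=(n, s))
        y = u[:, None] + site_eff[None, :] + e
        ids = [str(k) for k in range(n)]
        blues = pd.DataFrame(
            [(ids[i], f"S{j+1}", y[i, j]) for j in range(s) for i in range(n)],
            columns=["individual_id", "site", "blue_value"],
        )
        d = assemble_design(blues, {"a": np.eye(n)}, variant="A", gxe=False)
        fit = reml_fit(d)
        ybar_i = y.mean(axis=1)
        resid = y - ybar_i[:, None] - y.mean(axis=0)[None, :] + y.mean()
        mse = (resid**2).sum() / ((n - 1) * (s - 1))
        ms_ind = s * ((ybar_i - y.mean()) ** 2).sum() / (n - 1)
        assert fit.varcomps.get("e") == pytest.approx(mse, rel=1e-4)
        assert fit.varcomps.get("a") == pytest.approx((ms_ind - mse) / s, rel=1e-4)

    def test_reml_matches_dense_grid_search(self):
        """On a small two-component problem the REML optimum agrees with a
        brute-force grid evaluation of the restricted log-likelihood."""
        rng = np.random.default_rng(11)
        n = 30
        G = build_Ga(random_genotypes(rng, n, 100)).values
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        u = L @ rng.normal(size=n) * 0.8  # shared across the two records
        ids = [str(k) for k in range(n)]
        blues = pd.DataFrame(
            [
                (ids[i], site, u[i] + 0.7 * rng.normal() + off)
                for site, off in (("S1", 0.0), ("S2", 0.4))
                for i in range(n)
            ],
            columns=["individual_id", "site", "blue_value"],
        )
        d = assemble_design(blues, {"a": G}, variant="A", gxe=False)
        fit = reml_fit(d)
        grid = np.linspace(0.02, 3.0, 150)
        best, best_ll = None, -np.inf
        for sg in grid:
            for se in grid:
                pieces = _reml_pieces(d, np.array([sg, se]))
                if pieces is not None and pieces["ll"] > best_ll:
                    best, best_ll = (sg, se), pieces["ll"]
        step = grid[1] - grid[0]
        assert fit.restricted_loglik >= best_ll - 1e-6
        assert abs(fit.varcomps.get("a") - best[0]) <= step
        assert abs(fit.varcomps.get("e") - best[1]) <= step

    def test_gblup_equals_rrblup_with_matched_penalty(self):
        """Additive GBLUP genetic values equal ridge-regression marker-effect
        predictions M u_hat when the ridge penalty matches the variance
        ratio — solved through an independent mixed-model-equation path."""
        rng = np.random.default_rng(12)
        n, m = 40, 120
        geno = random_genotypes(rng, n, m)
        p = geno.compute_allele_freqs()
        c = float(np.sum(2 * p * (1 - p)))
        Mc = geno.dosages - 2 * p
        G = build_Ga(geno)
        sa, se = 1.3, 0.9
        y = rng.normal(size=n)
        blues = pd.DataFrame(
            {"individual_id": G.ids, "site": "S1", "blue_value": y}
        )
        d = assemble_design(blues, {"a": G}, variant="A", gxe=False)
        a_hat = solve_blups(d, VarianceComponents({"a": sa, "e": se}))["a"]
        # RR-BLUP oracle: MME for y = 1 mu + Mc u + e, u ~ N(0, I sa/c)
        su = sa / c
        X = np.ones((n, 1))
        top = np.hstack([X.T @ X / se, X.T @ Mc / se])
        bot = np.hstack([Mc.T @ X / se, Mc.T @ Mc / se + np.eye(m) / su])
        rhs = np.concatenate([X.T @ y / se, Mc.T @ y / se])
        sol = np.linalg.solve(np.vstack([top, bot]), rhs)
        pred = Mc @ sol[1:]
        assert np.max(np.abs(a_hat - pred)) / np.max(np.abs(pred)) < 1e-6

    def test_zero_variance_component_gives_zero_blup(self):
        rng = np.random.default_rng(13)
        G = build_Ga(random_genotypes(rng, 10, 60))
        blues = pd.DataFrame(
            {"individual_id": list(G.ids) * 2, "site": ["S1"] * 10 + ["S2"] * 10,
             "blue_value": rng.normal(size=20)}
        )
        d = assemble_design(blues, {"a": G, "d": G, "aa": G}, variant="ADE", gxe=False)
        eff = solve_blups(d, VarianceComponents({"a": 0.5, "d": 0.0, "aa": 0.3, "e": 0.4}))
        assert np.allclose(eff["d"], 0.0)
        assert not np.allclose(eff["a"], 0.0)


class TestRemlBehaviour:
    def test_loglik_nondecreasing_with_more_iterations(self, small_sim_blues, small_sim_kernels):
        tb = small_sim_blues
        d = assemble_design(tb, small_sim_kernels, "ADE")
        lls = [reml_fit(d, max_iter=k).restricted_loglik for k in (2, 10, 60)]
        assert lls[0] <= lls[1] + 1e-9 <= lls[2] + 2e-9

    def test_nested_variants_order_logliks(self, small_sim_blues, small_sim_kernels):
        fits = {}
        for v in ("A", "AD", "ADE"):
            d = assemble_design(small_sim_blues, small_sim_kernels, v)
            fits[v] = reml_fit(d)
        tol = 1e-3
        assert fits["A"].restricted_loglik <= fits["AD"].restricted_loglik + tol
        assert fits["AD"].restricted_loglik <= fits["ADE"].restricted_loglik + tol

    def test_start_values_reach_same_optimum(self, small_sim_blues, small_sim_kernels):
        d = assemble_design(small_sim_blues, small_sim_kernels, "ADE")
        f1 = reml_fit(d)
        vy = float(np.var(d.y, ddof=1))
        alt = np.array([0.6, 0.05, 0.05, 0.05, 0.05, 0.05, 0.15]) * vy
        f2 = reml_fit(d, start=alt)
        assert abs(f1.restricted_loglik - f2.restricted_loglik) < 0.05

    def test_scale_equivariance(self, small_sim_blues, small_sim_kernels):
        tb = small_sim_blues
        X = tb[["individual_id", "site"]]
        c = 3.7
        m1 = KernelGBLUP(kernels=small_sim_kernels).fit(X, tb["blue_value"].to_numpy())
        m2 = KernelGBLUP(kernels=small_sim_kernels).fit(X, c * tb["blue_value"].to_numpy())
        for k, v in m1.varcomps_.sigma2.items():
            assert m2.varcomps_.sigma2[k] == pytest.approx(c**2 * v, rel=0.02, abs=1e-6)
        assert m2.h2_ == pytest.approx(m1.h2_, abs=0.01)
        assert m2.H2_ == pytest.approx(m1.H2_, abs=0.01)
        if m1.rB_ is not None:
            assert m2.rB_ == pytest.approx(m1.rB_, abs=0.01)
        r = np.corrcoef(m1.gegv_, m2.gegv_)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-4)

    def test_too_few_records_rejected(self):
        G = np.eye(2)
        blues = pd.DataFrame(
            {"individual_id": ["0", "1"], "site": "S1", "blue_value": [0.1, 0.2]}
        )
        d = assemble_design(blues, {"a": G}, variant="A", gxe=False)
        with pytest.raises(ValueError, match="too few records"):
            reml_fit(d)


@pytest.fixture(scope="module")
def additive_fits():
    cfg = SimConfig(
        n_parents=8, n_families=6, family_size=10, n_snps=300, seed=21,
        var_components={"a": 0.5, "d": 0.0, "aa": 0.0, "a_site": 0.0,
                        "d_site": 0.0, "aa_site": 0.0, "e": 0.5},
    )
    ds = simulate_dataset(cfg)
    blues = compute_blues_all(ds.phenotypes)
    kernels = build_kernel_set(ds.offspring)
    fits = {}
    for v in ("A", "AD", "ADE"):
        d = assemble_design(blues, kernels, v)
        fits[v] = reml_fit(d)
    return fits


class TestLikelihoodRatio:
    def test_df_is_number_of_extra_components(self, additive_fits):
        out = likelihood_ratio_test(additive_fits["A"], additive_fits["ADE"])
        assert out["df"] == 4
        out2 = likelihood_ratio_test(additive_fits["A"], additive_fits["AD"])
        assert out2["df"] == 2

    def test_pure_additive_truth_gives_null_like_test(self, additive_fits):
        out = likelihood_ratio_test(additive_fits["A"], additive_fits["ADE"])
        assert out["statistic"] >= -1e-6
        assert out["p_value"] > 0.05
        assert out["p_value_mixture"] <= out["p_value"] + 1e-12

    def test_identical_loglik_gives_p_one(self, additive_fits):
        import copy

        red = additive_fits["A"]
        full = copy.copy(additive_fits["ADE"])
        full.restricted_loglik = red.restricted_loglik
        out = likelihood_ratio_test(red, full)
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p_value"] == 1.0

    def test_non_nested_rejected(self, additive_fits):
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(additive_fits["ADE"], additive_fits["A"])
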