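import numpy as np
import pytest
from scipy import stats

from conftest import make_genotypes
from _oracles import reml_fit_dense, reml_loglik_dense

import famburden as fb
from famburden.collapse import CollapsedDesign
from famburden.genotype import CovariateMatrix
from famburden.mixed import (
    DELTA_GRID_POINTS,
    DELTA_LOG10_BOUNDS,
    ModelSpec,
    build_fixed_design,
    gls_wald_test,
    ols_test,
    reml_fit,
    results_to_frame,
    run_all,
    run_method,
    spectral_decomposition,
)
from famburden.pedigree import RelatednessMatrix


def design_from(x, subjects=None):
    x = np.asarray(x, dtype=np.int8)
    return CollapsedDesign(
        gene="g", indicator=x, carrier_count=int(x.sum()),
        n_rare_variants=1, maf_threshold=0.01,
        subject_order=subjects or [f"s{i}" for i in range(len(x))],
    )


def random_problem(seed, n=40, h2=0.5):
    """Trait with genuine polygenic signal on a random family-ish K."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, max(n // 3, 2)))
    k = a @ a.T
    d = np.sqrt(np.diag(k))
    k = k / np.outer(d, d)  # correlation-like PSD matrix, unit diagonal
    x = (rng.random(n) < 0.3).astype(float)
    F = np.column_stack([np.ones(n), x])
    sg = h2
    se = 1.0 - h2
    chol = np.linalg.cholesky(k + 1e-10 * np.eye(n))
    y = np.sqrt(sg) * (chol @ rng.standard_normal(n)) + np.sqrt(se) * rng.standard_normal(n)
    return y, F, k


class TestModelSpec:
    def test_defaults_per_method(self):
        assert ModelSpec("REG").n_pcs == 0
        assert ModelSpec("PC").n_pcs == 10
        assert ModelSpec("PC-KIN").covariance_kind == "relationship_2phi"
        assert ModelSpec("IBS").covariance_kind == "ibs"
        assert not ModelSpec("REG").is_mixed

    def test_invalid_combinations(self):
        with pytest.raises(ValueError):
            ModelSpec("KIN", n_pcs=5)
        with pytest.raises(ValueError):
            ModelSpec("PC", n_pcs=0)
        with pytest.raises(ValueError):
            ModelSpec("XYZ")


class TestBuildFixedDesign:
    def test_reg_two_columns(self):
        F, status = build_fixed_design(design_from([0, 1, 0, 1]))
        assert F.shape == (4, 2) and status == "ok"
        np.testing.assert_array_equal(F[:, 0], 1)

    def test_pc_design_width(self):
        n = 30
        rng = np.random.default_rng(0)
        qmat, _ = np.linalg.qr(rng.normal(size=(n, 10)))
        q = CovariateMatrix(qmat, [f"s{i}" for i in range(n)],
                            np.arange(10, 0, -1, dtype=float))
        x = design_from(rng.integers(0, 2, n).astype(np.int8))
        F, status = build_fixed_design(x, q)
        assert F.shape == (n, 12) and status == "ok"

    def test_constant_indicator_untestable(self):
        _, status = build_fixed_design(design_from([0, 0, 0]))
        assert status == "untestable"
        _, status = build_fixed_design(design_from([1, 1, 1]))
        assert status == "untestable"


class TestOls:
    def test_hand_computed_slope(self):
        # points (0,0), (1,1), (0,0.5), (1,1.5): slope exactly 1
        x = np.array([0, 1, 0, 1], dtype=float)
        y = np.array([0, 1, 0.5, 1.5])
        F = np.column_stack([np.ones(4), x])
        res = ols_test(y, F)
        assert res.beta == pytest.approx(1.0)
        assert res.df == 2

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        for _ in range(10):
            n = 25
            F = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
            y = rng.normal(size=n) + 0.4 * F[:, 1]
            res = ols_test(y, F)
            ref = sm.OLS(y, F).fit()
            assert res.beta == pytest.approx(ref.params[1], rel=1e-10)
            assert res.se == pytest.approx(ref.bse[1], rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalues[1], rel=1e-8)

    def test_perfect_fit_underflows(self):
        x = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        y = 3.0 * x
        res = ols_test(y, np.column_stack([np.ones(6), x]))
        assert res.beta == pytest.approx(3.0)
        assert res.p_value < 1e-10


class TestRemlFit:
    def test_loglik_beats_whole_grid(self):
        """Optimiser contract: returned optimum dominates all grid points."""
        y, F, k = random_problem(3)
        km = RelatednessMatrix(k, [f"s{i}" for i in range(len(y))], "ibs")
        vc = reml_fit(y, F, km)
        grid = np.linspace(*DELTA_LOG10_BOUNDS, DELTA_GRID_POINTS)
        for g in grid:
            assert vc.reml_loglik >= reml_loglik_dense(y, F, k, 10.0**g) - 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_dense_oracle(self, seed):
        """Spectral profiled REML agrees with the naive dense optimiser."""
        y, F, k = random_problem(seed, n=35)
        km = RelatednessMatrix(k, [f"s{i}" for i in range(len(y))], "ibs")
        vc = reml_fit(y, F, km)
        delta_o, ll_o = reml_fit_dense(y, F, k)
        assert vc.reml_loglik == pytest.approx(ll_o, abs=1e-4)
        assert vc.delta == pytest.approx(delta_o, rel=0.01)

    def test_permutation_invariance(self):
        """Restricted likelihood is unchanged by relabelling subjects."""
        y, F, k = random_problem(8, n=30)
        km = RelatednessMatrix(k, [f"s{i}" for i in range(30)], "ibs")
        vc = reml_fit(y, F, km)
        rng = np.random.default_rng(0)
        perm = rng.permutation(30)
        km_p = RelatednessMatrix(k[np.ix_(perm, perm)],
                                 [f"s{i}" for i in perm], "ibs")
        vc_p = reml_fit(y[perm], F[perm], km_p)
        assert vc_p.reml_loglik == pytest.approx(vc.reml_loglik, abs=1e-8)
        assert vc_p.delta == pytest.approx(vc.delta, rel=1e-4)

    def test_variance_recovery_small(self):
        """Mean heritability estimate near truth over replicate fits."""
        rng = np.random.default_rng(15)
        n = 120
        blocks = [np.full((6, 6), 0.5) + 0.5 * np.eye(6) for _ in range(20)]
        from scipy.linalg import block_diag
        k = block_diag(*blocks)
        km = RelatednessMatrix(k, [f"s{i}" for i in range(n)], "relationship_2phi")
        eig = spectral_decomposition(km)
        chol = np.linalg.cholesky(k + 1e-10 * np.eye(n))
        F = np.ones((n, 1))
        h2 = []
        for _ in range(40):
            y = chol @ rng.standard_normal(n) + rng.standard_normal(n)
            vc = reml_fit(y, F, eig=eig)
            h2.append(vc.sigma2_g / (vc.sigma2_g + vc.sigma2_e))
        assert np.mean(h2) == pytest.approx(0.5, abs=0.08)

    def test_non_psd_rejected(self):
        n = 10
        k = -np.eye(n)
        km = RelatednessMatrix(k, [f"s{i}" for i in range(n)], "ibs")
        with pytest.raises(ValueError, match="positive semidefinite"):
            reml_fit(np.zeros(n), np.ones((n, 1)), km)


class TestGlsWald:
    def test_identity_k_reduces_to_ols(self):
        """With K = I only the total variance is identified; the Wald test
        must coincide with the OLS t-test."""
        rng = np.random.default_rng(31)
        for seed in range(10):
            n = 30
            x = rng.integers(0, 2, n).astype(float)
            F = np.column_stack([np.ones(n), x])
            y = 0.3 * x + rng.standard_normal(n)
            km = RelatednessMatrix(np.eye(n), [f"s{i}" for i in range(n)], "ibs")
            vc = reml_fit(y, F, km)
            mixed = gls_wald_test(y, F, vc, km)
            ols = ols_test(y, F)
            assert mixed.beta == pytest.approx(ols.beta, abs=1e-8)
            assert mixed.se == pytest.approx(ols.se, abs=1e-8)
            assert mixed.p_value == pytest.approx(ols.p_value, abs=1e-8)

    def test_null_pvalues_uniform(self):
        """Under the correctly specified mixed model, p is ~U(0,1)."""
        rng = np.random.default_rng(41)
        n = 60
        y0, F, k = random_problem(100, n=n)
        km = RelatednessMatrix(k, [f"s{i}" for i in range(n)], "ibs")
        eig = spectral_decomposition(km)
        chol = np.linalg.cholesky(k + 1e-10 * np.eye(n))
        pvals = []
        for _ in range(300):
            x = (rng.random(n) < 0.3).astype(float)
            if x.sum() in (0, n):
                continue
            F = np.column_stack([np.ones(n), x])
            y = chol @ rng.standard_normal(n) + rng.standard_normal(n)
            vc = reml_fit(y, F, eig=eig)
            pvals.append(gls_wald_test(y, F, vc, eig=eig).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRunMethod:
    def _inputs(self, n=24, seed=5):
        rng = np.random.default_rng(seed)
        x = design_from((rng.random(n) < 0.3).astype(np.int8))
        y = rng.standard_normal(n)
        a = rng.normal(size=(n, n))
        k = a @ a.T / n
        d = np.sqrt(np.diag(k))
        k = k / np.outer(d, d)
        relmats = {
            "relationship_2phi": RelatednessMatrix(k, x.subject_order, "relationship_2phi"),
            "ibs": RelatednessMatrix((k + 1) / 2, x.subject_order, "ibs"),
        }
        qmat, _ = np.linalg.qr(rng.normal(size=(n, 10)))
        q = CovariateMatrix(qmat, x.subject_order, np.arange(10, 0, -1, dtype=float))
        return x, y, q, relmats

    def test_missing_relmat_is_config_error(self):
        x, y, q, _ = self._inputs()
        with pytest.raises(ValueError, match="KIN"):
            run_method(ModelSpec("KIN"), x, y, None, {})

    def test_missing_pcs_is_config_error(self):
        x, y, _, relmats = self._inputs()
        with pytest.raises(ValueError, match="PC"):
            run_method(ModelSpec("PC"), x, y, None, relmats)

    def test_six_methods_one_gene(self):
        x, y, q, relmats = self._inputs()
        results = [
            run_method(ModelSpec(m), x, y, q, relmats)
            for m in fb.METHODS
        ]
        assert {r.gene for r in results} == {"g"}
        assert {r.carrier_count for r in results} == {x.carrier_count}
        assert all(r.status == "ok" for r in results)
        assert [r.method for r in results] == list(fb.METHODS)


class TestRunAll:
    def _scan(self, seed=9):
        rng = np.random.default_rng(seed)
        n = 30
        subjects = [f"s{i}" for i in range(n)]
        designs = []
        for gi in range(8):
            ind = (rng.random(n) < 0.25).astype(np.int8)
            if gi == 7:
                ind[:] = 0  # untestable gene
            designs.append(CollapsedDesign(
                gene=f"g{gi}", indicator=ind, carrier_count=int(ind.sum()),
                n_rare_variants=1, maf_threshold=0.01, subject_order=subjects,
            ))
        a = rng.normal(size=(n, n))
        k = a @ a.T / n
        d = np.sqrt(np.diag(k))
        k = k / np.outer(d, d)
        relmats = {"relationship_2phi": RelatednessMatrix(k, subjects, "relationship_2phi")}
        y = rng.standard_normal(n)
        specs = [ModelSpec("REG"), ModelSpec("KIN")]
        return specs, designs, y, relmats

    def test_cartesian_product(self):
        specs, designs, y, relmats = self._scan()
        res = run_all(specs, designs, y, relmats=relmats)
        assert len(res) == len(specs) * len(designs)

    def test_untestable_present_in_output(self):
        specs, designs, y, relmats = self._scan()
        df = results_to_frame(run_all(specs, designs, y, relmats=relmats))
        assert (df.loc[df.gene == "g7", "status"] == "untestable").all()
        assert np.isnan(df.loc[df.gene == "g7", "p_value"]).all()

    def test_rerun_bitwise_identical(self):
        specs, designs, y, relmats = self._scan()
        a = results_to_frame(run_all(specs, designs, y, relmats=relmats))
        b = results_to_frame(run_all(specs, designs, y, relmats=relmats))
        assert a.equals(b)
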