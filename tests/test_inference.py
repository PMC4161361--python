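import numpy as np
import pytest
from scipy import stats

from glmqtl import condprob, crosssim, genmap, inference
from glmqtl.condprob import RegressorSet
from glmqtl.crosssim import QTL, SimulationSpec
from glmqtl.glmfam import make_family


@pytest.fixture(scope="module")
def marker_regressors(bench_map, bench_grid):
    """Regressors for a small binary benchmark replicate on the full grid."""
    spec = crosssim.ten_qtl_scenario("binary", 200, seed=31)
    data = crosssim.simulate_dataset(spec)
    reg = condprob.build_regressors(
        data.marker_genotypes.astype(float), spec.gmap, bench_grid
    )
    return data, reg


class TestPruneSelected:
    def test_distinct_intervals_unchanged(self, marker_regressors):
        _, reg = marker_regressors
        b = np.zeros(reg.n_loci)
        b[5] = 1.0    # chr1, 5 cM -> interval 0
        b[25] = -0.5  # chr1, 25 cM -> interval 2
        kept = inference.prune_selected(b, reg)
        np.testing.assert_array_equal(kept, [5, 25])

    def test_largest_effect_wins_within_interval(self, marker_regressors):
        _, reg = marker_regressors
        b = np.zeros(reg.n_loci)
        b[3] = 0.4
        b[7] = -0.9  # same marker interval [0, 10)
        kept = inference.prune_selected(b, reg)
        np.testing.assert_array_equal(kept, [7])

    def test_tie_breaks_toward_smaller_position(self, marker_regressors):
        _, reg = marker_regressors
        b = np.zeros(reg.n_loci)
        b[3] = 0.5
        b[7] = -0.5
        kept = inference.prune_selected(b, reg)
        np.testing.assert_array_equal(kept, [3])

    def test_empty_selection(self, marker_regressors):
        _, reg = marker_regressors
        assert inference.prune_selected(np.zeros(reg.n_loci), reg).size == 0


class TestRefitGLM:
    def test_logistic_refit_matches_statsmodels(self, marker_regressors):
        import statsmodels.api as sm

        data, reg = marker_regressors
        cols = np.flatnonzero(reg.grid.at_marker)[[2, 20, 47]]  # observed markers
        refit = inference.refit_glm(data.phenotypes, reg, cols, make_family("binomial"))
        X = sm.add_constant(reg.d[:, cols])
        oracle = sm.GLM(data.phenotypes, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(refit.beta, oracle.params, atol=1e-6)
        np.testing.assert_allclose(refit.se, oracle.bse[1:], rtol=1e-4)

    def test_gaussian_refit_matches_least_squares(self, marker_regressors):
        data, reg = marker_regressors
        rng = np.random.default_rng(0)
        cols = np.flatnonzero(reg.grid.at_marker)[[5, 30]]
        y = 1.0 + 0.8 * reg.d[:, cols[0]] + rng.standard_normal(reg.n)
        refit = inference.refit_glm(y, reg, cols, make_family("gaussian"))
        X = np.hstack([np.ones((reg.n, 1)), reg.d[:, cols]])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(refit.beta, beta, atol=1e-6)
        resid = y - X @ refit.beta
        sigma2 = resid @ resid / (reg.n - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))[1:]
        np.testing.assert_allclose(refit.se, se, rtol=1e-3)

    def test_intercept_only_refit_is_null_glm(self, marker_regressors):
        data, reg = marker_regressors
        refit = inference.refit_glm(data.phenotypes, reg, np.array([], dtype=int),
                                    make_family("binomial"))
        expected = np.log(data.phenotypes.mean() / (1 - data.phenotypes.mean()))
        assert refit.beta[0] == pytest.approx(expected, abs=1e-6)

    def test_too_many_loci_rejected(self, marker_regressors):
        data, reg = marker_regressors
        with pytest.raises(ValueError):
            inference.refit_glm(data.phenotypes, reg, np.arange(reg.n), make_family("binomial"))

    def test_null_refit_t_statistics_are_tame(self, bench_map):
        grid = genmap.build_locus_grid(bench_map, 10.0)
        big = 0
        runs = 100
        for s in range(runs):
            null = crosssim.simulate_null(bench_map, "backcross", "binomial", 150,
                                          [500, s], link_name="logit")
            reg = condprob.build_regressors(null.marker_genotypes.astype(float),
                                            bench_map, grid)
            refit = inference.refit_glm(null.phenotypes, reg, np.array([12]),
                                        make_family("binomial"))
            if abs(refit.t[0]) >= 4:
                big += 1
        assert big <= 0.01 * runs + 1

    def test_null_refit_pvalues_approximately_uniform(self, bench_map):
        grid = genmap.build_locus_grid(bench_map, 10.0)
        pvals = []
        for s in range(400):
            null = crosssim.simulate_null(bench_map, "backcross", "gaussian", 80,
                                          [600, s])
            reg = condprob.build_regressors(null.marker_genotypes.astype(float),
                                            bench_map, grid)
            refit = inference.refit_glm(null.phenotypes, reg, np.array([30]),
                                        make_family("gaussian"))
            pvals.append(refit.p[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGenomeThreshold:
    @pytest.fixture(scope="class")
    def small_threshold(self, bench_map):
        fam = make_family("gaussian")
        return inference.genome_threshold(
            bench_map, "backcross", fam, 60, n_replicates=20, level=0.05,
            seed=9, grid_step=10.0, fit_options={"cv": "bic"},
        )

    def test_critical_is_order_statistic(self, small_threshold):
        thr = small_threshold
        maxima = np.sort(thr.maxima)
        order = int(np.ceil(0.95 * maxima.size)) - 1
        assert thr.critical_value == maxima[order]
        assert thr.n_replicates == 20

    def test_exceedance_rate_near_level(self, small_threshold):
        frac = np.mean(small_threshold.maxima > small_threshold.critical_value)
        assert frac <= 0.05 + 1e-12

    def test_invalid_arguments(self, bench_map):
        fam = make_family("gaussian")
        with pytest.raises(ValueError):
            inference.genome_threshold(bench_map, "backcross", fam, 50,
                                       n_replicates=5, seed=0)
        with pytest.raises(ValueError):
            inference.genome_threshold(bench_map, "backcross", fam, 50,
                                       n_replicates=20, level=1.5, seed=0)

    def test_permutation_threshold_runs_and_reproduces(self, bench_map):
        fam = make_family("binomial")
        data = crosssim.simulate_null(bench_map, "backcross", "binomial", 60, 3,
                                      link_name="logit")
        kwargs = dict(method="permutation", n_replicates=20, level=0.05, seed=4,
                      grid_step=10.0, dataset=data, fit_options={"cv": "bic"})
        a = inference.genome_threshold(bench_map, "backcross", fam, 60, **kwargs)
        b = inference.genome_threshold(bench_map, "backcross", fam, 60, **kwargs)
        assert a.critical_value == b.critical_value
        assert a.maxima.size == 20


class TestHeritability:
    def test_zero_effects(self):
        np.testing.assert_allclose(
            inference.heritability(np.zeros(3), np.ones(3), 1.0), 0.0
        )

    def test_probit_single_locus_half(self):
        h2 = inference.heritability(np.array([1.0]), np.array([1.0]), 1.0)
        assert h2[0] == pytest.approx(0.5)

    def test_invariant_to_coding_rescale(self):
        b = np.array([0.8, -0.3])
        v = np.array([1.0, 0.5])
        a = inference.heritability(b, v, np.pi**2 / 3)
        bb = inference.heritability(b / 2, 4 * v, np.pi**2 / 3)
        np.testing.assert_allclose(a, bb, atol=1e-12)

    def test_residual_variance_per_family(self):
        logit = make_family("binomial", "logit")
        probit = make_family("binomial", "probit")
        assert inference.link_scale_residual_variance(logit) == pytest.approx(np.pi**2 / 3)
        assert inference.link_scale_residual_variance(probit) == pytest.approx(1.0)
        pois = make_family("poisson", "log")
        assert inference.link_scale_residual_variance(pois, np.full(10, 4.0)) == pytest.approx(0.25)

    def test_invalid_variances_rejected(self):
        with pytest.raises(ValueError):
            inference.heritability(np.ones(1), np.ones(1), 0.0)


class TestCallsAndScan:
    def test_refit_based_call_qtls(self, marker_regressors):
        data, reg = marker_regressors
        fam = make_family("binomial")
        cols = np.flatnonzero(reg.grid.at_marker)[[2, 30]]
        refit = inference.refit_glm(data.phenotypes, reg, cols, fam)
        everything = inference.Threshold(level=0.05, critical_value=0.0,
                                         method="given", n_replicates=0, seed=0)
        calls = inference.call_qtls(refit, everything, reg, fam)
        assert len(calls) == 2
        assert [c.column for c in calls] == list(cols)
        nothing = inference.Threshold(level=0.05, critical_value=1e9,
                                      method="given", n_replicates=0, seed=0)
        assert inference.call_qtls(refit, nothing, reg, fam) == []

    def test_no_call_below_threshold(self, marker_regressors):
        data, reg = marker_regressors
        res = inference.scan(data.phenotypes, reg, make_family("binomial"),
                             cv="bic", seed=1)
        thr = inference.Threshold(level=0.05, critical_value=1e9,
                                  method="given", n_replicates=0, seed=0)
        assert inference.calls_from_scan(res, thr, reg, make_family("binomial")) == []

    def test_single_qtl_scan_calls_near_truth(self, bench_map, bench_grid):
        fam = make_family("binomial")
        thr = inference.Threshold(level=0.05, critical_value=3.0,
                                  method="given", n_replicates=0, seed=0)
        hits = 0
        runs = 10
        for s in range(runs):
            spec = SimulationSpec(design="backcross", gmap=bench_map,
                                  qtls=(QTL("chr2", 35.0, 2.0),),
                                  family_name="binomial", n=300, seed=0)
            data = crosssim.simulate_dataset(spec, seed=[700, s])
            reg = condprob.build_regressors(data.marker_genotypes.astype(float),
                                            bench_map, bench_grid)
            res = inference.scan(data.phenotypes, reg, fam, cv="bic", seed=s)
            calls = inference.calls_from_scan(res, thr, reg, fam)
            if any(abs(c.genome_pos_cM - 135.0) <= 10.0 for c in calls):
                hits += 1
        assert hits >= 0.9 * runs

    def test_call_fields_consistent(self, marker_regressors):
        data, reg = marker_regressors
        fam = make_family("binomial")
        res = inference.scan(data.phenotypes, reg, fam, cv="bic", seed=2)
        thr = inference.Threshold(level=0.05, critical_value=2.0,
                                  method="given", n_replicates=0, seed=0)
        calls = inference.calls_from_scan(res, thr, reg, fam)
        for c in calls:
            assert c.neglog10p >= 2.0
            assert 0.0 <= c.heritability < 1.0
            assert c.chrom in reg.grid.gmap.chrom_names
        # at most one call per marker interval window
        pos = sorted(c.genome_pos_cM for c in calls if c.effect_type == "additive")
        assert all(b - a > 10.0 or b - a == 0.0 for a, b in zip(pos, pos[1:]))


class TestPowerExperiment:
    def test_single_replicate_schema(self, bench_map):
        spec = crosssim.ten_qtl_scenario("binary", 120, seed=0)
        thr = inference.Threshold(level=0.05, critical_value=2.5,
                                  method="given", n_replicates=0, seed=0)
        table = inference.power_experiment(
            spec, 1, thr, seed=5, methods=("IRglmnet", "UWglmnet"),
            fit_options={"cv": "bic"},
        )
        assert len(table) == 20  # 10 QTLs x 2 methods
        assert set(table.power_pct.unique()) <= {0.0, 100.0}
        assert {"method", "qtl", "true_pos_cM", "true_effect", "power_pct",
                "mean_pos_cM", "sd_pos_cM", "mean_effect", "sd_effect"} <= set(table.columns)
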