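"""Shrinkage estimator, partial correlations, mixture fit, edge selection."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad

from emp_mirnet.ggm import (
    build_network,
    fit_mixture,
    null_pdf,
    partial_correlations,
    sample_null,
    shrink_correlation,
)
from emp_mirnet.synthdata import make_precision_matrix, sample_dataset


def _corr_from_precision(theta: np.ndarray) -> np.ndarray:
    cov = np.linalg.inv(theta)
    d = 1 / np.sqrt(np.diag(cov))
    return cov * np.outer(d, d)


class TestShrinkage:
    def test_duplicated_column_keeps_intensity_low(self, rng):
        # a duplicated feature pair has empirical r = 1; the estimated
        # variance of that correlation (from the spread of the products
        # x_k^2) is small relative to r^2 = 1, so lambda* stays near 0 and
        # vanishes as n grows
        lams = []
        for n in (20, 2000):
            x = rng.normal(size=(n, 1))
            res = shrink_correlation(np.hstack([x, x.copy()]))
            assert res.r_empirical[0, 1] == pytest.approx(1.0, abs=1e-12)
            lams.append(res.lambda_star)
        assert lams[0] < 0.2
        assert lams[1] < lams[0]

    def test_pure_noise_shrinks_hard(self):
        # p >> n noise: the optimal intensity is large
        lams = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal((10, 50))
            lams.append(shrink_correlation(x).lambda_star)
        assert min(lams) > 0.5

    def test_offdiagonal_scaling_identity(self, rng):
        x = rng.normal(size=(15, 8))
        res = shrink_correlation(x)
        iu = np.triu_indices(8, 1)
        nonzero = np.abs(res.r_empirical[iu]) > 1e-12
        ratio = res.r_shrunk[iu][nonzero] / res.r_empirical[iu][nonzero]
        np.testing.assert_allclose(ratio, 1 - res.lambda_star, atol=1e-12)
        np.testing.assert_allclose(np.diag(res.r_shrunk), 1.0)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            shrink_correlation(rng.normal(size=(2, 5)))

    def test_zero_variance_feature_named(self, rng):
        x = rng.normal(size=(12, 4))
        x[:, 2] = 3.0
        with pytest.raises(ValueError, match="2"):
            shrink_correlation(x)


class TestPartialCorrelations:
    def test_equicorrelated_closed_form(self):
        # exchangeable 3-variable case: rho_partial = r / (1 + r)
        r = 0.5
        corr = np.full((3, 3), r)
        np.fill_diagonal(corr, 1.0)
        pcor = partial_correlations(corr)
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(pcor[iu], r / (1 + r), atol=1e-12)

    def test_diagonal_input_gives_zero_partials(self):
        pcor = partial_correlations(np.eye(4))
        np.testing.assert_allclose(pcor, np.eye(4))

    def test_matches_residual_regression_oracle(self, rng):
        # independent least-squares definition: correlation of residuals
        # after regressing i and j on all other variables
        for _ in range(5):
            theta = make_precision_matrix(6, 0.4, (0.2, 0.5), seed=int(rng.integers(1 << 30)))
            corr = _corr_from_precision(theta)
            x = rng.multivariate_normal(np.zeros(6), corr, size=4000)
            emp = np.corrcoef(x, rowvar=False)
            pcor = partial_correlations(emp)
            for i, j in [(0, 1), (2, 5), (3, 4)]:
                others = [k for k in range(6) if k not in (i, j)]
                a = np.column_stack([np.ones(len(x)), x[:, others]])
                ri = x[:, i] - a @ np.linalg.lstsq(a, x[:, i], rcond=None)[0]
                rj = x[:, j] - a @ np.linalg.lstsq(a, x[:, j], rcond=None)[0]
                oracle = np.corrcoef(ri, rj)[0, 1]
                assert pcor[i, j] == pytest.approx(oracle, abs=1e-8)

    def test_inverse_rebuild_is_involution(self, rng):
        x = rng.normal(size=(40, 10))
        res = shrink_correlation(x)
        omega = np.linalg.inv(res.r_shrunk)
        np.testing.assert_allclose(np.linalg.inv(omega), res.r_shrunk, atol=1e-8)

    def test_singular_matrix_advises_shrinkage(self):
        corr = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            partial_correlations(corr)


class TestMixture:
    @pytest.mark.parametrize("kappa", [4.0, 10.0, 100.0])
    def test_null_density_normalized(self, kappa):
        val, err = quad(lambda r: null_pdf(r, kappa), -1, 1, epsabs=1e-12)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_null_sampler_matches_density_moments(self, rng):
        kappa = 20.0
        draws = sample_null(kappa, 200_000, rng)
        # Var(rho) = 1/kappa for the correlation null
        assert draws.mean() == pytest.approx(0.0, abs=5e-3)
        assert draws.var() == pytest.approx(1 / kappa, rel=0.03)

    @pytest.mark.parametrize("method", ["empirical", "mle"])
    def test_parameter_recovery_on_pure_null(self, method):
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            rho = sample_null(20.0, 5000, rng)
            fit = fit_mixture(rho, method=method)
            assert 15.0 <= fit.kappa <= 27.0
            assert fit.eta0 >= 0.95

    def test_ranking_separates_alternative_from_null(self, rng):
        null = sample_null(50.0, 4000, rng)
        alt = rng.uniform(-1, 1, 1000)
        fit = fit_mixture(np.concatenate([null, alt]))
        frac_alt = (fit.prob(alt) > 0.95).mean()
        frac_null = (fit.prob(null) > 0.95).mean()
        assert frac_alt > frac_null

    def test_fdr_bounded_and_low_at_tails(self, rng):
        rho = np.concatenate([sample_null(100.0, 2000, rng), [0.85, -0.9]])
        fit = fit_mixture(rho)
        vals = fit.fdr(rho)
        assert ((0 <= vals) & (vals <= 1)).all()
        assert fit.fdr(np.array([0.85]))[0] < fit.fdr(np.array([0.05]))[0]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_mixture(np.linspace(-0.5, 0.5, 5))


class TestBuildNetwork:
    def _fit_all_null(self):
        rng = np.random.default_rng(0)
        return fit_mixture(sample_null(50.0, 1000, rng))

    def test_all_null_fit_gives_empty_network(self, rng):
        pcor = np.eye(4)
        pcor[0, 1] = pcor[1, 0] = 0.02
        net = build_network(pcor, self._fit_all_null(), ["a", "b", "c", "d"])
        assert net.graph.number_of_edges() == 0
        assert net.largest_component == set()

    def test_threshold_zero_keeps_every_nonnull_pair(self, rng):
        null = sample_null(50.0, 2000, rng)
        strong = np.array([0.8, -0.75, 0.9])
        fit = fit_mixture(np.concatenate([null, strong]))
        pcor = np.eye(3)
        pcor[0, 1] = pcor[1, 0] = 0.8
        pcor[0, 2] = pcor[2, 0] = -0.75
        pcor[1, 2] = pcor[2, 1] = 0.9
        net = build_network(pcor, fit, ["a", "b", "c"], prob_threshold=0.0)
        assert net.graph.number_of_edges() == 3  # complete graph on fdr < 1 pairs

    def test_edge_attributes_and_sign(self, rng):
        null = sample_null(50.0, 2000, rng)
        fit = fit_mixture(np.concatenate([null, [0.9, -0.85]]))
        pcor = np.eye(3)
        pcor[0, 1] = pcor[1, 0] = 0.9
        pcor[1, 2] = pcor[2, 1] = -0.85
        net = build_network(pcor, fit, ["a", "b", "c"])
        assert net.graph.edges["a", "b"]["sign"] == 1
        assert net.graph.edges["b", "c"]["sign"] == -1
        for _, _, d in net.graph.edges(data=True):
            assert d["prob"] > 0.95

    def test_node_policy_all_keeps_isolates(self, rng):
        fit = self._fit_all_null()
        net = build_network(np.eye(3), fit, ["a", "b", "c"], node_policy="all")
        assert set(net.nodes) == {"a", "b", "c"}

    def test_feature_permutation_permutes_edges(self, rng):
        theta = make_precision_matrix(20, 0.1, (0.4, 0.6), seed=8)
        corr = _corr_from_precision(theta)
        x = rng.multivariate_normal(np.zeros(20), corr, size=300)
        ids = [f"f{i}" for i in range(20)]

        def edges_of(xm, names):
            res = shrink_correlation(xm)
            pcor = partial_correlations(res.r_shrunk)
            fit = fit_mixture(pcor[np.triu_indices(20, 1)])
            net = build_network(pcor, fit, names)
            return {frozenset(e) for e in net.graph.edges()}

        perm = rng.permutation(20)
        e0 = edges_of(x, ids)
        e1 = edges_of(x[:, perm], [ids[i] for i in perm])
        assert e0 == e1


class TestRecovery:
    def test_planted_structure_recovered(self):
        # moderate-dimension benchmark where the planted magnitudes are
        # geometrically realizable: FDP and recall against the truth
        cfg_kwargs = dict(
            n_features=40, n_samples=100, n_network=40, n_emp_associated=0,
            n_expressed=40, edge_density=0.02, partial_cor_range=(0.3, 0.6),
            hub_degree=0, n_regions=2, enriched_region_size=2,
            enriched_overlap=2, exact_edge_count=True, seed=3,
        )
        from emp_mirnet.synthdata import SyntheticConfig

        expr, _, _, truth = sample_dataset(SyntheticConfig(**cfg_kwargs))
        res = shrink_correlation(expr.values.T)
        pcor = partial_correlations(res.r_shrunk)
        fit = fit_mixture(pcor[np.triu_indices(40, 1)])
        net = build_network(pcor, fit, expr.feature_ids)
        selected = {frozenset(e) for e in net.graph.edges()}
        true_edges = truth.true_edge_set()
        tp = len(selected & true_edges)
        fdp = (len(selected) - tp) / max(1, len(selected))
        recall = tp / len(true_edges)
        assert fdp <= 0.15
        assert recall >= 0.5

    def test_fully_null_data_selects_almost_nothing(self):
        fractions = []
        for seed in range(20):
            x = np.random.default_rng(4000 + seed).standard_normal((24, 100))
            res = shrink_correlation(x)
            pcor = partial_correlations(res.r_shrunk)
            off = pcor[np.triu_indices(100, 1)]
            fit = fit_mixture(off)
            fractions.append((fit.prob(off) > 0.95).mean())
        assert np.mean(fractions) < 0.01
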