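"""Generator: planted precision structure, coupling model, determinism."""

import dataclasses
from math import comb

import numpy as np
import pytest
from scipy import stats

from emp_mirnet.ioformats import checksum
from emp_mirnet.synthdata import (
    SyntheticConfig,
    make_precision_matrix,
    sample_dataset,
    write_dataset,
    read_truth,
)


class TestMakePrecision:
    def test_zero_density_gives_identity(self):
        theta = make_precision_matrix(5, 0.0, (0.3, 0.6), seed=1)
        np.testing.assert_array_equal(theta, np.eye(5))
        # implied covariance diagonal, all partial correlations zero
        cov = np.linalg.inv(theta)
        np.testing.assert_allclose(cov, np.eye(5))

    def test_single_edge_round_trip(self):
        # one planted edge; inverting the implied covariance must recover
        # the planted partial correlation exactly
        theta = make_precision_matrix(
            3, 0.0, (0.5, 0.5), seed=4, extra_edges=[(1, 2)]
        )
        planted = -theta[1, 2]
        assert abs(planted) == pytest.approx(0.5, abs=1e-12)
        cov = np.linalg.inv(theta)
        omega = np.linalg.inv(cov)
        rho = -omega[1, 2] / np.sqrt(omega[1, 1] * omega[2, 2])
        assert rho == pytest.approx(planted, abs=1e-10)

    def test_edge_count_within_binomial_bounds(self):
        p, density = 40, 0.05
        theta = make_precision_matrix(p, density, (0.3, 0.6), seed=1)
        # independent brute-force count of nonzero entries
        k = sum(
            1
            for i in range(p)
            for j in range(i + 1, p)
            if abs(theta[i, j]) > 1e-12
        )
        n_pairs = comb(p, 2)
        lo = stats.binom.ppf(0.005, n_pairs, density)
        hi = stats.binom.ppf(0.995, n_pairs, density)
        assert lo <= k <= hi

    def test_always_positive_definite(self):
        for seed in range(10):
            theta = make_precision_matrix(60, 0.08, (0.4, 0.7), seed=seed)
            assert np.linalg.eigvalsh(theta)[0] > 0

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            make_precision_matrix(10, 1.5, (0.3, 0.6), seed=0)


class TestSampleDataset:
    def test_seed_fixes_every_byte(self, tmp_path, small_config):
        sums = []
        for sub in ("a", "b"):
            paths = write_dataset(str(tmp_path / sub), small_config)
            sums.append({k: checksum(v) for k, v in sorted(paths.items())})
        assert sums[0] == sums[1]

    def test_different_seed_changes_expression(self, tmp_path, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a = sample_dataset(small_config)[0]
        b = sample_dataset(other)[0]
        assert not np.array_equal(a.values, b.values)

    def test_truth_round_trips_through_json(self, tmp_path, small_config):
        paths = write_dataset(str(tmp_path / "d"), small_config)
        _, _, _, truth = sample_dataset(small_config)
        back = read_truth(paths["truth"])
        assert back.true_edge_set() == truth.true_edge_set()
        assert back.emp_associated == truth.emp_associated
        assert back.enriched_members == truth.enriched_members
        np.testing.assert_allclose(back.precision_matrix, truth.precision_matrix)

    def test_enriched_overlap_is_exact(self, small_config):
        _, _, loci, truth = sample_dataset(small_config)
        members = set(truth.enriched_members)
        overlap = members & set(truth.network_features)
        assert len(overlap) == small_config.enriched_overlap
        assert len(members) == small_config.enriched_region_size
        # locus table agrees with the truth object
        in_region = set(loci.loc[loci["region"] == truth.enriched_region, "feature_id"])
        assert in_region == members

    def test_true_edges_match_precision_support(self, small_config):
        _, _, _, truth = sample_dataset(small_config)
        theta = truth.precision_matrix
        ids = truth.network_features
        support = {
            frozenset((ids[i], ids[j]))
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if abs(theta[i, j]) > 1e-12
        }
        assert support == truth.true_edge_set()
        assert np.linalg.eigvalsh(theta)[0] > 0

    def test_network_block_covariance_converges(self, small_config):
        # with EMP coupling off, the sample correlation of the network block
        # converges to the inverse of the planted precision matrix
        base = dataclasses.replace(small_config, n_emp_associated=0, seed=5)
        theta = sample_dataset(base)[3].precision_matrix
        cov = np.linalg.inv(theta)
        d = 1 / np.sqrt(np.diag(cov))
        target = cov * np.outer(d, d)
        devs = []
        for n in (50, 5000):
            cfg = dataclasses.replace(base, n_samples=n)
            expr = sample_dataset(cfg)[0]
            block = expr.values[: base.n_network].T
            emp_corr = np.corrcoef(block, rowvar=False)
            devs.append(np.abs(emp_corr - target).max())
        assert devs[1] < devs[0]
        assert devs[1] < 0.1

    def test_emp_is_lognormal_linear_in_associated_features(self, small_config):
        # log-EMP must equal a linear function of the associated features
        # plus noise independent of them: the implied coefficients in the
        # truth object must be recovered by least squares at large n
        cfg = dataclasses.replace(small_config, n_samples=6000, seed=3)
        expr, samples, _, truth = sample_dataset(cfg)
        na = len(truth.emp_associated)
        idx = [expr.feature_ids.index(f) for f in truth.emp_associated]
        x = expr.values[idx].T
        # undo the per-feature affine intensity scaling
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        y = samples["log_emp"].to_numpy()
        beta_hat = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), x]), y, rcond=None
        )[0][1:]
        beta_true = np.array([truth.emp_coefficients[f] for f in truth.emp_associated])
        assert np.abs(beta_hat - beta_true).max() < 0.12
        assert (samples["emp_per_ul"] > 0).all()

    def test_all_zero_coupling_gives_constant_free_screen(self, small_config):
        # beta = 0 and noise sd -> 0 makes EMP essentially constant
        cfg = dataclasses.replace(
            small_config,
            assoc_strength_range=(0.0, 0.0),
            emp_factor_scale=0.0,
            emp_noise_sd=0.0,
        )
        _, samples, _, _ = sample_dataset(cfg)
        assert samples["log_emp"].std() == pytest.approx(0.0, abs=1e-12)

    def test_detection_forces_unexpressed_features_out(self, small_config):
        expr, _, _, _ = sample_dataset(small_config)
        below = expr.detected[small_config.n_expressed:]
        assert not below.any()

    def test_inconsistent_config_names_field(self):
        cfg = SyntheticConfig(n_network=50, n_emp_associated=20)
        with pytest.raises(ValueError, match="n_emp_associated"):
            cfg.validate()
        cfg = SyntheticConfig(enriched_overlap=200)
        with pytest.raises(ValueError, match="enriched_overlap"):
            cfg.validate()
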