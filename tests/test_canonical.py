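import numpy as np
import pytest

from factor_entropy import (
    FactorModelError,
    GroupSpec,
    build_model,
    canonical_decomposition,
    kl_contribution,
    subgroup_analysis,
    transform_model,
)
from tests.conftest import random_models


def brute_force_contributions(model, idx):
    """Independent oracle: eigenvalues of Lambda_a^T Omega_a^-1 Lambda_a Phi.

    Uses the plain (non-symmetric) product and scipy's general eigensolver,
    sharing no code path with the Cholesky-whitened implementation.
    """
    import scipy.linalg

    lam, omega = model.loadings[idx], model.unique_vars[idx]
    a_phi = lam.T @ np.diag(1.0 / omega) @ lam @ model.factor_corr
    vals = scipy.linalg.eigvals(a_phi)
    return np.sort(np.real(vals))[::-1]


class TestFullVector:
    def test_five_subject_model_canonical_pairs(self, example1):
        # oracle eigenvalues of ((3.1365, 1.297), (1.297, 6.6072))
        dec = canonical_decomposition(example1)
        expected = brute_force_contributions(example1, list(range(5)))
        np.testing.assert_allclose(dec.contributions, expected, atol=1e-10)
        np.testing.assert_allclose(dec.rho_sq, [0.876, 0.730], atol=5e-4)
        np.testing.assert_allclose(dec.contributions, [7.04, 2.71], atol=5e-3)
        np.testing.assert_allclose(
            dec.pairs[0].factor_coeffs, [0.32, 0.95], atol=5e-3
        )

    def test_pair_normalization_and_orientation(self, example1):
        sigma = example1.implied_covariance()
        phi = example1.factor_corr
        for pair in canonical_decomposition(example1).pairs:
            f, b = pair.factor_coeffs, pair.manifest_coeffs
            assert f @ phi @ f == pytest.approx(1.0, abs=1e-10)
            assert b @ sigma @ b == pytest.approx(1.0, abs=1e-10)
            # corr(V_j, eta_j) equals +rho_j under the sign convention
            corr = b @ example1.loadings @ phi @ f
            assert corr == pytest.approx(pair.rho, abs=1e-10)
            assert f[np.argmax(np.abs(f))] > 0

    def test_contribution_identity_and_ordering(self):
        for model in random_models(200, seed=31):
            dec = canonical_decomposition(model)
            # trace identity: contributions sum to the KL total
            assert abs(dec.contributions.sum() - dec.total_kl) < 1e-8 * max(
                1.0, dec.total_kl
            )
            assert np.all(np.diff(dec.rho_sq) <= 1e-12)
            for pair in dec.pairs:
                assert pair.contribution == pytest.approx(
                    pair.rho_sq / (1 - pair.rho_sq), abs=1e-12 * (1 + pair.contribution)
                )

    def test_single_factor_model_closed_form(self):
        lam = np.array([[0.6], [0.5], [0.7]])
        model = build_model(lam, recompute_uniqueness=True)
        dec = canonical_decomposition(model)
        expected = float(np.sum(lam[:, 0] ** 2 / model.unique_vars))
        assert len(dec.pairs) == 1
        assert dec.pairs[0].contribution == pytest.approx(expected, rel=1e-12)

    def test_per_variable_multiple_correlation_identity(self):
        # sum_j rho_j^2/(1-rho_j^2) = sum_i R_i^2/(1-R_i^2) with
        # R_i^2 = communality_i / Sigma_ii
        for model in random_models(50, seed=41):
            dec = canonical_decomposition(model)
            sigma = model.implied_covariance()
            r_sq = model.communalities() / np.diag(sigma)
            assert dec.contributions.sum() == pytest.approx(
                np.sum(r_sq / (1 - r_sq)), abs=1e-8 * (1 + dec.total_kl)
            )


class TestInvariance:
    def test_factor_transform_leaves_canonical_structure(self, example1):
        rng = np.random.default_rng(8)
        base = canonical_decomposition(example1).rho_sq
        for _ in range(50):
            q = rng.normal(size=(2, 2))
            while abs(np.linalg.det(q)) < 0.1:
                q = rng.normal(size=(2, 2))
            transformed = transform_model(example1, q)
            np.testing.assert_allclose(
                canonical_decomposition(transformed).rho_sq, base, atol=1e-8
            )

    def test_manifest_rescaling_leaves_canonical_structure(self):
        rng = np.random.default_rng(9)
        for model in random_models(20, seed=53):
            base = canonical_decomposition(model).rho_sq
            scale = rng.uniform(0.2, 5.0, size=model.p)
            rescaled = build_model(
                model.loadings * scale[:, None],
                factor_corr=model.factor_corr,
                unique_vars=model.unique_vars * scale**2,
            )
            np.testing.assert_allclose(
                canonical_decomposition(rescaled).rho_sq, base, atol=1e-8
            )


class TestSubsets:
    def test_liberal_arts_subset_of_five_subject_model(self, example1):
        dec = canonical_decomposition(example1, ["X1", "X2", "X3"])
        np.testing.assert_allclose(dec.contributions, [3.274, 0.140], atol=5e-4)
        np.testing.assert_allclose(dec.pairs[0].factor_coeffs, [0.95, 0.32], atol=5e-3)

    def test_pair_count_capped_by_subset_size(self, example1):
        assert len(canonical_decomposition(example1, ["X1"]).pairs) == 1
        assert len(canonical_decomposition(example1, ["X1", "X2"]).pairs) == 2

    def test_single_variable_group_closed_form(self):
        # for one manifest variable rho^2 is communality/Sigma_ii exactly
        for model in random_models(20, seed=61):
            sigma = model.implied_covariance()
            i = model.p // 2
            dec = canonical_decomposition(model, [i])
            expected = model.communalities()[i] / sigma[i, i]
            assert dec.pairs[0].rho_sq == pytest.approx(expected, abs=1e-12)

    def test_empty_subset_rejected(self, example1):
        with pytest.raises(FactorModelError, match="non-empty"):
            canonical_decomposition(example1, [])


class TestSubgroupAnalysis:
    def test_six_score_model_three_groups(self, example2, example2_groups):
        decs = subgroup_analysis(example2, example2_groups)
        leading = [decs[name].rho_sq[0] for name in ("g", "problem", "verbal")]
        np.testing.assert_allclose(leading, [0.546, 0.826, 0.959], atol=5e-3)

    def test_partition_grand_sum_is_total_kl(self, example1, example1_groups):
        decs = subgroup_analysis(example1, example1_groups)
        grand = sum(dec.contributions.sum() for dec in decs.values())
        assert grand == pytest.approx(kl_contribution(example1), abs=1e-8)
        # frozen hand values: 3.274 + 0.140 + 6.164 + 0.167
        assert grand == pytest.approx(9.744, abs=5e-4)

    def test_partition_grand_sum_on_random_models(self):
        rng = np.random.default_rng(77)
        for model in random_models(50, seed=71):
            perm = rng.permutation(model.p)
            cut = int(rng.integers(1, model.p))
            groups = GroupSpec({"a": perm[:cut].tolist(), "b": perm[cut:].tolist()})
            decs = subgroup_analysis(model, groups)
            grand = sum(dec.contributions.sum() for dec in decs.values())
            assert grand == pytest.approx(
                kl_contribution(model), abs=1e-8 * (1 + grand)
            )

    def test_single_group_matches_full_decomposition(self, example1):
        full = canonical_decomposition(example1)
        via_groups = subgroup_analysis(
            example1, GroupSpec({"all": list(range(5))})
        )["all"]
        np.testing.assert_allclose(via_groups.rho_sq, full.rho_sq, atol=1e-14)

    def test_overlapping_groups_flagged(self, example1):
        with pytest.warns(UserWarning, match="partition"):
            subgroup_analysis(example1, GroupSpec({"a": [0, 1], "b": [1, 2, 3, 4]}))


class TestSampleCCAOracle:
    def test_sample_canonical_correlations_match_population(self, example1):
        # independent route: statsmodels CCA on simulated joint draws
        from statsmodels.multivariate.cancorr import CanCorr

        from factor_entropy import sample_observations

        n = 200_000
        draws = sample_observations(example1, n, seed=2024)
        x, xi = draws[:, :5], draws[:, 5:]
        sample_rho = CanCorr(xi, x).cancorr
        pop_rho = np.sqrt(canonical_decomposition(example1).rho_sq)
        # analytic large-sample SE of a correlation: (1 - rho^2)/sqrt(n)
        se = (1 - pop_rho**2) / np.sqrt(n)
        np.testing.assert_array_less(np.abs(sample_rho - pop_rho), 3 * se)
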