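"""Inversion: analytic evidence oracle, monotonicity, priors, recovery basics."""

import numpy as np
import pytest

from dcmv0.forward_model import BOLDTimeSeries
from dcmv0.inversion import (
    InversionOptions,
    Priors,
    default_priors,
    fit_nonlinear_gaussian,
    log_evidence,
    variational_laplace,
)
from dcmv0.model_space import ArchitectureMask, enumerate_architectures
from dcmv0.synthetic_data import V0_SETS

MASKS = enumerate_architectures("study13")
TRUE_MASK = MASKS[2]


class TestLinearGaussianOracle:
    """On a linear forward model with known noise, variational Laplace is
    exact: posterior moments match the conjugate closed form and the free
    energy equals the marginal likelihood."""

    @pytest.fixture(scope="class")
    @staticmethod
    def problem():
        rng = np.random.default_rng(3)
        T, p = 60, 4
        X = rng.standard_normal((T, p))
        sigma = 0.4
        theta = rng.standard_normal(p)
        y = (X @ theta + sigma * rng.standard_normal(T))[:, None]
        S0 = np.diag(rng.uniform(0.5, 3.0, p))
        m0 = rng.standard_normal(p) * 0.3
        priors = Priors(names=tuple("abcd"), mean=m0, cov=S0)

        def predict(th):
            return (np.atleast_2d(th) @ X.T)[:, :, None]

        opts = InversionOptions(fixed_precision=1.0 / sigma**2, tol=1e-12, max_iter=64)
        post = fit_nonlinear_gaussian(predict, y, priors, opts)
        return X, y[:, 0], sigma, m0, S0, post

    def test_posterior_moments_match_conjugate_form(self, problem):
        X, y, sigma, m0, S0, post = problem
        Sn = np.linalg.inv(np.linalg.inv(S0) + X.T @ X / sigma**2)
        mn = Sn @ (np.linalg.inv(S0) @ m0 + X.T @ y / sigma**2)
        assert post.mean == pytest.approx(mn, abs=1e-8)
        assert post.cov == pytest.approx(Sn, abs=1e-8)

    def test_free_energy_equals_analytic_log_evidence(self, problem):
        X, y, sigma, m0, S0, post = problem
        T = y.size
        K = sigma**2 * np.eye(T) + X @ S0 @ X.T
        r = y - X @ m0
        logz = (
            -0.5 * T * np.log(2 * np.pi)
            - 0.5 * np.linalg.slogdet(K)[1]
            - 0.5 * r @ np.linalg.solve(K, r)
        )
        assert log_evidence(post) == pytest.approx(logz, abs=1e-6)


class TestDefaultPriors:
    def test_disallowed_couplings_absent(self):
        pri = default_priors(MASKS[6], V0_SETS["set1"])  # A1->A2 only
        a_names = [n for n in pri.names if n.startswith("A:")]
        assert a_names == ["A:A1->A2"]

    def test_allowed_couplings_zero_mean(self):
        pri = default_priors(TRUE_MASK, V0_SETS["set1"])
        assert np.all(pri.mean == 0)
        assert len([n for n in pri.names if n.startswith("A:")]) == 4

    def test_v0_clamped_not_free(self):
        pri = default_priors(TRUE_MASK, (0.04, 0.04, 0.04))
        assert not any("V_0" in n for n in pri.names)
        assert pri.fixed["V_0:A2"] == 0.04

    def test_hemo_parameters_have_tight_priors(self):
        pri = default_priors(TRUE_MASK, V0_SETS["set1"])
        var = np.diag(pri.cov)
        hemo_idx = [i for i, n in enumerate(pri.names) if n.startswith("log_")]
        assert np.all(var[hemo_idx] == 0.015)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            default_priors(TRUE_MASK, V0_SETS["set1"], coupling_var=0.0)


class TestVariationalLaplace:
    def test_self_consistency_at_prior_mean(self, study_dataset):
        # Data generated noise-free from the prior means (zero couplings)
        # leave the posterior at the prior: zero complexity.
        pri = default_priors(TRUE_MASK, V0_SETS["set1"])
        zero = BOLDTimeSeries(
            tr=2.0, values=np.zeros((120, 3)), region_names=("A1", "A2", "A3")
        )
        post = variational_laplace(zero, study_dataset.design, TRUE_MASK, pri)
        assert post.mean == pytest.approx(pri.mean, abs=1e-6)

    def test_free_energy_trace_monotone_on_accepted_steps(self, study_dataset):
        pri = default_priors(TRUE_MASK, V0_SETS["set1"])
        post = variational_laplace(
            study_dataset.noisy, study_dataset.design, TRUE_MASK, pri
        )
        assert post.converged
        assert np.all(np.diff(post.trace) >= 0)

    def test_deterministic_bit_identical(self, study_dataset):
        pri = default_priors(MASKS[6], V0_SETS["set1"])
        kw = dict(
            data=study_dataset.noisy,
            design=study_dataset.design,
            mask=MASKS[6],
            priors=pri,
        )
        p1, p2 = variational_laplace(**kw), variational_laplace(**kw)
        assert np.array_equal(p1.mean, p2.mean)
        assert np.array_equal(p1.cov, p2.cov)
        assert p1.free_energy == p2.free_energy
        assert p1.trace == p2.trace

    def test_couplings_recovered_under_correct_v0(self, study_dataset):
        pri = default_priors(TRUE_MASK, V0_SETS["set1"])
        post = variational_laplace(
            study_dataset.noisy, study_dataset.design, TRUE_MASK, pri
        )
        for name in ("A:A1->A2", "A:A2->A1", "A:A1->A3", "A:A3->A1"):
            assert abs(post[name] - 1.0) < 0.3

    def test_absent_couplings_shrink_toward_zero(self, clean_dataset):
        # noise-free: the lateral couplings absent from the generating model
        # must shrink to (near) zero in the full model's posterior
        full = MASKS[12]
        pri = default_priors(full, V0_SETS["set1"])
        post = variational_laplace(clean_dataset.clean, clean_dataset.design, full, pri)
        assert abs(post["A:A2->A3"]) < 0.3
        assert abs(post["A:A3->A2"]) < 0.3

    def test_true_architecture_beats_disconnected_regions(self, study_dataset):
        pri = default_priors(TRUE_MASK, V0_SETS["set1"])
        f_true = variational_laplace(
            study_dataset.noisy, study_dataset.design, TRUE_MASK, pri
        ).free_energy
        isolated = ArchitectureMask(
            a_mask=np.eye(3, dtype=bool),
            c_mask=np.array([[True], [False], [False]]),
            label="isolated",
            index=0,
        )
        f_null = variational_laplace(
            study_dataset.noisy,
            study_dataset.design,
            isolated,
            default_priors(isolated, V0_SETS["set1"]),
        ).free_energy
        assert f_true > f_null + 100.0

    def test_irrelevant_coupling_costs_bounded_occam_penalty(self, clean_dataset):
        # On noise-free data a superset of the generating model may not gain:
        # F(superset) <= F(true); the loss is the Occam penalty of the extra
        # parameter and must be finite and modest.
        opts = InversionOptions(tol=1e-4, max_iter=128)
        f_true = variational_laplace(
            clean_dataset.clean,
            clean_dataset.design,
            TRUE_MASK,
            default_priors(TRUE_MASK, V0_SETS["set1"]),
            opts,
        ).free_energy
        superset = MASKS[9]  # generating + lateral A2->A3
        f_sup = variational_laplace(
            clean_dataset.clean,
            clean_dataset.design,
            superset,
            default_priors(superset, V0_SETS["set1"]),
            opts,
        ).free_energy
        assert f_sup <= f_true
        assert f_true - f_sup < 20.0

    def test_identical_model_identical_evidence(self, study_dataset):
        pri = default_priors(MASKS[6], V0_SETS["set2"])
        f1 = variational_laplace(
            study_dataset.noisy, study_dataset.design, MASKS[6], pri
        )
        f2 = variational_laplace(
            study_dataset.noisy, study_dataset.design, MASKS[6], pri
        )
        assert log_evidence(f1) - log_evidence(f2) == 0.0

    def test_data_design_length_mismatch(self, study_dataset, short_design):
        pri = default_priors(TRUE_MASK, V0_SETS["set1"])
        with pytest.raises(ValueError, match="does not match"):
            variational_laplace(study_dataset.noisy, short_design, TRUE_MASK, pri)
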