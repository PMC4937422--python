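"""Forward-model unit and property tests: drifts, BOLD equation, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcmv0.forward_model import (
    DEFAULT_SELF_CONNECTION,
    ConnectivityParameters,
    HemodynamicParameters,
    IntegrationDivergedError,
    StimulusDesign,
    bold_coefficients,
    bold_from_states,
    hemodynamic_drift,
    integrate_dcm,
    neuronal_drift,
)
from dcmv0.sensitivity import evaluate_bold_responses


class TestNeuronalDrift:
    def test_rest_is_fixed_point(self, study_connectivity):
        dz = neuronal_drift(np.zeros(3), np.zeros(1), study_connectivity)
        assert np.all(dz == 0)

    def test_direct_input_only(self):
        conn = ConnectivityParameters(A=[[-0.5]], C=[[1.0]])
        dz = neuronal_drift(np.zeros(1), np.ones(1), conn)
        assert dz == pytest.approx([1.0])

    def test_matches_hand_computed_matrix_vector_product(self, study_connectivity):
        # A has self -1.5 and unit couplings A1<->A2, A1<->A3; with
        # z = (1,1,1): row A1 = -1.5+1+1, rows A2/A3 = 1-1.5.
        dz = neuronal_drift(np.ones(3), np.zeros(1), study_connectivity)
        assert dz == pytest.approx([0.5, -0.5, -0.5])

    def test_linear_in_z_for_fixed_input(self, study_connectivity):
        rng = np.random.default_rng(0)
        z1, z2 = rng.standard_normal((2, 3))
        u = np.array([1.0])
        lhs = neuronal_drift(z1 + z2, u, study_connectivity)
        rhs = (
            neuronal_drift(z1, u, study_connectivity)
            + neuronal_drift(z2, u, study_connectivity)
            - neuronal_drift(np.zeros(3), u, study_connectivity)
        )
        assert lhs == pytest.approx(rhs)

    def test_shape_mismatch_raises(self, study_connectivity):
        with pytest.raises(ValueError, match="shape"):
            neuronal_drift(np.zeros(2), np.zeros(1), study_connectivity)
        with pytest.raises(ValueError, match="shape"):
            neuronal_drift(np.zeros(3), np.zeros(2), study_connectivity)

    def test_positive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            ConnectivityParameters(A=[[0.5]], C=[[1.0]])


class TestHemodynamicDrift:
    def test_resting_fixed_point(self, default_hemo):
        d = hemodynamic_drift((0.0, 1.0, 1.0, 1.0), 0.0, default_hemo)
        # zero up to the rounding of (1 - E_0) in the extraction ratio
        assert d == pytest.approx(np.zeros(4), abs=1e-15)

    def test_only_signal_equation_sees_neuronal_state(self, default_hemo):
        d = hemodynamic_drift((0.0, 1.0, 1.0, 1.0), 1.0, default_hemo)
        assert d[0] == pytest.approx(default_hemo.epsilon)
        assert d[1:] == pytest.approx(np.zeros(3), abs=1e-15)

    def test_extraction_ratio_is_unity_at_rest(self):
        # E(f=1, E_0) = E_0 exactly, so the q-equation's E/E_0 ratio is 1.
        e0 = 0.32
        assert 1.0 - (1.0 - e0) ** (1.0 / 1.0) == pytest.approx(e0)

    def test_nonpositive_state_rejected(self, default_hemo):
        with pytest.raises(ValueError, match="positive"):
            hemodynamic_drift((0.0, -1.0, 1.0, 1.0), 0.0, default_hemo)

    @pytest.mark.parametrize(
        "kwargs",
        [{"tau_0": -1.0}, {"alpha": 1.5}, {"E_0": 0.0}, {"V_0": 1.0}],
    )
    def test_parameter_domain_validation(self, kwargs):
        with pytest.raises(ValueError):
            HemodynamicParameters(**kwargs)


class TestBoldEquation:
    def test_zero_at_rest(self, default_hemo):
        assert bold_from_states(1.0, 1.0, default_hemo) == 0.0

    def test_hand_evaluated_value(self):
        # y = 0.04*(2.24*(1-0.9) + 2*(1-0.9/1.1) + 0.44*(1-1.1)) = 0.0239*...
        h = HemodynamicParameters(E_0=0.32, V_0=0.04)
        y = bold_from_states(1.1, 0.9, h, field_coeffs=(2.24, 2.0, 0.44))
        assert y == pytest.approx(0.04 * 5.98 / 11.0, rel=1e-12)

    def test_doubling_v0_doubles_signal(self):
        h1 = HemodynamicParameters(V_0=0.02)
        h2 = HemodynamicParameters(V_0=0.04)
        y1 = bold_from_states(1.07, 0.91, h1)
        y2 = bold_from_states(1.07, 0.91, h2)
        assert y2 == pytest.approx(2.0 * y1, rel=1e-14)

    @settings(derandomize=True, max_examples=50)
    @given(
        v=st.floats(0.5, 2.0),
        q=st.floats(0.5, 2.0),
        scale=st.floats(1.1, 20.0),
    )
    def test_exact_linearity_in_v0(self, v, q, scale):
        h = HemodynamicParameters(V_0=0.01)
        hs = HemodynamicParameters(V_0=0.01 * scale)
        y, ys = bold_from_states(v, q, h), bold_from_states(v, q, hs)
        assert ys == pytest.approx(scale * y, rel=1e-12, abs=1e-300)

    def test_default_coefficients(self):
        k1, k2, k3 = bold_coefficients(0.32)
        assert (k1, k2, k3) == pytest.approx((2.24, 2.0, 0.44))


class TestIntegration:
    def test_zero_input_stays_at_rest(self, study_connectivity):
        design = StimulusDesign(
            tr=2.0, n_scans=10, dt=0.125, inputs=np.zeros((1, 160))
        )
        hemo = [HemodynamicParameters()] * 3
        traj, bold = integrate_dcm(design, study_connectivity, hemo)
        assert np.all(bold.values == 0)
        assert np.all(traj.z == 0) and np.all(traj.f == 1)

    def test_starts_at_resting_state(self, short_design, study_connectivity):
        hemo = [HemodynamicParameters()] * 3
        traj, _ = integrate_dcm(short_design, study_connectivity, hemo)
        assert traj.z[0] == pytest.approx([0, 0, 0])
        assert traj.v[0] == pytest.approx([1, 1, 1])
        assert np.all(traj.f > 0) and np.all(traj.v > 0) and np.all(traj.q > 0)

    def test_grid_convergence_order_at_least_one(
        self, short_design, study_connectivity
    ):
        hemo = [HemodynamicParameters()] * 3
        ref = integrate_dcm(short_design, study_connectivity, hemo, dt=0.015625)[1]
        errs = []
        for dt in (0.25, 0.125, 0.0625):
            b = integrate_dcm(short_design, study_connectivity, hemo, dt=dt)[1]
            errs.append(np.max(np.abs(b.values - ref.values)))
        # halving dt must cut the error by at least 2x (order >= 1); RK4 in
        # fact converges much faster
        assert errs[0] / errs[1] > 2.0 and errs[1] / errs[2] > 2.0
        assert errs[2] < 1e-4

    def test_single_pulse_peaks_between_4_and_7_seconds(self):
        times, y = evaluate_bold_responses(
            HemodynamicParameters().as_array()[None], stim_duration=2.0
        )
        t_peak = times[np.argmax(y[0])]
        assert 4.0 <= t_peak <= 7.0

    def test_states_remain_finite_over_240s(self, study_dataset):
        traj, bold = integrate_dcm(
            study_dataset.design,
            study_dataset.connectivity,
            list(study_dataset.hemodynamics),
        )
        assert np.all(np.isfinite(traj.z))
        assert np.all(np.isfinite(bold.values))

    def test_unstable_network_raises_diverged(self, short_design):
        conn = ConnectivityParameters(
            A=[[-0.1, 5.0], [5.0, -0.1]], C=[[1.0], [0.0]]
        )
        hemo = [HemodynamicParameters()] * 2
        with pytest.warns(UserWarning, match="unstable"):
            with pytest.raises(IntegrationDivergedError):
                design = StimulusDesign(
                    tr=2.0,
                    n_scans=30,
                    dt=0.125,
                    inputs=short_design.inputs[:1],
                )
                integrate_dcm(design, conn, hemo)

    def test_deterministic_output(self, short_design, study_connectivity):
        hemo = [HemodynamicParameters()] * 3
        b1 = integrate_dcm(short_design, study_connectivity, hemo)[1]
        b2 = integrate_dcm(short_design, study_connectivity, hemo)[1]
        assert np.array_equal(b1.values, b2.values)

    def test_compiled_and_numpy_engines_agree(
        self, short_design, study_connectivity, monkeypatch
    ):
        from dcmv0 import _engine

        hemo = [HemodynamicParameters()] * 3
        fast = integrate_dcm(short_design, study_connectivity, hemo)[1]
        monkeypatch.setattr(_engine, "HAVE_NUMBA", False)
        slow = integrate_dcm(short_design, study_connectivity, hemo)[1]
        assert slow.values == pytest.approx(fast.values, rel=1e-12, abs=1e-15)
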