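"""Screening: Jacobians, subset selection, sensitivities, error weights."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import linalg

from stagefit.screen import (
    PerturbationGrid,
    aggregate_sensitivities,
    error_weights,
    relative_sensitivity_tensor,
    residual_jacobian,
    screen,
    subset_selection_rank,
)
from conftest import ToyLinearModel, toy_protocol


def central_difference_jacobian(model, params, protocol, level, candidates, fd_step):
    """Independent central-difference oracle for the residual Jacobian."""
    from stagefit.screen import _simulate_level

    jac = np.empty((len(model.variables.names), len(candidates)))
    for j, name in enumerate(candidates):
        step = max(fd_step * abs(params[name]), 1e-9)
        hi, lo = dict(params), dict(params)
        hi[name] += step
        lo[name] -= step
        y_hi = _simulate_level(model, hi, protocol, level)
        y_lo = _simulate_level(model, lo, protocol, level)
        jac[:, j] = -(y_hi - y_lo) / (2 * step)
    return jac


class TestResidualJacobian:
    def test_independent_output_gives_zero_column(self):
        # y1 depends only on u1, y2 only on u2; column cross-terms vanish
        model = ToyLinearModel(np.diag([2.0, 3.0]))
        jac = residual_jacobian(
            model, np.zeros(2), model.registry.nominal_values(), toy_protocol(), 0
        )
        assert jac[0, 1] == 0.0 and jac[1, 0] == 0.0

    def test_linear_model_recovers_analytic_derivative(self):
        model = ToyLinearModel([[3.5]])
        jac = residual_jacobian(
            model,
            np.zeros(1),
            model.registry.nominal_values(),
            toy_protocol(),
            0,
            fd_step=1e-6,
        )
        # r = y_exp - a u  ->  dr/du = -a
        assert jac[0, 0] == pytest.approx(-3.5, rel=1e-6)

    def test_variation_shifts_linearization_point(self):
        # y = u^2: derivative at (1+h) u is 2 (1+h) u
        class Quad(ToyLinearModel):
            def steady_state(self, params, vo2, vco2):
                return {"y1": params["u1"] ** 2}

        model = Quad([[1.0]])
        jac = residual_jacobian(
            model, np.zeros(1), model.registry.nominal_values(),
            toy_protocol(), 0, variation=0.05,
        )
        assert jac[0, 0] == pytest.approx(-2.1, rel=1e-4)

    def test_forward_matches_central_difference_on_minicr(self, minicr, protocol3):
        params = minicr.registry.nominal_values()
        candidates = ["Gc", "Rtot", "BF0", "kHR"]
        for level in range(protocol3.n_levels):
            fwd = residual_jacobian(
                minicr, np.zeros(10), params, protocol3, level,
                candidates=candidates, fd_step=1e-6,
            )
            cen = central_difference_jacobian(
                minicr, params, protocol3, level, candidates, 1e-6
            )
            scale = np.abs(cen).max()
            assert np.all(np.abs(fwd - cen) <= 1e-4 * scale)


class TestSubsetSelection:
    def _rank(self, jac, eps=1e-6, names=None):
        names = names or [f"u{j + 1}" for j in range(jac.shape[1])]
        return subset_selection_rank({(0, 0): jac}, names, [0], [0.05], eps)

    def test_diagonal_jacobian_hand_case(self):
        Z_jkl, Z_jl, Z_j, rho, orderings = self._rank(np.diag([1.0, 0.5]))
        assert rho[(0, 0)] == 2
        assert orderings[(0, 0)] == ["u1", "u2"]
        assert Z_j.tolist() == [1.0, 0.5]

    def test_zero_column_ranked_last_below_tolerance(self):
        jac = np.array([[1.0, 0.0, 0.0], [0.0, 0.5, 0.0]])
        _, _, Z_j, rho, orderings = self._rank(jac)
        assert rho[(0, 0)] == 2
        assert orderings[(0, 0)][-1] == "u3"
        assert Z_j[2] < 1e-6

    def test_collinear_columns_keep_exactly_one(self):
        jac = np.array([[1.0, 1.0], [1.0, 1.0]])
        _, _, _, rho, orderings = self._rank(jac)
        assert rho[(0, 0)] == 1
        estimable = orderings[(0, 0)][: rho[(0, 0)]]
        assert len(set(estimable) & {"u1", "u2"}) == 1

    def test_all_zero_jacobian_rejected(self):
        with pytest.raises(ValueError, match="no identifiable"):
            self._rank(np.zeros((2, 2)))

    def test_full_rank_linear_model_rank_equals_param_count(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 3))
        _, _, _, rho, _ = self._rank(A, eps=1e-10)
        assert rho[(0, 0)] == 3

    def test_pivot_matches_exhaustive_top1_search(self):
        """First pivot equals the exhaustive best single column of the
        projected right-singular-vector matrix (the quantity pivoted QR
        ranks), over a randomized suite of small Jacobians."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            m = int(rng.integers(2, 5))
            n = int(rng.integers(2, 5))
            jac = rng.normal(size=(m, n))
            _, sv, Vt = np.linalg.svd(jac, full_matrices=False)
            r = int(np.sum(sv / sv[0] > 1e-6))
            V_r = Vt[:r, :]
            # exhaustive top-1: largest smallest-singular-value over all
            # 1-column submatrices (= column norm); the pivot must achieve
            # it (ties count as achieving it)
            svals = [
                np.linalg.svd(V_r[:, [j]], compute_uv=False)[0] for j in range(n)
            ]
            _, _, perm = linalg.qr(V_r, pivoting=True, mode="economic")
            assert svals[perm[0]] == pytest.approx(max(svals), abs=1e-12), f"trial {trial}"


class TestSensitivities:
    def test_linear_parameter_map_has_unit_sensitivity(self):
        model = ToyLinearModel(np.diag([2.0, 5.0]))
        s = relative_sensitivity_tensor(
            model, model.registry.nominal_values(), toy_protocol(), PerturbationGrid()
        )
        # proportional map y_i = a_i u_i: own sensitivity 1 (to round-off),
        # cross-sensitivity exactly 0
        assert np.allclose(s[[0, 1], [0, 1], :, :], 1.0, atol=1e-12)
        assert np.all(s[[0, 1], [1, 0], :, :] == 0.0)

    def test_quadratic_map_hand_value(self):
        class Quad(ToyLinearModel):
            def steady_state(self, params, vo2, vco2):
                return {"y1": params["u1"] ** 2}

        model = Quad([[1.0]])
        grid = PerturbationGrid(h=(-0.05, 0.05))
        s = relative_sensitivity_tensor(
            model, model.registry.nominal_values(), toy_protocol(1), grid
        )
        # u^2 at u=1, h=+0.05: DY = 0.1025 -> s = 2.05
        assert s[0, 0, 1, 0] == pytest.approx(2.05, abs=1e-12)

    def test_degenerate_reference_rejected(self):
        model = ToyLinearModel([[1.0]], intercept=-1.0)  # y = u - 1 = 0 at nominal
        with pytest.raises(ValueError, match="level"):
            relative_sensitivity_tensor(
                model, model.registry.nominal_values(), toy_protocol(1), PerturbationGrid()
            )

    def test_rms_aggregation_hand_values(self):
        # constant 1 over variations -> 1; {3, 4} -> sqrt(25/2)
        s = np.zeros((1, 2, 2, 1))
        s[0, 0] = 1.0
        s[0, 1, 0, 0], s[0, 1, 1, 0] = 3.0, 4.0
        P_ik = np.ones((1, 1))
        P_i = np.ones(1)
        s_ijk, s_ij, s_j = aggregate_sensitivities(s, P_ik, P_i)
        assert s_ijk[0, 0, 0] == 1.0
        assert s_ijk[0, 1, 0] == pytest.approx(np.sqrt(12.5), abs=1e-12)

    def test_error_weights_hand_values(self):
        y_exp = np.array([[1.0, 1.0]])
        y_sim = np.array([[0.9, 0.7]])
        E_ik, E_iT, P_ik, E_i, P_i, E_T = error_weights(y_exp, y_sim)
        assert E_ik[0].tolist() == pytest.approx([0.1, 0.3])
        assert E_iT[0] == pytest.approx(0.2)
        assert P_ik[0].tolist() == pytest.approx([0.25, 0.75])
        assert P_ik.sum() == pytest.approx(1.0, abs=1e-14)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_weight_normalization_property(self, seed):
        rng = np.random.default_rng(seed)
        I, K = int(rng.integers(1, 8)), int(rng.integers(1, 6))
        y_exp = rng.uniform(0.5, 10.0, size=(I, K))
        y_sim = y_exp * rng.uniform(0.5, 1.5, size=(I, K))
        _, _, P_ik, _, P_i, _ = error_weights(y_exp, y_sim)
        assert np.allclose(P_ik.sum(axis=1), 1.0, atol=1e-12)
        assert P_i.sum() == pytest.approx(1.0, abs=1e-12)


class TestEndToEndScreen:
    def test_scale_invariance_of_rankings(self, minicr, perturbed_cohort):
        """Rescaling a variable's units (data and simulation together)
        leaves sensitivities, weights and rankings unchanged."""
        base = screen(minicr, perturbed_cohort)
        scaled = perturbed_cohort.observations.copy()
        mask = scaled["variable"] == "HR"
        scaled.loc[mask, "value"] *= 60.0  # beats/min -> beats/s... any unit

        class ScaledModel:
            def __init__(self, inner):
                self._m = inner
                self.name = inner.name
                self.registry = inner.registry
                self.variables = inner.variables
                self.related_subsystems = inner.related_subsystems

            def steady_state(self, params, vo2, vco2):
                out = self._m.steady_state(params, vo2, vco2)
                out["HR"] *= 60.0
                return out

            def time_constant(self, v, p):
                return self._m.time_constant(v, p)

            def initial_state(self, p, f):
                return self._m.initial_state(p, f)

        ds2 = perturbed_cohort
        from stagefit.cohort import SteadyStateDataset

        ds2 = SteadyStateDataset(
            observations=scaled,
            protocol=ds2.protocol,
            covariates=ds2.covariates,
            at=ds2.at,
        )
        other = screen(ScaledModel(minicr), ds2)
        assert np.allclose(other.s_ijlk, base.s_ijlk, rtol=1e-9)
        assert np.allclose(other.P_ik, base.P_ik, rtol=1e-9)
        assert [n for n, _ in other.total_ranking()] == [
            n for n, _ in base.total_ranking()
        ]

    def test_screening_result_round_trip_fields(self, minicr, perturbed_cohort, tmp_path):
        res = screen(minicr, perturbed_cohort)
        res.to_json(tmp_path / "screen.json")
        assert (tmp_path / "screen.json").stat().st_size > 0
        frame = res.rankings_frame()
        assert set(frame["ranking"]) == {"subset_selection", "total_sensitivity"}
        # every candidate appears once per ranking
        assert len(frame) == 2 * len(res.candidates)
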