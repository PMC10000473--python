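"""Selection approaches: role filter, standardization, base/specific/stimulus."""

import numpy as np
import pytest

from stagefit.cohort import SteadyStateDataset
from stagefit.model import ParameterRegistry, ParameterSpec
from stagefit.screen import ScreeningResult, screen
from stagefit.select import (
    SelectionPlan,
    build_selection_plan,
    reduction_percent,
    role_filter,
    select_base,
    select_specific,
    select_stimulus,
    standardize,
)


def make_screening(candidates, Z_j, s_j, subsystems, variables=("y1",), s_ij=None):
    """Minimal ScreeningResult for selection-rule tests."""
    J, I = len(candidates), len(variables)
    if s_ij is None:
        s_ij = np.tile(np.asarray(s_j, dtype=float), (I, 1))
    return ScreeningResult(
        candidates=list(candidates),
        variables=list(variables),
        levels=[0],
        h=[0.05],
        epsilon=1e-6,
        Z_jkl=np.zeros((J, 1, 1)),
        Z_jl=np.zeros((J, 1)),
        Z_j=np.asarray(Z_j, dtype=float),
        rho={},
        orderings={},
        s_ijlk=np.zeros((I, J, 1, 1)),
        s_ijk=np.zeros((I, J, 1)),
        s_ij=np.asarray(s_ij, dtype=float),
        s_j=np.asarray(s_j, dtype=float),
        P_ik=np.ones((I, 1)),
        P_i=np.full(I, 1.0 / I),
        E_ik=np.ones((I, 1)),
        E_iT=np.ones(I),
        E_i=np.ones(I),
        E_T=1.0,
        param_subsystems=dict(zip(candidates, subsystems)),
    )


def full_scale_registry():
    """A registry with the role distribution of a large cardiorespiratory
    model: 12 covariates, 1 conversion, 239 gains/thresholds (1 excluded),
    24 initial values, 40 time constants = 316 parameters."""
    specs = []
    for i in range(12):
        specs.append(ParameterSpec(f"cov{i}", 1.0, "covariate", "gas_exchange"))
    specs.append(ParameterSpec("conv0", 863.0, "conversion", "gas_exchange"))
    for i in range(239):
        specs.append(
            ParameterSpec(
                f"g{i}", 1.0, "gain_threshold", "cardiovascular_system",
                excluded=(i == 0),
            )
        )
    for i in range(24):
        specs.append(ParameterSpec(f"iv{i}", 0.0, "initial_value", "gas_exchange"))
    for i in range(40):
        specs.append(ParameterSpec(f"tc{i}", 10.0, "time_constant", "gas_exchange"))
    return ParameterRegistry(specs)


class TestRoleFilterAndCounts:
    def test_large_registry_counts(self):
        reg = full_scale_registry()
        assert len(reg) == 316
        candidates, covariates = role_filter(reg)
        assert len(candidates) == 238  # 239 gains minus the excluded one
        assert len(covariates) == 12

    def test_registry_of_only_time_constants_yields_no_candidates(self):
        reg = ParameterRegistry(
            [ParameterSpec(f"tc{i}", 1.0, "time_constant", "s") for i in range(3)]
        )
        assert role_filter(reg) == ([], [])

    def test_excluded_gain_absent_from_candidates(self, minicr):
        candidates, _ = role_filter(minicr.registry)
        assert "PP0" not in candidates

    @pytest.mark.parametrize(
        "n_stage, total, expected",
        [
            (216, 316, 31.6),  # standardization leaves 216 of 316
            (9, 316, 97.2),  # specific stage: 9 parameters
            (15, 316, 95.3),  # stimulus stage: 15 parameters
            (8, 316, 97.5),  # base stage: 8 parameters (round-half-away)
        ],
    )
    def test_reduction_percentages(self, n_stage, total, expected):
        assert reduction_percent(n_stage, total) == expected


class TestStandardize:
    def _dataset(self, minicr, protocol3, covariates):
        import pandas as pd

        obs = pd.DataFrame(
            [("S1", 1, 0.3, "VE", 9.0)],
            columns=["subject", "level", "vco2", "variable", "value"],
        )
        return SteadyStateDataset(
            observations=obs, protocol=protocol3, covariates=covariates, at={}
        )

    def test_direct_equivalence(self, minicr, protocol3):
        cov = {n: minicr.registry[n].nominal for n in minicr.registry.covariate_names()}
        cov["FiO2"] = 0.2093
        cov["Patm"] = 640.0
        ds = self._dataset(minicr, protocol3, cov)
        std = standardize(minicr.registry, ds)
        assert std["FiO2"] == 0.2093
        assert std["Patm"] == 640.0
        assert len(std) == 5  # MiniCR declares five covariates

    def test_missing_covariate_named_in_error(self, minicr, protocol3):
        ds = self._dataset(minicr, protocol3, {"FiO2": 0.21})
        with pytest.raises(KeyError, match="FiCO2"):
            standardize(minicr.registry, ds)


class TestSelectBase:
    def test_tolerance_criterion_admits_scores_above_epsilon(self):
        sc = make_screening(
            ["p1", "p2", "p3"], [1.0, 1e-3, 1e-8], [0.5, 0.4, 0.3], ["A", "A", "A"]
        )
        base, prov = select_base(sc, epsilon=1e-6)
        assert base == ["p1", "p2"]
        assert "subset selection" in prov["p1"]

    def test_covered_subsystem_takes_no_extra_parameter(self):
        sc = make_screening(
            ["p1", "p2"], [1.0, 1e-9], [0.1, 0.9], ["A", "A"]
        )
        base, _ = select_base(sc, epsilon=1e-6)
        assert base == ["p1"]  # p2 not taken: A already covered

    def test_coverage_walk_stops_at_last_subsystem(self):
        """Subset criterion admits nothing; the total-sensitivity walk takes
        exactly one parameter per subsystem, skipping repeats."""
        sc = make_screening(
            ["a1", "a2", "b1", "c1", "c2"],
            [1e-9] * 5,
            [0.8, 0.7, 0.6, 0.5, 0.4],
            ["A", "A", "B", "C", "C"],
        )
        base, prov = select_base(sc, epsilon=1e-6)
        assert base == ["a1", "b1", "c1"]
        assert all("coverage" in prov[p] for p in base)

    def test_uncoverable_subsystem_is_an_error(self):
        sc = make_screening(["p1"], [1.0], [0.5], ["A"])
        with pytest.raises(ValueError, match="B"):
            select_base(sc, subsystems=["A", "B"])


class TestSelectSpecific:
    def test_disjoint_dominant_parameters(self):
        s_ij = np.array([[1.0, 0.0], [0.0, 1.0]])
        sc = make_screening(
            ["p1", "p2"], [0, 0], [0.5, 0.5], ["A", "B"],
            variables=("v1", "v2"), s_ij=s_ij,
        )
        got, _ = select_specific(
            sc, [], {"v1": "A", "v2": "B"},
            {"A": frozenset({"A"}), "B": frozenset({"B"})},
        )
        assert got == {"v1": "p1", "v2": "p2"}

    def test_cross_sensitive_candidate_loses_to_specific_runner_up(self):
        """p1 tops v1's ranking but is equally sensitive for unrelated v2;
        p2 is slightly less sensitive for v1 with no cross-talk."""
        s_ij = np.array([[1.0, 0.9], [1.0, 0.0]])
        sc = make_screening(
            ["p1", "p2"], [0, 0], [0.5, 0.4], ["A", "A"],
            variables=("v1", "v2"), s_ij=s_ij,
        )
        got, _ = select_specific(
            sc, [], {"v1": "A", "v2": "B"},
            {"A": frozenset({"A"}), "B": frozenset({"B"})},
        )
        assert got["v1"] == "p2"

    def test_base_parameter_skipped(self):
        s_ij = np.array([[1.0, 0.5]])
        sc = make_screening(
            ["p1", "p2"], [0, 0], [0.5, 0.4], ["A", "A"],
            variables=("v1",), s_ij=s_ij,
        )
        got, _ = select_specific(
            sc, ["p1"], {"v1": "A"}, {"A": frozenset({"A"})}
        )
        assert got == {"v1": "p2"}

    def test_conflict_resolved_by_higher_specificity(self):
        """v1 and v2 both propose p1; v1's specificity is higher (v2 pays a
        cross-sensitivity penalty to the unrelated v3), so v2 falls back to
        its runner-up."""
        s_ij = np.array(
            [
                [1.0, 0.2, 0.33],
                [1.0, 0.4, 0.0],
                [0.5, 0.0, 1.0],
            ]
        )
        sc = make_screening(
            ["p1", "p2", "p3"], [0, 0, 0], [0.5, 0.4, 0.3], ["A", "B", "C"],
            variables=("v1", "v2", "v3"), s_ij=s_ij,
        )
        got, _ = select_specific(
            sc,
            [],
            {"v1": "A", "v2": "B", "v3": "C"},
            {
                "A": frozenset({"A", "B", "C"}),
                "B": frozenset({"A", "B"}),
                "C": frozenset({"A", "C"}),
            },
        )
        assert got == {"v1": "p1", "v2": "p2", "v3": "p3"}

    def test_variable_without_admissible_candidate_unassigned(self, caplog):
        s_ij = np.array([[1.0]])
        sc = make_screening(
            ["p1"], [0], [0.5], ["B"], variables=("v1",), s_ij=s_ij
        )
        with caplog.at_level("WARNING"):
            got, _ = select_specific(
                sc, [], {"v1": "A"}, {"A": frozenset({"A"})}
            )
        assert got == {}
        assert "v1" in caplog.text


class TestSelectStimulus:
    def _registry(self):
        return ParameterRegistry(
            [
                ParameterSpec(
                    "g1", 1.0, "gain_threshold", "S",
                    mechanisms=(("M1", "act1"),),
                ),
                ParameterSpec(
                    "g2", 1.0, "gain_threshold", "S",
                    mechanisms=(("M1", "act2"),),
                ),
                ParameterSpec(
                    "g3", 1.0, "gain_threshold", "S",
                    mechanisms=(("M2", "act1"),),
                ),
                ParameterSpec(
                    "g4", 2.0, "gain_threshold", "S",
                    mechanisms=(("M2", "act1"),),
                ),
            ]
        )

    def test_single_free_tagged_parameter_selected(self):
        reg = self._registry()
        got, _ = select_stimulus(reg, [], {}, {"g1": 0.1, "g2": 0.2, "g3": 0.3, "g4": 0.4})
        assert got[("M1", "act1")] == "g1"
        assert got[("M1", "act2")] == "g2"

    def test_taken_parameter_leaves_mechanism_empty(self, caplog):
        reg = self._registry()
        with caplog.at_level("WARNING"):
            got, _ = select_stimulus(
                reg, [], {"v": "g1"}, {"g1": 1.0, "g2": 1.0, "g3": 1.0, "g4": 1.0}
            )
        assert ("M1", "act1") not in got
        assert "M1" in caplog.text

    def test_highest_total_sensitivity_wins_within_activity(self):
        reg = self._registry()
        got, _ = select_stimulus(reg, [], {}, {"g3": 0.1, "g4": 0.9})
        assert got[("M2", "act1")] == "g4"

    def test_one_selection_per_activity_label(self, minicr, perturbed_cohort):
        sc = screen(minicr, perturbed_cohort)
        s_j = dict(zip(sc.candidates, map(float, sc.s_j)))
        got, _ = select_stimulus(minicr.registry, [], {}, s_j)
        tags = {tuple(t) for n in minicr.registry.candidates()
                for t in minicr.registry[n].mechanisms}
        assert set(got) == tags
        assert len(set(got.values())) == len(got)


class TestPlan:
    def test_fitted_sets_disjoint_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            SelectionPlan(base_set=["p1"], specific_set={"v": "p1"})

    def test_end_to_end_plan_deterministic(self, minicr, perturbed_cohort):
        sc1 = screen(minicr, perturbed_cohort)
        sc2 = screen(minicr, perturbed_cohort)
        p1 = build_selection_plan(minicr, perturbed_cohort, sc1)
        p2 = build_selection_plan(minicr, perturbed_cohort, sc2)
        assert p1.base_set == p2.base_set
        assert p1.specific_set == p2.specific_set
        assert p1.stimulus_set == p2.stimulus_set
        # disjointness and exclusion contracts hold on the real pipeline
        sets = p1.stage_sets()
        flat = sets["base"] + sets["specific"] + sets["stimulus"]
        assert len(flat) == len(set(flat))
        assert "PP0" not in flat

    def test_plan_round_trips_through_json(self, minicr, perturbed_cohort, tmp_path):
        sc = screen(minicr, perturbed_cohort)
        plan = build_selection_plan(minicr, perturbed_cohort, sc)
        plan.to_json(tmp_path / "plan.json")
        back = SelectionPlan.from_json(tmp_path / "plan.json")
        assert back.base_set == plan.base_set
        assert back.specific_set == plan.specific_set
        assert back.stimulus_set == plan.stimulus_set
        assert back.standardized == plan.standardized

    def test_minicr_stage_reductions_match_hand_counts(self, minicr, perturbed_cohort):
        sc = screen(minicr, perturbed_cohort)
        plan = build_selection_plan(minicr, perturbed_cohort, sc)
        total = len(minicr.registry)
        for stage, names in plan.stage_sets().items():
            expected = round(100.0 * (1 - len(names) / total), 1)
            assert reduction_percent(len(names), total) == pytest.approx(
                expected, abs=0.05
            )
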