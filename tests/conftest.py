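"""Shared fixtures: the MiniCR demo model, protocols, datasets, and a toy
linear model implementing the simulator contract for analytic oracles."""

from __future__ import annotations

import numpy as np
import pytest

from stagefit.cohort import NoiseModel, generate_cohort
from stagefit.minicr import fit_protocol, minicr_model, validation_protocol
from stagefit.model import (
    ParameterRegistry,
    ParameterSpec,
    StimulusProtocol,
    VariableSet,
)


class ToyLinearModel:
    """``y = A u + b``, optionally scaled by ``(1 + vco2)`` per level.

    Parameters are ``u1..un`` (gain/threshold, nominal 1) plus one time
    constant ``tau``.  Gives closed-form Jacobians and sensitivities.
    """

    name = "toy_linear"

    def __init__(self, A, intercept=0.0, level_scale=False):
        self.A = np.atleast_2d(np.asarray(A, dtype=float))
        m, n = self.A.shape
        self.intercept = intercept
        self.level_scale = level_scale
        specs = [
            ParameterSpec(f"u{j + 1}", 1.0, "gain_threshold", "sys")
            for j in range(n)
        ]
        specs.append(ParameterSpec("tau", 100.0, "time_constant", "sys"))
        self.registry = ParameterRegistry(specs)
        names = tuple(f"y{i + 1}" for i in range(m))
        self.variables = VariableSet(
            names=names, subsystems={v: "sys" for v in names}
        )
        self.related_subsystems = {"sys": frozenset({"sys"})}

    def steady_state(self, params, vo2, vco2):
        u = np.array([params[f"u{j + 1}"] for j in range(self.A.shape[1])])
        y = self.A @ u + self.intercept
        if self.level_scale:
            y = y * (1.0 + vco2)
        return dict(zip(self.variables.names, map(float, y)))

    def time_constant(self, variable, params):
        return float(params["tau"])

    def initial_state(self, params, first_level):
        return dict(first_level)


def toy_protocol(n_levels=2):
    vco2 = tuple(0.3 + 0.3 * i for i in range(n_levels))
    return StimulusProtocol(tuple((v, v) for v in vco2), 3000.0, 60.0)


@pytest.fixture(scope="session")
def minicr():
    return minicr_model()


@pytest.fixture(scope="session")
def protocol3():
    return fit_protocol()


@pytest.fixture(scope="session")
def protocol8():
    return validation_protocol()


@pytest.fixture(scope="session")
def clean_cohort(minicr, protocol3):
    """Zero-noise three-subject cohort at nominal parameters."""
    return generate_cohort(
        minicr, None, protocol3, n_subjects=3, noise=NoiseModel(0.0, 0.0), seed=0
    )


@pytest.fixture(scope="session")
def perturbed_cohort(minicr, protocol3):
    """Zero-noise cohort at a truth perturbed away from nominal, so the
    nominal model has nonzero errors (screening weights are well defined)."""
    truth = {
        "Gc": minicr.registry["Gc"].nominal * 1.15,
        "Rtot": minicr.registry["Rtot"].nominal * 0.92,
        "BF0": minicr.registry["BF0"].nominal * 0.90,
        "kHR": minicr.registry["kHR"].nominal * 1.10,
    }
    return generate_cohort(
        minicr, truth, protocol3, n_subjects=3, noise=NoiseModel(0.0, 0.0), seed=0
    )
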