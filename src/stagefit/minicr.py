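"""MiniCR: a miniature cardiorespiratory fixed-point model.

MiniCR is the bundled demonstration model used by all tests and examples.
It reproduces, at desk scale, the subsystem structure, observed-variable
set, and nonlinearity classes (controller saturation, exponential hypoxic
chemoreflex, hyperbolic alveolar gas exchange) of full-scale
cardiorespiratory exercise models, without their several-hundred-parameter
equation systems.

Steady state at one stimulus level (VO2, VCO2 in L/min):

* inspired partial pressures: ``PIO2 = FiO2 (Patm - p_h2o)``,
  ``PICO2 = FiCO2 (Patm - p_h2o)``;
* alveolar gas exchange for an alveolar ventilation ``VA`` (L/min):
  ``PACO2 = PICO2 + k_gas VCO2 / (co2_eff VA)`` and
  ``PAO2 = PIO2 - k_gas VO2 / (o2_eff VA)``;
* ventilatory controller, solved as a scalar fixed point in ``VA``::

      VA = max(VA_min, Gc (PACO2 - Bc) + Gp exp(-PAO2 / Kp)
                        + Gm (VCO2 - VCO2_rest))

  For ``Gc, Gp > 0`` the drive is strictly decreasing in ``VA`` so the
  fixed point is unique; it is bracketed by bisection and polished with
  Newton steps to a residual below 1e-10.
* breathing pattern: ``BF = BF0 + kBF VA``; ``VE = VA + BF VD0``;
  ``VT = VE / BF``; ``TI = 60 DI / BF``.
* cardiovascular loop, driven by the metabolic surplus
  ``dVO2 = VO2 - VO2_rest``: ``CO = CO0 + kCO dVO2``;
  ``HR = HR0 + kHR dVO2``; mean pressure
  ``PM = Pv0 + CO Rtot (1 - phi dVO2)`` (exercise vasodilation);
  pulse pressure ``PP = PP0 + kPP (CO - CO0)``; ``PS = PM + 2 PP / 3``;
  ``PD = PM - PP / 3``.

Transients are first-order relaxations toward the active level's steady
state with one time constant per subsystem group (respiratory,
cardiovascular, gas stores).

Nominal values are fixed here, inside textbook physiological ranges for a
healthy adult, so that rest outputs are plausible (HR ~70 bpm, PACO2
~40 mmHg, VE ~9 L/min); tests rely on these exact defaults.
"""

from __future__ import annotations

import math
from collections.abc import Mapping

from .model import (
    ParameterRegistry,
    ParameterSpec,
    SimulationError,
    StimulusProtocol,
    VariableSet,
)

#: Default respiratory exchange ratio used to derive VO2 from VCO2 when a
#: protocol is specified by its VCO2 grid alone.
DEFAULT_RQ = 0.85

VARIABLES = VariableSet(
    names=("VE", "VT", "BF", "TI", "HR", "PS", "PD", "PM", "PAO2", "PACO2"),
    units={
        "VE": "L/min",
        "VT": "L",
        "BF": "1/min",
        "TI": "s",
        "HR": "1/min",
        "PS": "mmHg",
        "PD": "mmHg",
        "PM": "mmHg",
        "PAO2": "mmHg",
        "PACO2": "mmHg",
    },
    subsystems={
        "VE": "respiratory_mechanics",
        "VT": "respiratory_mechanics",
        "BF": "respiratory_mechanics",
        "TI": "respiratory_mechanics",
        "HR": "cardiovascular_system",
        "PS": "cardiovascular_system",
        "PD": "cardiovascular_system",
        "PM": "cardiovascular_system",
        "PAO2": "gas_exchange",
        "PACO2": "gas_exchange",
    },
)


def _registry() -> ParameterRegistry:
    P = ParameterSpec
    return ParameterRegistry(
        [
            # covariates: environment and subject characteristics
            P("FiO2", 0.2093, "covariate", "gas_exchange", units="fraction"),
            P("FiCO2", 0.0004, "covariate", "gas_exchange", units="fraction"),
            P("Patm", 760.0, "covariate", "gas_exchange", units="mmHg"),
            P("VO2_rest", 0.35, "covariate", "gas_exchange", units="L/min"),
            P("VCO2_rest", 0.30, "covariate", "gas_exchange", units="L/min"),
            # conversion constants
            P("k_gas", 863.0, "conversion", "gas_exchange", units="mmHg", fixed=True),
            P("p_h2o", 47.0, "conversion", "gas_exchange", units="mmHg", fixed=True),
            # ventilatory controller gains and thresholds
            P("Gc", 2.0, "gain_threshold", "respiratory_controller", units="L/min/mmHg"),
            P("Bc", 37.0, "gain_threshold", "respiratory_controller", units="mmHg"),
            P("Gp", 30.0, "gain_threshold", "respiratory_controller", units="L/min"),
            P("Kp", 50.0, "gain_threshold", "respiratory_controller", units="mmHg"),
            P(
                "Gm",
                8.0,
                "gain_threshold",
                "respiratory_controller",
                units="L/min per L/min",
                mechanisms=(("metabolic_drive", "ventilatory gain"),),
            ),
            P("VA_min", 2.0, "gain_threshold", "respiratory_controller", units="L/min"),
            # breathing pattern
            P("BF0", 8.0, "gain_threshold", "respiratory_mechanics", units="1/min"),
            P(
                "kBF",
                1.2,
                "gain_threshold",
                "respiratory_mechanics",
                units="1/min per L/min",
                mechanisms=(("ventilatory_pattern", "breathing frequency drive"),),
            ),
            P("VD0", 0.15, "gain_threshold", "respiratory_mechanics", units="L"),
            P("DI", 0.4, "gain_threshold", "respiratory_mechanics", units="fraction"),
            # cardiovascular system
            P("CO0", 5.0, "gain_threshold", "cardiovascular_system", units="L/min"),
            P(
                "kCO",
                5.0,
                "gain_threshold",
                "cardiovascular_system",
                units="L/min per L/min",
                mechanisms=(("exercise_inotropy", "cardiac output gain"),),
            ),
            P("Pv0", 5.0, "gain_threshold", "cardiovascular_system", units="mmHg"),
            P("Rtot", 17.5, "gain_threshold", "cardiovascular_system", units="mmHg/(L/min)"),
            # PP0 is clinically non-modifiable in this fixture and exercises
            # the exclusion contract (it never enters a candidate set).
            P("PP0", 40.0, "gain_threshold", "cardiovascular_system", units="mmHg", excluded=True),
            P(
                "kPP",
                6.0,
                "gain_threshold",
                "cardiovascular_system",
                units="mmHg/(L/min)",
                mechanisms=(("pulse_pressure", "stroke volume effect"),),
            ),
            # cardiovascular controller
            P("HR0", 70.0, "gain_threshold", "cardiovascular_controller", units="1/min"),
            P(
                "kHR",
                60.0,
                "gain_threshold",
                "cardiovascular_controller",
                units="1/min per L/min",
                mechanisms=(("exercise_chronotropy", "heart rate gain"),),
            ),
            P(
                "phi",
                0.45,
                "gain_threshold",
                "cardiovascular_controller",
                units="per L/min",
                mechanisms=(("exercise_vasodilation", "peripheral resistance"),),
            ),
            # gas exchange efficiency gains
            P("co2_eff", 1.0, "gain_threshold", "gas_exchange", units="fraction"),
            P("o2_eff", 1.0, "gain_threshold", "gas_exchange", units="fraction"),
            # transient time constants
            P("tau_resp", 60.0, "time_constant", "respiratory_mechanics", units="s"),
            P("tau_cardio", 40.0, "time_constant", "cardiovascular_system", units="s"),
            P("tau_gas", 120.0, "time_constant", "gas_exchange", units="s"),
            # initial states of the transient integrator, as fractional
            # offsets of the first level's steady state (0 = start settled)
            P("init_resp", 0.0, "initial_value", "respiratory_mechanics", units="fraction"),
            P("init_cardio", 0.0, "initial_value", "cardiovascular_system", units="fraction"),
            P("init_gas", 0.0, "initial_value", "gas_exchange", units="fraction"),
        ]
    )


_TAU_OF_SUBSYS = {
    "respiratory_mechanics": "tau_resp",
    "respiratory_controller": "tau_resp",
    "cardiovascular_system": "tau_cardio",
    "cardiovascular_controller": "tau_cardio",
    "gas_exchange": "tau_gas",
}

_INIT_OF_SUBSYS = {
    "respiratory_mechanics": "init_resp",
    "respiratory_controller": "init_resp",
    "cardiovascular_system": "init_cardio",
    "cardiovascular_controller": "init_cardio",
    "gas_exchange": "init_gas",
}


class MiniCR:
    """Bundled miniature cardiorespiratory demo model (see module docstring)."""

    name = "minicr"
    #: solver settings for the scalar ventilation fixed point
    fp_tol = 1e-10
    fp_max_iter = 200
    va_hi = 100.0

    def __init__(self) -> None:
        self.registry = _registry()
        self.variables = VARIABLES
        self.related_subsystems = {
            "respiratory_mechanics": frozenset(
                {"respiratory_mechanics", "respiratory_controller", "gas_exchange"}
            ),
            "respiratory_controller": frozenset(
                {"respiratory_controller", "respiratory_mechanics", "gas_exchange"}
            ),
            "cardiovascular_system": frozenset(
                {"cardiovascular_system", "cardiovascular_controller"}
            ),
            "cardiovascular_controller": frozenset(
                {"cardiovascular_controller", "cardiovascular_system"}
            ),
            "gas_exchange": frozenset(
                {"gas_exchange", "respiratory_controller", "respiratory_mechanics"}
            ),
        }

    # -- ventilation fixed point ---------------------------------------

    def _solve_va(self, p: Mapping[str, float], vo2: float, vco2: float) -> float:
        pio2 = p["FiO2"] * (p["Patm"] - p["p_h2o"])
        pico2 = p["FiCO2"] * (p["Patm"] - p["p_h2o"])
        kg = p["k_gas"]
        gc, bc, gp, kp, gm = p["Gc"], p["Bc"], p["Gp"], p["Kp"], p["Gm"]
        va_min = p["VA_min"]
        a_c = kg * vco2 / p["co2_eff"]
        a_o = kg * vo2 / p["o2_eff"]
        met = gm * (vco2 - p["VCO2_rest"])

        def drive(va: float) -> float:
            paco2 = pico2 + a_c / va
            pao2 = pio2 - a_o / va
            return gc * (paco2 - bc) + gp * math.exp(min(-pao2 / kp, 50.0)) + met

        def resid(va: float) -> float:
            return va - drive(va)

        if resid(va_min) >= 0.0:
            # controller saturates at its ventilation floor
            return va_min
        lo, hi = va_min, self.va_hi
        f_hi = resid(hi)
        while f_hi < 0.0 and hi < 1e4:
            hi *= 2.0
            f_hi = resid(hi)
        if f_hi < 0.0:
            raise SimulationError(
                f"ventilation fixed point did not converge at (VO2={vo2}, "
                f"VCO2={vco2}): residual {f_hi:.3g} at VA={hi:.3g}"
            )
        # bisection to a coarse bracket, then Newton polish
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if resid(mid) < 0.0:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-6:
                break
        va = 0.5 * (lo + hi)
        for _ in range(self.fp_max_iter):
            paco2 = pico2 + a_c / va
            pao2 = pio2 - a_o / va
            ex = math.exp(min(-pao2 / kp, 50.0))
            f = va - (gc * (paco2 - bc) + gp * ex + met)
            # d(drive)/dVA = -gc a_c/va^2 - gp ex a_o/(kp va^2)
            fp = 1.0 + gc * a_c / va**2 + gp * ex * a_o / (kp * va**2)
            step = f / fp
            va_new = va - step
            if not va_min <= va_new <= hi + 1.0:
                break
            va = va_new
            if abs(f) < self.fp_tol:
                break
        if abs(resid(va)) > 100 * self.fp_tol:
            raise SimulationError(
                f"ventilation fixed point residual {resid(va):.3g} exceeds "
                f"tolerance at (VO2={vo2}, VCO2={vco2})"
            )
        return max(va, va_min)

    # -- contract surface ----------------------------------------------

    def steady_state(
        self, params: Mapping[str, float], vo2: float, vco2: float
    ) -> dict[str, float]:
        p = params
        va = self._solve_va(p, vo2, vco2)
        pio2 = p["FiO2"] * (p["Patm"] - p["p_h2o"])
        pico2 = p["FiCO2"] * (p["Patm"] - p["p_h2o"])
        paco2 = pico2 + p["k_gas"] * vco2 / (p["co2_eff"] * va)
        pao2 = pio2 - p["k_gas"] * vo2 / (p["o2_eff"] * va)
        bf = p["BF0"] + p["kBF"] * va
        if bf <= 0:
            raise SimulationError("non-positive breathing frequency")
        ve = va + bf * p["VD0"]
        vt = ve / bf
        ti = 60.0 * p["DI"] / bf
        dvo2 = vo2 - p["VO2_rest"]
        co = p["CO0"] + p["kCO"] * dvo2
        hr = p["HR0"] + p["kHR"] * dvo2
        pm = p["Pv0"] + co * p["Rtot"] * (1.0 - p["phi"] * dvo2)
        pp = p["PP0"] + p["kPP"] * (co - p["CO0"])
        ps = pm + 2.0 * pp / 3.0
        pd_ = pm - pp / 3.0
        return {
            "VE": ve,
            "VT": vt,
            "BF": bf,
            "TI": ti,
            "HR": hr,
            "PS": ps,
            "PD": pd_,
            "PM": pm,
            "PAO2": pao2,
            "PACO2": paco2,
        }

    def time_constant(self, variable: str, params: Mapping[str, float]) -> float:
        subsys = self.variables.subsystem_of(variable)
        return float(params[_TAU_OF_SUBSYS[subsys]])

    def initial_state(
        self, params: Mapping[str, float], first_level: Mapping[str, float]
    ) -> dict[str, float]:
        out = {}
        for v in self.variables.names:
            frac = float(params[_INIT_OF_SUBSYS[self.variables.subsystem_of(v)]])
            out[v] = first_level[v] * (1.0 + frac)
        return out


def minicr_model() -> MiniCR:
    return MiniCR()


def fit_protocol(
    vco2: tuple[float, ...] = (0.3, 0.6, 0.9),
    rq: float = DEFAULT_RQ,
    step_duration: float = 3000.0,
    settle_window: float = 60.0,
) -> StimulusProtocol:
    """Three-level fitting protocol: rest, intermediate exercise, anaerobic
    threshold, as consecutive equidistant incremental VCO2 steps.

    The default tops out at the cohort's expected mean AT (0.9 L/min) so
    that AT-truncated data still cover every fitting level; it nests in the
    default validation grid."""
    levels = tuple((v / rq, v) for v in vco2)
    return StimulusProtocol(levels, step_duration, settle_window)


def validation_protocol(
    start: float = 0.3,
    stop: float = 1.0,
    n_steps: int = 8,
    rq: float = DEFAULT_RQ,
    step_duration: float = 3000.0,
    settle_window: float = 60.0,
) -> StimulusProtocol:
    """Eight incremental, successive, equidistant VCO2 steps (default
    0.3 to 1.0 L/min) used for steady-state validation."""
    step = (stop - start) / (n_steps - 1)
    vco2 = tuple(start + i * step for i in range(n_steps))
    levels = tuple((v / rq, v) for v in vco2)
    return StimulusProtocol(levels, step_duration, settle_window)
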