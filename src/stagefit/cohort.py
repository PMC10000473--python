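"""Synthetic cohort generator with known ground truth.

Real cohorts for cardiopulmonary exercise testing record per-subject
steady-state values of the observed variables at each exercise level,
environment covariates, and each subject's anaerobic threshold (AT).
This module emulates that structure from a model and a "cohort-truth"
parameter vector, so that fitting accuracy is exactly computable:

* each subject's true parameters are the cohort truth with multiplicative
  lognormal inter-subject variability on gain/threshold parameters;
* observations are the subject's simulated steady state times
  multiplicative lognormal measurement noise (physiological variables are
  positive and errors scale with magnitude);
* AT is drawn uniformly over the top portion of the protocol's VCO2 grid,
  and :func:`truncate_at_AT` drops observations above it.

Both noise terms are mean-one (``E[exp(N(mu, s^2))] = 1`` with
``mu = -s^2/2``), so the cohort mean converges to the cohort-truth
simulation as the number of subjects grows. Zero noise reproduces the
cohort-truth simulation exactly, making the fitting cost exactly zero at
the true parameters.

Seeding: one master seed; subject ``i`` draws from
``default_rng([seed, i])`` so adding subjects never reshuffles earlier
ones and identical seeds give bit-identical datasets.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import Model, SimulationError, StimulusProtocol, simulate_steady_state, simulate_transient

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["subject", "level", "vco2", "variable", "value"]


@dataclass(frozen=True)
class NoiseModel:
    """Lognormal noise settings for the generator.

    ``inter_subject_cv`` is the coefficient of variation of subject-level
    true gain/threshold parameters around the cohort truth;
    ``measurement_cv`` is the CV of multiplicative observation noise.
    """

    inter_subject_cv: float = 0.08
    measurement_cv: float = 0.05
    distribution: str = "lognormal"

    def __post_init__(self) -> None:
        if self.inter_subject_cv < 0 or self.measurement_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.distribution != "lognormal":
            raise ValueError("only lognormal noise is supported")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with coefficient of
    variation ``cv`` (exact for the lognormal: sigma^2 = ln(1 + cv^2))."""
    s2 = math.log1p(cv * cv)
    s = math.sqrt(s2)
    return np.exp(rng.normal(-0.5 * s2, s, size=size))


@dataclass
class SteadyStateDataset:
    """Per-subject, per-variable, per-level observations plus metadata.

    ``observations`` is tidy with columns (subject, level, vco2, variable,
    value); ``level`` is 1-based.  ``at`` maps subject -> VCO2 at the
    anaerobic threshold (L/min).  ``true_params`` / ``subject_params``
    expose the generator's ground truth (None for real datasets).
    """

    observations: pd.DataFrame
    protocol: StimulusProtocol
    covariates: dict[str, float]
    at: dict[str, float]
    noise_meta: dict = field(default_factory=dict)
    true_params: Optional[dict[str, float]] = None
    subject_params: Optional[dict[str, dict[str, float]]] = None
    transients: Optional[pd.DataFrame] = None  # tidy: subject, time, variable, value

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.observations["subject"]))

    @property
    def variables(self) -> list[str]:
        return list(dict.fromkeys(self.observations["variable"]))

    def cohort_mean(self) -> pd.DataFrame:
        """Across-subject mean per (variable, level): variables x 0-based
        level columns.  Levels with no surviving subject are absent."""
        wide = self.observations.pivot_table(
            index="variable", columns="level", values="value", aggfunc="mean"
        )
        wide = wide.reindex(index=self.variables)
        wide.columns = [int(c) - 1 for c in wide.columns]
        return wide

    def truncate_at_AT(self) -> "SteadyStateDataset":
        """Drop, per subject, all observations at levels whose VCO2 exceeds
        that subject's anaerobic threshold; nothing else changes."""
        obs = self.observations
        keep = obs.apply(
            lambda row: row["vco2"] <= self.at.get(row["subject"], math.inf), axis=1
        )
        out = obs[keep].reset_index(drop=True)
        if out.empty:
            logger.warning("AT truncation removed every observation")
        return SteadyStateDataset(
            observations=out,
            protocol=self.protocol,
            covariates=dict(self.covariates),
            at=dict(self.at),
            noise_meta=dict(self.noise_meta),
            true_params=self.true_params,
            subject_params=self.subject_params,
            transients=self.transients,
        )

    # -- serialization: tidy TSV + JSON sidecar -------------------------

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.observations.to_csv(d / "dataset.tsv", sep="\t", index=False)
        if self.transients is not None:
            self.transients.to_csv(d / "transients.tsv", sep="\t", index=False)
        sidecar = {
            "covariates": self.covariates,
            "at": self.at,
            "noise_meta": self.noise_meta,
            "true_params": self.true_params,
            "subject_params": self.subject_params,
            "protocol": {
                "levels": [list(lv) for lv in self.protocol.levels],
                "step_duration": self.protocol.step_duration,
                "settle_window": self.protocol.settle_window,
            },
        }
        with open(d / "dataset.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def read(cls, directory) -> "SteadyStateDataset":
        d = Path(directory)
        obs = pd.read_csv(d / "dataset.tsv", sep="\t")
        with open(d / "dataset.json") as fh:
            sc = json.load(fh)
        transients = None
        if (d / "transients.tsv").exists():
            transients = pd.read_csv(d / "transients.tsv", sep="\t")
        proto = sc["protocol"]
        return cls(
            observations=obs,
            protocol=StimulusProtocol(
                tuple(tuple(lv) for lv in proto["levels"]),
                proto["step_duration"],
                proto["settle_window"],
            ),
            covariates=sc["covariates"],
            at=sc["at"],
            noise_meta=sc.get("noise_meta", {}),
            true_params=sc.get("true_params"),
            subject_params=sc.get("subject_params"),
            transients=transients,
        )


def restrict_to_protocol(
    dataset: SteadyStateDataset, protocol: StimulusProtocol
) -> SteadyStateDataset:
    """Dataset restricted and renumbered to ``protocol``'s levels.

    Levels are matched by VCO2 value (the dataset's grid must contain
    every target level); observations at other levels are dropped.
    """
    have = {round(v, 9): i + 1 for i, v in enumerate(dataset.protocol.vco2)}
    mapping: dict[int, int] = {}
    for k, v in enumerate(protocol.vco2):
        key = round(v, 9)
        if key not in have:
            raise ValueError(f"dataset grid has no level with VCO2 = {v}")
        mapping[have[key]] = k + 1
    obs = dataset.observations[dataset.observations["level"].isin(mapping)].copy()
    obs["level"] = obs["level"].map(mapping)
    obs = obs.sort_values(["subject", "level"], kind="stable").reset_index(drop=True)
    return SteadyStateDataset(
        observations=obs,
        protocol=protocol,
        covariates=dict(dataset.covariates),
        at=dict(dataset.at),
        noise_meta=dict(dataset.noise_meta),
        true_params=dataset.true_params,
        subject_params=dataset.subject_params,
        transients=dataset.transients,
    )


def union_protocol(*protocols: StimulusProtocol) -> StimulusProtocol:
    """Merge protocols into one grid sorted by VCO2 (duplicates removed)."""
    seen: dict[float, tuple[float, float]] = {}
    for p in protocols:
        for lv in p.levels:
            seen.setdefault(round(lv[1], 9), lv)
    levels = tuple(seen[k] for k in sorted(seen))
    first = protocols[0]
    return StimulusProtocol(levels, first.step_duration, first.settle_window)


def generate_cohort(
    model: Model,
    true_params: Optional[dict[str, float]],
    protocol: StimulusProtocol,
    n_subjects: int,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    include_transients: bool = False,
    transient_dt: float = 5.0,
    max_resample: int = 5,
) -> SteadyStateDataset:
    """Generate an experimental-style dataset with known ground truth.

    Observations are per-subject simulations times mean-one lognormal
    measurement noise.  A subject whose sampled parameters fail to
    simulate is resampled up to ``max_resample`` times.  AT per subject is
    drawn uniformly between the VCO2 of the protocol's third-highest and
    highest levels (the top two inter-level spans), mirroring validation
    protocols that restrict data at the anaerobic threshold.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    truth = dict(model.registry.nominal_values())
    if true_params:
        truth.update(true_params)
    gains = model.registry.candidates()
    vco2 = protocol.vco2
    at_lo = vco2[max(0, len(vco2) - 3)]
    at_hi = vco2[-1]

    rows: list[tuple] = []
    at: dict[str, float] = {}
    subject_params: dict[str, dict[str, float]] = {}
    trans_rows: list[tuple] = []
    var_names = list(model.variables.names)

    for i in range(n_subjects):
        sid = f"S{i + 1:03d}"
        rng = np.random.default_rng([int(seed), i])
        for attempt in range(max_resample):
            sp = dict(truth)
            if noise.inter_subject_cv > 0:
                factors = _lognormal_factors(rng, noise.inter_subject_cv, len(gains))
                for name, f in zip(gains, factors):
                    sp[name] = truth[name] * float(f)
            try:
                resp = simulate_steady_state(model, sp, protocol)
                break
            except SimulationError:
                logger.warning("subject %s resampled (attempt %d)", sid, attempt + 1)
        else:
            raise SimulationError(
                f"subject {sid}: simulation failed for {max_resample} parameter draws"
            )
        values = resp.values.to_numpy()
        if noise.measurement_cv > 0:
            values = values * _lognormal_factors(rng, noise.measurement_cv, values.shape)
        if at_hi > at_lo:
            at[sid] = float(rng.uniform(at_lo, at_hi))
        else:
            at[sid] = float(at_hi)
        subject_params[sid] = sp
        for k in range(protocol.n_levels):
            for vi, v in enumerate(var_names):
                rows.append((sid, k + 1, vco2[k], v, values[vi, k]))
        if include_transients and protocol.n_levels >= 2:
            step_proto = StimulusProtocol(
                protocol.levels[:2], protocol.step_duration, protocol.settle_window
            )
            times, frame = simulate_transient(model, sp, step_proto, transient_dt)
            for v in var_names:
                series = frame.loc[v].to_numpy()
                for t, y in zip(times, series):
                    trans_rows.append((sid, float(t), v, float(y)))

    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    covariates = {n: truth[n] for n in model.registry.covariate_names()}
    transients = (
        pd.DataFrame(trans_rows, columns=["subject", "time", "variable", "value"])
        if trans_rows
        else None
    )
    return SteadyStateDataset(
        observations=obs,
        protocol=protocol,
        covariates=covariates,
        at=at,
        noise_meta={
            "seed": int(seed),
            "n_subjects": n_subjects,
            "inter_subject_cv": noise.inter_subject_cv,
            "measurement_cv": noise.measurement_cv,
            "distribution": noise.distribution,
        },
        true_params=truth,
        subject_params=subject_params,
        transients=transients,
    )
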