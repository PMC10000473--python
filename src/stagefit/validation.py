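"""Validation metrics: prediction error, percent change, settling time.

Steady-state accuracy is summarized by the prediction error

    ``PE = (1/N) sum_v Median_{s,l} |y_exp_svl - y_sim_vl| / |y_exp_svl| x 100%``

— the median absolute relative error over all (subject, level) pairs per
variable, averaged over variables.  The median is taken jointly over
subject x level pairs (robust to the non-normal error distributions of
exercise data); every subject is compared against the single
cohort-level simulation; data are restricted to each subject's anaerobic
threshold before scoring.

Transient behavior is summarized per variable by the percent change from
rest and by the settling time: the time from stimulus onset until the
response *permanently* enters a +/-5% band around its final value (final
entry into band; the final value is the last-minute signal average).

Stage-to-stage improvement is assessed by a paired two-sided Wilcoxon
signed-rank test on per-subject PE values (chosen over a t-test because
these errors are not normally distributed), flagged at 0.05 and 0.01.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SteadyStateDataset
from .model import Model, SteadyStateResponse, StimulusProtocol, simulate_steady_state, simulate_transient

logger = logging.getLogger(__name__)

BAND_FRACTION = 0.05


def _relative_errors(dataset: SteadyStateDataset, response: SteadyStateResponse) -> pd.DataFrame:
    """Tidy (subject, level, variable, rel_err) against the cohort-level
    simulation; levels missing from the response are ignored."""
    sim = response.values
    obs = dataset.observations
    rows = []
    for _, r in obs.iterrows():
        k = int(r["level"]) - 1
        if k not in sim.columns or r["variable"] not in sim.index:
            continue
        y_exp = float(r["value"])
        if y_exp == 0:
            continue
        y_sim = float(sim.loc[r["variable"], k])
        rows.append((r["subject"], k + 1, r["variable"], abs(y_exp - y_sim) / abs(y_exp)))
    return pd.DataFrame(rows, columns=["subject", "level", "variable", "rel_err"])


def prediction_error(
    dataset: SteadyStateDataset,
    response: SteadyStateResponse,
    variables: Optional[list[str]] = None,
) -> tuple[float, dict[str, float]]:
    """Overall PE (%) and the per-variable median terms (x100).

    Variables with no surviving (subject, level) pairs are excluded with
    a warning.
    """
    err = _relative_errors(dataset, response)
    if variables is None:
        variables = list(dict.fromkeys(dataset.observations["variable"]))
    per_var: dict[str, float] = {}
    for v in variables:
        vals = err.loc[err["variable"] == v, "rel_err"]
        if vals.empty:
            logger.warning("no (subject, level) pairs for variable %s; excluded", v)
            continue
        per_var[v] = float(vals.median()) * 100.0
    if not per_var:
        raise ValueError("no variable has any usable observation")
    pe = float(np.mean(list(per_var.values())))
    return pe, per_var


def per_subject_pe(
    dataset: SteadyStateDataset,
    response: SteadyStateResponse,
    variables: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Per-subject, per-variable PE terms (%): median over that subject's
    levels.  Rows: subjects, columns: variables."""
    err = _relative_errors(dataset, response)
    if variables is not None:
        err = err[err["variable"].isin(variables)]
    table = err.pivot_table(
        index="subject", columns="variable", values="rel_err", aggfunc="median"
    )
    return table * 100.0


def percent_change_from_rest(series: np.ndarray, baseline: float) -> np.ndarray:
    """``(y(t) - y0)/y0`` per sample; exactly 0 where y equals baseline."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    series = np.asarray(series, dtype=float)
    return (series - baseline) / baseline


def settling_time(
    times: np.ndarray,
    series: np.ndarray,
    t_onset: float,
    final_value: Optional[float] = None,
    settle_window: float = 60.0,
) -> float:
    """Time from ``t_onset`` until the response permanently stays within
    +/-5% of its final value.

    ``final_value`` defaults to the mean over the trailing
    ``settle_window`` seconds.  Containment is checked over every suffix
    (final entry into the band), so a response that re-exits the band
    settles only at its last entry.  Returns 0 when already inside at
    onset; raises if the band is never permanently entered.  A final
    value indistinguishable from zero falls back to a band of 5% of the
    step magnitude, with a warning.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if final_value is None:
        tail = times >= times[-1] - settle_window
        final_value = float(series[tail].mean())
    if abs(final_value) < 1e-9:
        onset_idx = int(np.searchsorted(times, t_onset))
        step = abs(float(series[-1]) - float(series[onset_idx]))
        band = BAND_FRACTION * step
        logger.warning("settling band fallback: |final| ~ 0, using 5%% of step")
    else:
        band = BAND_FRACTION * abs(final_value)
    mask = times >= t_onset
    t_seg = times[mask]
    y_seg = series[mask]
    inside = np.abs(y_seg - final_value) <= band
    if not inside[-1]:
        raise ValueError("response never permanently enters the settling band")
    outside = np.flatnonzero(~inside)
    if outside.size == 0:
        return 0.0
    return float(t_seg[outside[-1] + 1] - t_onset)


def compare_stages(
    per_subject: Mapping[str, pd.DataFrame],
    alpha: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests between consecutive stages.

    ``per_subject`` maps stage name -> subjects x variables PE table (in
    stage order).  Returns a tidy frame (stage_from, stage_to, variable,
    p_value, significant_05, significant_01).  With fewer than 5 paired
    subjects the test is skipped with a warning.
    """
    stages = list(per_subject)
    rows = []
    for a, b in zip(stages, stages[1:]):
        ta, tb = per_subject[a].align(per_subject[b], join="inner")
        if len(ta) < 5:
            logger.warning("fewer than 5 subjects; %s vs %s test skipped", a, b)
            continue
        for v in ta.columns:
            x = ta[v].to_numpy()
            y = tb[v].to_numpy()
            if np.allclose(x, y):
                p = 1.0
            else:
                p = float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)
            rows.append((a, b, v, p, p < alpha[0], p < alpha[1]))
    return pd.DataFrame(
        rows,
        columns=[
            "stage_from",
            "stage_to",
            "variable",
            "p_value",
            "significant_05",
            "significant_01",
        ],
    )


def relative_pe_reduction(pe_first: float, pe_last: float) -> float:
    """Percent reduction of the overall PE from the first to the last
    stage: ``100 (pe_first - pe_last)/pe_first``."""
    if pe_first == 0:
        raise ValueError("reference PE must be nonzero")
    return 100.0 * (pe_first - pe_last) / pe_first


@dataclass
class ValidationReport:
    """Steady-state and transient validation of one or more fit stages."""

    pe_overall: dict[str, float]  # stage -> PE %
    pe_per_variable: dict[str, dict[str, float]]
    pe_per_subsystem: dict[str, dict[str, tuple[float, float]]]  # stage -> subsys -> (mean, sd)
    settling_times: dict[str, dict[str, float]]  # stage -> variable -> s
    stage_comparison: pd.DataFrame = field(default_factory=pd.DataFrame)
    pe_relative_reduction: float = float("nan")

    def to_json(self, path) -> None:
        payload = {
            "pe_overall": self.pe_overall,
            "pe_per_variable": self.pe_per_variable,
            "pe_per_subsystem": {
                st: {s: list(v) for s, v in d.items()}
                for st, d in self.pe_per_subsystem.items()
            },
            "settling_times": self.settling_times,
            "stage_comparison": self.stage_comparison.to_dict(orient="records"),
            "pe_relative_reduction": self.pe_relative_reduction,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def build_validation_report(
    model: Model,
    dataset: SteadyStateDataset,
    stage_params: Mapping[str, Mapping[str, float]],
    protocol: Optional[StimulusProtocol] = None,
    transient_protocol: Optional[StimulusProtocol] = None,
    sample_dt: float = 1.0,
) -> ValidationReport:
    """Validate each stage's parameter vector against the dataset.

    ``stage_params`` maps stage label -> full parameter vector, in stage
    order (typically nominal first, then each fitting stage).  The
    dataset is truncated at each subject's anaerobic threshold before
    scoring.  Transient settling is evaluated on the first load step of
    ``transient_protocol`` (defaults to the first two validation levels).
    """
    protocol = protocol or dataset.protocol
    data = dataset.truncate_at_AT()
    if transient_protocol is None and protocol.n_levels >= 2:
        transient_protocol = StimulusProtocol(
            protocol.levels[:2], protocol.step_duration, protocol.settle_window
        )

    pe_overall: dict[str, float] = {}
    pe_var: dict[str, dict[str, float]] = {}
    pe_sub: dict[str, dict[str, tuple[float, float]]] = {}
    settling: dict[str, dict[str, float]] = {}
    per_subject_tables: dict[str, pd.DataFrame] = {}

    subsys_of = {v: model.variables.subsystem_of(v) for v in model.variables.names}

    for stage, params in stage_params.items():
        resp = simulate_steady_state(model, params, protocol)
        pe, per_var = prediction_error(data, resp)
        pe_overall[stage] = pe
        pe_var[stage] = per_var
        table = per_subject_pe(data, resp)
        per_subject_tables[stage] = table
        # subsystem summary: mean +/- sd across subjects of per-subject
        # subsystem PE (mean over that subsystem's variables)
        sub: dict[str, tuple[float, float]] = {}
        for s in dict.fromkeys(subsys_of.values()):
            cols = [v for v in table.columns if subsys_of.get(v) == s]
            if not cols:
                continue
            per_subj = table[cols].mean(axis=1)
            sub[s] = (float(per_subj.mean()), float(per_subj.std(ddof=1)))
        pe_sub[stage] = sub

        if transient_protocol is not None:
            times, frame = simulate_transient(model, params, transient_protocol, sample_dt)
            onset = transient_protocol.step_duration
            st: dict[str, float] = {}
            for v in model.variables.names:
                try:
                    st[v] = settling_time(
                        times,
                        frame.loc[v].to_numpy(),
                        onset,
                        settle_window=transient_protocol.settle_window,
                    )
                except ValueError:
                    st[v] = float("nan")
            settling[stage] = st

    comparison = compare_stages(per_subject_tables)
    stages = list(stage_params)
    reduction = (
        relative_pe_reduction(pe_overall[stages[0]], pe_overall[stages[-1]])
        if len(stages) > 1 and pe_overall[stages[0]] != 0
        else float("nan")
    )
    return ValidationReport(
        pe_overall=pe_overall,
        pe_per_variable=pe_var,
        pe_per_subsystem=pe_sub,
        settling_times=settling,
        stage_comparison=comparison,
        pe_relative_reduction=reduction,
    )
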