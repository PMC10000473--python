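"""The four parameter-selection approaches.

Candidates are narrowed in four passes, each producing one piece of a
:class:`SelectionPlan`:

1. **Role filter** — time constants, conversion constants and initial
   values are discarded; covariates are routed to standardization;
   excluded parameters are dropped outright.
2. **Standardization** — covariates are fixed by direct equivalence with
   the dataset's recorded values (environment, subject characteristics).
3. **Base set** — parameters the model is sensitive to *as a group*:
   the union of (a) subset-selection candidates whose aggregated
   normalized singular value exceeds the rank tolerance and (b) the top
   of the total-sensitivity ranking, walked descending until every
   declared subsystem and controller has at least one selected parameter.
4. **Specific set** — one parameter per observed variable, chosen for
   high sensitivity to that variable and low sensitivity to variables of
   unrelated subsystems (specificity score below).
5. **Stimulus set** — one remaining free parameter per (mechanism,
   regulatory activity) tag, by total sensitivity.

The three fitted sets are pairwise disjoint by construction; no excluded
or standardized parameter ever appears in any of them.

The specificity score makes the qualitative rule "high for the variable
of interest and low for the remaining ones" monotone and testable: with
``s~_ij`` the per-variable max-normalized sensitivity, the score of
parameter j for variable i is ``s~_ij - max over unrelated variables i'
of s~_i'j``, where related variables are those whose subsystem is in the
model-declared adjacency of variable i's subsystem.  Conflicts (one
parameter topping two variables) are resolved in favour of the higher
score; the loser takes its next admissible candidate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .cohort import SteadyStateDataset
from .model import ParameterRegistry
from .screen import DEFAULT_EPSILON, ScreeningResult

logger = logging.getLogger(__name__)


@dataclass
class SelectionPlan:
    """Outcome of the four selection approaches, with provenance."""

    standardized: dict[str, float] = field(default_factory=dict)
    base_set: list[str] = field(default_factory=list)
    specific_set: dict[str, str] = field(default_factory=dict)  # variable -> parameter
    stimulus_set: dict[tuple[str, str], str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        base = set(self.base_set)
        spec = set(self.specific_set.values())
        stim = set(self.stimulus_set.values())
        if base & spec or base & stim or spec & stim:
            raise ValueError("fitted sets must be pairwise disjoint")
        if set(self.standardized) & (base | spec | stim):
            raise ValueError("standardized parameters cannot be fitted")
        if len(spec) != len(self.specific_set):
            raise ValueError("a parameter may serve only one variable")

    def stage_sets(self) -> dict[str, list[str]]:
        return {
            "base": list(self.base_set),
            "specific": list(self.specific_set.values()),
            "stimulus": list(self.stimulus_set.values()),
        }

    def to_json(self, path) -> None:
        payload = {
            "standardized": self.standardized,
            "base_set": self.base_set,
            "specific_set": self.specific_set,
            "stimulus_set": {f"{m}|{a}": p for (m, a), p in self.stimulus_set.items()},
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SelectionPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            standardized=d["standardized"],
            base_set=d["base_set"],
            specific_set=d["specific_set"],
            stimulus_set={
                tuple(key.split("|", 1)): p for key, p in d["stimulus_set"].items()
            },
            provenance=d.get("provenance", {}),
        )

    def report(self) -> str:
        lines = ["standardized:"]
        lines += [f"  {n} = {v}" for n, v in self.standardized.items()]
        for stage, names in self.stage_sets().items():
            lines.append(f"{stage} set ({len(names)}):")
            lines += [f"  {n}: {self.provenance.get(n, '')}" for n in names]
        return "\n".join(lines)


def reduction_percent(n_stage: int, n_total: int) -> float:
    """Percent reduction 100 (1 - n_stage/n_total), one decimal,
    round-half-away-from-zero."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    value = Decimal(100) * (1 - Decimal(n_stage) / Decimal(n_total))
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def role_filter(registry: ParameterRegistry) -> tuple[list[str], list[str]]:
    """Split the registry by role: ``(fit candidates, covariates)``.

    Gain/threshold parameters minus excluded (and already-fixed) ones are
    the fit candidates; covariates go to standardization; conversion
    constants, time constants and initial values are discarded.
    """
    return registry.candidates(), registry.covariate_names()


def standardize(
    registry: ParameterRegistry, dataset: SteadyStateDataset
) -> dict[str, float]:
    """Covariate values taken from the dataset by direct equivalence.

    The returned parameters are fixed for every later stage.  A covariate
    the dataset does not record is an error.
    """
    out: dict[str, float] = {}
    for name in registry.covariate_names():
        if name not in dataset.covariates:
            raise KeyError(f"dataset records no value for covariate {name!r}")
        out[name] = float(dataset.covariates[name])
    return out


def select_base(
    screening: ScreeningResult,
    epsilon: float = DEFAULT_EPSILON,
    subsystem_map: Optional[Mapping[str, str]] = None,
    subsystems: Optional[list[str]] = None,
) -> tuple[list[str], dict[str, str]]:
    """Base-stage set: subset-selection criterion plus subsystem coverage.

    Returns ``(base_set, provenance)``.  Admits every candidate whose
    aggregated normalized singular value ``Z_j`` exceeds ``epsilon``, then
    walks the total-sensitivity ranking descending until every declared
    subsystem has at least one admitted parameter (counting those already
    admitted).
    """
    subsystem_map = subsystem_map or screening.param_subsystems
    if subsystems is None:
        subsystems = list(dict.fromkeys(subsystem_map.values()))
    uncoverable = [
        s for s in subsystems if not any(subsystem_map.get(p) == s for p in screening.candidates)
    ]
    if uncoverable:
        raise ValueError(f"subsystems with no candidate parameters: {uncoverable}")

    base: list[str] = []
    prov: dict[str, str] = {}
    for name, z in zip(screening.candidates, screening.Z_j):
        if z > epsilon:
            base.append(name)
            prov[name] = f"subset selection: Z_j = {z:.3g} > eps = {epsilon:g}"
    covered = {subsystem_map[p] for p in base}
    if not covered >= set(subsystems):
        for name, s in screening.total_ranking():
            if covered >= set(subsystems):
                break
            if name in base:
                continue
            subsys = subsystem_map[name]
            if subsys not in covered:
                base.append(name)
                covered.add(subsys)
                prov[name] = f"total sensitivity: coverage of {subsys} (s_j = {s:.3g})"
    # keep registry (candidate) order for determinism
    ordered = [p for p in screening.candidates if p in set(base)]
    return ordered, prov


def select_specific(
    screening: ScreeningResult,
    base_set: list[str],
    variable_subsystem_map: Mapping[str, str],
    related_subsystems: Mapping[str, frozenset[str]],
    specificity_margin: float = 0.0,
) -> tuple[dict[str, str], dict[str, str]]:
    """One parameter per variable maximizing the specificity score.

    Returns ``(specific_set, provenance)``; variables with no admissible
    candidate are left unassigned with a warning.
    """
    base = set(base_set)
    cand = screening.candidates
    s = screening.s_ij
    max_i = s.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        stilde = np.where(max_i > 0, s / max_i, 0.0)

    var_names = screening.variables
    related_of: dict[str, frozenset[str]] = {
        v: related_subsystems.get(
            variable_subsystem_map[v], frozenset({variable_subsystem_map[v]})
        )
        for v in var_names
    }
    unrelated_rows: dict[str, list[int]] = {
        v: [
            i2
            for i2, v2 in enumerate(var_names)
            if variable_subsystem_map[v2] not in related_of[v]
        ]
        for v in var_names
    }

    # ranked admissible candidates with scores, per variable
    queues: dict[str, list[tuple[str, float]]] = {}
    for i, v in enumerate(var_names):
        entries: list[tuple[str, float, float, int]] = []
        for j, name in enumerate(cand):
            if name in base:
                continue
            if screening.param_subsystems.get(name) not in related_of[v]:
                continue
            cross = max((stilde[i2, j] for i2 in unrelated_rows[v]), default=0.0)
            score = float(stilde[i, j] - cross)
            if score > specificity_margin:
                entries.append((name, score, float(s[i, j]), j))
        entries.sort(key=lambda e: (-e[1], -e[2], e[3]))
        queues[v] = [(name, score) for name, score, _, _ in entries]

    assigned: dict[str, str] = {}  # variable -> parameter
    scores: dict[str, float] = {}
    pointer = {v: 0 for v in var_names}
    changed = True
    while changed:
        changed = False
        for v in var_names:
            if v in assigned:
                continue
            q = queues[v]
            while pointer[v] < len(q):
                name, score = q[pointer[v]]
                holder = next((v2 for v2, p in assigned.items() if p == name), None)
                if holder is None:
                    assigned[v] = name
                    scores[v] = score
                    changed = True
                    break
                if score > scores[holder]:
                    # steal: higher specificity wins, loser re-enters
                    del assigned[holder]
                    assigned[v] = name
                    scores[v] = score
                    changed = True
                    break
                pointer[v] += 1
    prov: dict[str, str] = {}
    for v in var_names:
        if v in assigned:
            prov[assigned[v]] = f"specific: variable {v} (specificity {scores[v]:.3g})"
        else:
            logger.warning("no admissible specific-stage candidate for %s", v)
    return assigned, prov


def select_stimulus(
    registry: ParameterRegistry,
    base_set: list[str],
    specific_set: Mapping[str, str],
    s_j: Mapping[str, float],
) -> tuple[dict[tuple[str, str], str], dict[str, str]]:
    """One free parameter per (mechanism, regulatory activity) tag.

    Among the tagged parameters not already selected, the one with the
    highest total sensitivity wins; a tag whose parameters are all taken
    produces a logged warning and no selection.
    """
    taken = set(base_set) | set(specific_set.values())
    groups: dict[tuple[str, str], list[str]] = {}
    for name in registry.candidates():
        for tag in registry[name].mechanisms:
            groups.setdefault(tuple(tag), []).append(name)
    out: dict[tuple[str, str], str] = {}
    prov: dict[str, str] = {}
    chosen: set[str] = set()
    for tag, names in groups.items():
        free = [n for n in names if n not in taken and n not in chosen]
        if not free:
            logger.warning("mechanism %s has no free parameter", tag)
            continue
        best = max(free, key=lambda n: (s_j.get(n, 0.0), -registry.names.index(n)))
        out[tag] = best
        chosen.add(best)
        prov[best] = f"stimulus: mechanism {tag[0]!r}, activity {tag[1]!r}"
    return out, prov


def build_selection_plan(
    model,
    dataset: SteadyStateDataset,
    screening: ScreeningResult,
    epsilon: float = DEFAULT_EPSILON,
    specificity_margin: float = 0.0,
) -> SelectionPlan:
    """Apply all four approaches in order and assemble the plan."""
    std = standardize(model.registry, dataset)
    base, prov_b = select_base(screening, epsilon)
    var_subsys = {v: model.variables.subsystem_of(v) for v in model.variables.names}
    specific, prov_sp = select_specific(
        screening, base, var_subsys, model.related_subsystems, specificity_margin
    )
    s_j = dict(zip(screening.candidates, map(float, screening.s_j)))
    stimulus, prov_st = select_stimulus(model.registry, base, specific, s_j)
    prov = {n: "standardized from dataset covariate" for n in std}
    prov.update(prov_b)
    prov.update(prov_sp)
    prov.update(prov_st)
    return SelectionPlan(
        standardized=std,
        base_set=base,
        specific_set=specific,
        stimulus_set=stimulus,
        provenance=prov,
    )
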